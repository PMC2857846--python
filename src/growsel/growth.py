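"""Sigmoid growth curves and per-individual nonlinear least-squares fitting.

Two three-parameter sigmoids are provided:

* the Gompertz curve in the (A, B, C) parameterisation used for analysis,
  ``y(t) = A * exp(-exp(B * e * (C - t) / A))``, where ``A`` is the asymptotic
  final yield, ``B`` the maximum growth rate (the slope at the inflection) and
  ``C`` the age at maximum growth rate (the inflection time).  Two analytic
  identities pin the parameterisation down: ``y(C) = A / e`` and
  ``dy/dt|_{t=C} = B``;
* the standard three-parameter logistic,
  ``y(t) = asym / (1 + exp((xmid - t) / scal))`` (the ``SSlogis``
  parameterisation), which is the data-generating model of the bundled
  simulator.

Fitting is per individual: a handful of time/yield records are condensed into
one :class:`GompertzParams` triple by Levenberg-Marquardt least squares with
an analytic Jacobian.  The fitted triple summarises the whole trajectory and
lets the trait be predicted at times outside the observed range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GompertzParams",
    "LogisticParams",
    "FittedCurve",
    "gompertz_value",
    "gompertz_rate",
    "logistic_value",
    "fit_gompertz",
    "predict_yield",
    "GompertzCurve",
]

_E = math.e
# |inner exponent| beyond this the curve is numerically 0 or A; clipping keeps
# exp() finite while leaving double-precision results unchanged.
_ZCLIP = 50.0


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz curve parameters.

    A : asymptotic final yield (trait units), must be > 0 for a valid curve.
    B : maximum growth rate (trait units per time unit), must be > 0.
    C : age at maximum growth rate (time units).

    Construction is permissive so that a failed fit can still report its
    best-found point; validity is checked by :attr:`valid` and enforced by the
    evaluation functions.
    """

    A: float
    B: float
    C: float

    @property
    def valid(self) -> bool:
        return (
            np.isfinite([self.A, self.B, self.C]).all()
            and self.A > 0
            and self.B > 0
        )


@dataclass(frozen=True)
class LogisticParams:
    """Three-parameter logistic curve parameters (``SSlogis`` naming).

    asym : asymptotic yield (> 0); comparable in meaning to Gompertz ``A``.
    xmid : inflection time — the curve passes through ``asym / 2`` there.
    scal : time-scale parameter (> 0).
    """

    asym: float
    xmid: float
    scal: float

    @property
    def valid(self) -> bool:
        return (
            np.isfinite([self.asym, self.xmid, self.scal]).all()
            and self.asym > 0
            and self.scal > 0
        )


@dataclass(frozen=True)
class FittedCurve:
    """Result of fitting a Gompertz curve to one individual's records."""

    params: GompertzParams
    residual_ss: float
    r_squared: float
    converged: bool
    n_points: int
    individual_id: object = None


def _check_params(p: GompertzParams) -> None:
    if not p.valid:
        raise ValueError(f"invalid Gompertz parameters (need A>0, B>0, finite): {p}")


def _inner_exponent(p: GompertzParams, t: np.ndarray) -> np.ndarray:
    return np.clip(p.B * _E * (p.C - t) / p.A, -_ZCLIP, _ZCLIP)


def gompertz_value(p: GompertzParams, t):
    """Evaluate the Gompertz curve at time(s) ``t``.

    Returns values in ``(0, A)``, strictly increasing in ``t``.
    """
    _check_params(p)
    t = np.asarray(t, dtype=float)
    z = _inner_exponent(p, t)
    out = p.A * np.exp(-np.exp(z))
    return float(out) if out.ndim == 0 else out


def gompertz_rate(p: GompertzParams, t):
    """Analytic growth rate dy/dt of the Gompertz curve.

    Non-negative everywhere; maximised at ``t = C`` where it equals ``B``.
    """
    _check_params(p)
    t = np.asarray(t, dtype=float)
    z = _inner_exponent(p, t)
    ez = np.exp(z)
    out = p.B * _E * ez * np.exp(-ez)
    return float(out) if out.ndim == 0 else out


def logistic_value(q: LogisticParams, t):
    """Evaluate the three-parameter logistic curve at time(s) ``t``."""
    if not q.valid:
        raise ValueError(f"invalid logistic parameters (need asym>0, scal>0): {q}")
    t = np.asarray(t, dtype=float)
    z = np.clip((q.xmid - t) / q.scal, -_ZCLIP, _ZCLIP)
    out = q.asym / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def _default_init(times: np.ndarray, yields: np.ndarray) -> GompertzParams:
    """Scale-free starting values for sigmoid-shaped data.

    A0 slightly above the largest observation; C0 the observed time whose
    yield is closest to A0/e (the Gompertz inflection value); B0 the steepest
    observed successive slope.
    """
    a0 = 1.05 * float(np.max(yields))
    if a0 <= 0:
        a0 = 1.0
    order = np.argsort(times)
    ts, ys = times[order], yields[order]
    c0 = float(ts[np.argmin(np.abs(ys - a0 / _E))])
    slopes = np.diff(ys) / np.diff(ts)
    b0 = float(np.max(slopes)) if slopes.size else 0.0
    if b0 <= 0:
        # flat or decreasing data: fall back to mean absolute slope magnitude
        span = float(ts[-1] - ts[0]) or 1.0
        b0 = max(float(np.ptp(ys)) / span, 1e-8 * a0)
    return GompertzParams(a0, b0, c0)


def _residuals_and_jac(theta, times, yields):
    a, b, c = theta
    z = np.clip(b * _E * (c - times) / a, -_ZCLIP, _ZCLIP)
    ez = np.exp(z)
    u = np.exp(-ez)
    resid = a * u - yields
    # dy/dA = u (1 + z e^z); dy/dB = -A u z e^z / B; dy/dC = -B e u e^z
    jac = np.empty((times.size, 3))
    jac[:, 0] = u * (1.0 + z * ez)
    jac[:, 1] = -a * u * z * ez / b
    jac[:, 2] = -b * _E * u * ez
    return resid, jac


def fit_gompertz(
    times,
    yields,
    init: GompertzParams | None = None,
    individual_id=None,
    max_nfev: int = 200,
) -> FittedCurve:
    """Least-squares fit of the Gompertz curve to one individual's records.

    Parameters
    ----------
    times, yields : array-like, equal length, at least 3 distinct time points.
    init : optional starting parameters; a scale-free heuristic is used when
        omitted.
    max_nfev : Levenberg-Marquardt function-evaluation budget.

    Returns a :class:`FittedCurve`; ``converged`` is False when the iteration
    budget is hit, the optimizer fails, or the solution leaves the valid
    domain (A <= 0 or B <= 0).  Constant yields are degenerate (asymptote and
    rate unidentifiable) and are returned unconverged without optimisation.
    """
    times = np.asarray(times, dtype=float).ravel()
    yields = np.asarray(yields, dtype=float).ravel()
    if times.size != yields.size:
        raise ValueError("times and yields must have equal length")
    if np.unique(times).size < 3:
        raise ValueError("need at least 3 distinct time points to fit 3 parameters")
    if not np.isfinite(times).all() or not np.isfinite(yields).all():
        raise ValueError("non-finite values in times or yields")

    p0 = init if init is not None else _default_init(times, yields)
    sst = float(np.sum((yields - yields.mean()) ** 2))

    if np.ptp(yields) == 0.0:
        # degenerate: every parameterisation through the constant is equal
        return FittedCurve(
            params=p0,
            residual_ss=float(np.sum((_safe_eval(p0, times) - yields) ** 2)),
            r_squared=float("nan"),
            converged=False,
            n_points=times.size,
            individual_id=individual_id,
        )

    x0 = np.array([p0.A, p0.B, p0.C], dtype=float)
    r0, _ = _residuals_and_jac(x0, times, yields)
    ss0 = float(r0 @ r0)

    res = least_squares(
        lambda th: _residuals_and_jac(th, times, yields)[0],
        x0,
        jac=lambda th: _residuals_and_jac(th, times, yields)[1],
        method="lm",
        ftol=1e-10,
        xtol=1e-10,
        max_nfev=max_nfev,
    )
    ssr = float(2.0 * res.cost)
    params = GompertzParams(*map(float, res.x))
    if ssr > ss0:  # LM should never worsen the start; keep the better point
        params, ssr = p0, ss0
    converged = bool(res.status > 0) and params.valid
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    return FittedCurve(
        params=params,
        residual_ss=ssr,
        r_squared=r2,
        converged=converged,
        n_points=times.size,
        individual_id=individual_id,
    )


def _safe_eval(p: GompertzParams, t: np.ndarray) -> np.ndarray:
    """Evaluate without the validity check (for reporting failed fits)."""
    z = np.clip(p.B * _E * (p.C - np.asarray(t, float)) / p.A, -_ZCLIP, _ZCLIP)
    return p.A * np.exp(-np.exp(z))


def predict_yield(fit: FittedCurve, t, allow_unconverged: bool = False):
    """Predict the trait from a fitted curve at time(s) ``t``.

    Refuses non-converged fits unless ``allow_unconverged`` is set, in which
    case a warning is emitted and the best-found parameters are used.
    """
    if not fit.converged:
        if not allow_unconverged:
            raise ValueError(
                "refusing to predict from a non-converged fit "
                "(pass allow_unconverged=True to override)"
            )
        warnings.warn("predicting from a non-converged Gompertz fit", stacklevel=2)
        return _safe_eval(fit.params, t)
    return gompertz_value(fit.params, t)


class GompertzCurve(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for one individual's Gompertz trajectory.

    ``fit(X, y)`` takes observation times (1-d or a single-column 2-d array)
    and yields; ``predict(X)`` evaluates the fitted curve.  Thin wrapper over
    :func:`fit_gompertz` / :func:`gompertz_value`.

    Attributes (after fit)
    ----------------------
    params_ : GompertzParams
    curve_ : FittedCurve with residual_ss, r_squared and the converged flag.
    """

    def __init__(self, init: GompertzParams | None = None, max_nfev: int = 200):
        self.init = init
        self.max_nfev = max_nfev

    @staticmethod
    def _as_times(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-d times or a single-column 2-d array")
        return t

    def fit(self, X, y):
        t = self._as_times(X)
        self.curve_ = fit_gompertz(t, y, init=self.init, max_nfev=self.max_nfev)
        self.params_ = self.curve_.params
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "curve_"):
            raise ValueError("GompertzCurve is not fitted yet")
        return predict_yield(self.curve_, self._as_times(X), allow_unconverged=True)
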