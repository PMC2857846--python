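"""Mixture-prior whole-genome regression via single-site Gibbs sampling.

The model is the classic marker-effect regression

    y = X b + sum_i g_i * alpha_i + e,       e ~ N(0, sigma2_e I)

where ``g_i`` is the (column-centered) dosage vector of SNP i and each
allelic substitution effect follows a point-mass/normal mixture

    alpha_i = 0                    with probability 1 - pi
    alpha_i ~ N(0, sigma2_alpha)   with probability pi.

A single slab variance ``sigma2_alpha`` is shared across SNPs and the mixture
proportion ``pi`` is *estimated from the data* under a uniform prior — the
"BayesC-pi" flavour of whole-genome regression.  Flat priors are placed on
both variance components; the resulting full conditionals are scaled
inverse-chi-square.  The indicator update is collapsed: the inclusion
probability of a SNP is computed with its effect integrated out analytically,
which mixes well and is testable against one-dimensional quadrature.

Posterior means over the kept (thinned, post-burn-in) states summarise the
chain: per-SNP inclusion probabilities and mean effects, the variance
components, ``pi`` and per-individual genomic estimated breeding values
(GEBVs) — centered sums of dosage-weighted mean effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "GsData",
    "McmcConfig",
    "PosteriorSummary",
    "run_sampler",
    "inclusion_log_bayes_factor",
    "inclusion_probability",
    "sample_indicator_and_effect",
    "sample_pi",
    "sample_variances",
    "compute_gebv",
    "BayesCPi",
]

# fallback scaled-inv-chi2 for the effect-variance conditional when fewer
# than _MIN_ACTIVE effects are in the model (flat-prior conditional improper)
_FALLBACK_DF = 4.2
_MIN_ACTIVE = 3


@dataclass
class GsData:
    """Inputs of one genomic-evaluation analysis.

    y : phenotype vector, length n.
    G : n x p dosage matrix; files use codes 1/2/3 for genotypes 00, 01|10
        and 11 (columns are centered internally before sampling).
    X : n x q fixed-effect design; intercept-only when omitted.
    snp_map : optional per-SNP table (snp_id, chrom, pos_morgan) carried
        through to reports.
    """

    y: np.ndarray
    G: np.ndarray
    X: np.ndarray | None = None
    snp_map: pd.DataFrame | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be a 2-d matrix")
        if self.G.shape[0] != self.y.size:
            raise ValueError(
                f"G has {self.G.shape[0]} rows but y has {self.y.size} entries"
            )
        if not np.isfinite(self.y).all():
            raise ValueError("non-finite phenotypes")
        if not np.isfinite(self.G).all():
            raise ValueError("non-finite genotype dosages")
        if self.X is None:
            self.X = np.ones((self.y.size, 1))
        else:
            self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if self.X.shape[0] != self.y.size:
                raise ValueError("X and y have incompatible shapes")


@dataclass(frozen=True)
class McmcConfig:
    """Chain schedule: total cycles = burn_in + n_samples * thin.

    The reference schedule of the method is 10000 burn-in cycles followed by
    10000 kept realisations separated by 50 cycles; ``desk_scale`` is a
    reduced preset for interactive and test runs.
    """

    burn_in: int = 10000
    n_samples: int = 10000
    thin: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.burn_in, self.n_samples, self.thin) < 1:
            raise ValueError("burn_in, n_samples and thin must all be >= 1")

    @property
    def total_cycles(self) -> int:
        return self.burn_in + self.n_samples * self.thin

    @classmethod
    def full_scale(cls, seed: int = 0) -> "McmcConfig":
        return cls(burn_in=10000, n_samples=10000, thin=50, seed=seed)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "McmcConfig":
        return cls(burn_in=2000, n_samples=600, thin=5, seed=seed)


@dataclass
class PosteriorSummary:
    """Posterior means over the kept realisations of one chain."""

    alpha_mean: np.ndarray
    incl_prob: np.ndarray
    pi_mean: float
    sigma2a_mean: float
    sigma2e_mean: float
    b_mean: np.ndarray
    gebv: np.ndarray
    n_kept: int
    monomorphic: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_variance_fallbacks: int = 0
    trace: dict | None = None

    def snp_table(self, snp_map: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-SNP report: inclusion probability, mean and rescaled effect."""
        p = self.alpha_mean.size
        tab = pd.DataFrame(
            {
                "snp_id": (
                    snp_map["snp_id"].to_numpy()
                    if snp_map is not None
                    else [f"snp{i + 1}" for i in range(p)]
                ),
                "incl_prob": self.incl_prob,
                "alpha_mean": self.alpha_mean,
            }
        )
        if snp_map is not None:
            tab.insert(1, "chrom", snp_map["chrom"].to_numpy())
            tab.insert(2, "pos_morgan", snp_map["pos_morgan"].to_numpy())
        amax = np.max(np.abs(self.alpha_mean)) if p else 0.0
        tab["alpha_rescaled"] = self.alpha_mean / amax if amax > 0 else 0.0
        return tab


def inclusion_log_bayes_factor(rhs: float, gtg: float, sigma2a: float, sigma2e: float) -> float:
    """log marginal-likelihood ratio (effect in vs. out) for one SNP.

    ``rhs = g' r_excl`` with the SNP's own contribution removed from the
    residual and ``gtg = g'g``.  Derived from r_excl ~ N(0, sigma2e I +
    sigma2a g g') via the matrix determinant / Sherman-Morrison identities.
    """
    t1 = sigma2a * gtg
    return -0.5 * math.log1p(t1 / sigma2e) + 0.5 * sigma2a * rhs * rhs / (
        sigma2e * (sigma2e + t1)
    )


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x)) if x < 35 else 1.0
    return math.exp(x) / (1.0 + math.exp(x)) if x > -35 else 0.0


def inclusion_probability(g, resid_excl, sigma2a: float, sigma2e: float, pi: float) -> float:
    """Collapsed P(delta=1 | rest) for one SNP, effect integrated out.

    ``resid_excl`` must exclude the SNP's current contribution.
    """
    g = np.asarray(g, dtype=float)
    r = np.asarray(resid_excl, dtype=float)
    rhs = float(g @ r)
    gtg = float(g @ g)
    log_odds = math.log(pi / (1.0 - pi)) + inclusion_log_bayes_factor(
        rhs, gtg, sigma2a, sigma2e
    )
    return _sigmoid(log_odds)


def sample_indicator_and_effect(
    rng: np.random.Generator, g, resid_excl, sigma2a: float, sigma2e: float, pi: float
) -> tuple[int, float]:
    """Draw (delta_i, alpha_i) for one SNP from their joint full conditional."""
    g = np.asarray(g, dtype=float)
    r = np.asarray(resid_excl, dtype=float)
    prob = inclusion_probability(g, r, sigma2a, sigma2e, pi)
    if rng.random() >= prob:
        return 0, 0.0
    gtg = float(g @ g)
    v = gtg + sigma2e / sigma2a
    mean = float(g @ r) / v
    return 1, mean + math.sqrt(sigma2e / v) * rng.standard_normal()


def sample_pi(rng: np.random.Generator, delta) -> float:
    """Draw pi from its Beta(1 + k, 1 + p - k) full conditional (uniform prior)."""
    delta = np.asarray(delta)
    k = int(delta.sum())
    p = delta.size
    return float(rng.beta(1.0 + k, 1.0 + p - k))


def sample_variances(
    rng: np.random.Generator,
    alpha,
    delta,
    resid,
    *,
    anchor_sigma2a: float,
    fallback_df: float = _FALLBACK_DF,
) -> tuple[float, float, bool]:
    """Draw (sigma2_alpha, sigma2_e) from their flat-prior full conditionals.

    Flat prior on a variance gives a scaled inverse-chi-square conditional:
    sigma2_e ~ e'e / chi2(n - 2) and sigma2_alpha ~ sum(alpha^2) / chi2(k - 2)
    with k the number of active effects.  With k < 3 the latter is improper,
    so a weakly-informative scaled-inv-chi2 with df ``fallback_df`` is drawn
    instead (flag returned): its scale is the current second moment of the
    active effects (sum(alpha^2)/k) when k is 1 or 2, or the fixed anchor
    ``anchor_sigma2a`` when no effect is in the model.  The k=0 scale must be
    a fixed quantity — re-centering on the previous draw would turn the
    conditional into an upward-drifting multiplicative random walk.
    """
    resid = np.asarray(resid, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n = resid.size
    if n <= 2:
        raise ValueError("need more than 2 records to sample the residual variance")
    sse = float(resid @ resid)
    sigma2e = sse / float(rng.chisquare(n - 2))

    k = int(np.asarray(delta).sum())
    used_fallback = k < _MIN_ACTIVE
    if used_fallback:
        ssa = float(alpha @ alpha)
        scale = ssa / k if k > 0 else anchor_sigma2a
        sigma2a = fallback_df * scale / float(rng.chisquare(fallback_df))
    else:
        ssa = float(alpha @ alpha)
        sigma2a = ssa / float(rng.chisquare(k - 2))
    return max(sigma2a, 1e-300), max(sigma2e, 1e-300), used_fallback


def compute_gebv(G, alpha_mean) -> np.ndarray:
    """Centered genomic values: gebv_j = sum_i (g_ij - mean_i) alpha_i.

    Columns are centered within the supplied matrix, so the returned vector
    is mean-zero over exactly the individuals given.
    """
    G = np.asarray(G, dtype=float)
    alpha_mean = np.asarray(alpha_mean, dtype=float).ravel()
    if G.ndim != 2 or G.shape[1] != alpha_mean.size:
        raise ValueError(
            f"dimension mismatch: G is {G.shape}, alpha has {alpha_mean.size} entries"
        )
    gebv = (G - G.mean(axis=0)) @ alpha_mean
    return gebv - gebv.mean()


def run_sampler(
    data: GsData,
    cfg: McmcConfig,
    *,
    update_indicators: bool = True,
    update_pi: bool = True,
    update_variances: bool = True,
    init: dict | None = None,
    keep_trace: bool = False,
) -> PosteriorSummary:
    """Run the Gibbs sampler and return posterior means.

    Deterministic given ``cfg.seed``.  ``update_*`` flags freeze parts of the
    state at their initial values (used by closed-form oracle checks, e.g.
    the ridge/BLUP limit with all indicators on and variances fixed).
    ``init`` may override initial ``pi``, ``sigma2a``, ``sigma2e``, ``delta``.

    With p = 0 SNPs the model reduces to the fixed-effect-only conjugate
    normal model.
    """
    rng = np.random.default_rng(cfg.seed)
    y, X = data.y, data.X
    n, q = X.shape
    p = data.G.shape[1]

    col_mean = data.G.mean(axis=0) if p else np.zeros(0)
    # p x n layout: each SNP's centered dosage vector is contiguous
    Gt = np.ascontiguousarray((data.G - col_mean).T)
    gtg = np.einsum("ij,ij->i", Gt, Gt) if p else np.zeros(0)
    mono = np.flatnonzero(gtg <= 1e-12)
    if mono.size:
        logger.warning("%d monomorphic SNP(s) carry no information; delta forced to 0", mono.size)

    init = dict(init or {})
    vary = float(np.var(y)) or 1.0
    pi = float(init.get("pi", 0.5))
    sigma2e = float(init.get("sigma2e", vary / 2.0))
    sigma2a = float(init.get("sigma2a", vary / (2.0 * max(p, 1) * 0.5)))
    anchor_sigma2a = sigma2a
    alpha = np.zeros(p)
    delta = np.asarray(init.get("delta", np.zeros(p)), dtype=bool).copy()
    if delta.size != p:
        raise ValueError("init delta has wrong length")
    delta[mono] = False

    XtX = X.T @ X
    XtX_chol = np.linalg.cholesky(XtX)
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ b

    asum = np.zeros(p)
    dsum = np.zeros(p)
    bsum = np.zeros(q)
    pi_sum = s2a_sum = s2e_sum = 0.0
    kept = 0
    n_fallback = 0
    trace = {"pi": [], "sigma2a": [], "sigma2e": [], "k": [], "b0": []} if keep_trace else None

    total = cfg.total_cycles
    exp_, log1p_, sqrt_ = math.exp, math.log1p, math.sqrt
    for cycle in range(total):
        if p:
            u = rng.random(p)
            z = rng.standard_normal(p)
            log_pi_odds = math.log(pi / (1.0 - pi))
            for i in range(p):
                gg = gtg[i]
                if gg <= 1e-12:
                    continue
                gi = Gt[i]
                a_old = alpha[i]
                rhs = float(gi @ r) + gg * a_old
                if update_indicators:
                    t1 = sigma2a * gg
                    lo = (
                        log_pi_odds
                        - 0.5 * log1p_(t1 / sigma2e)
                        + 0.5 * sigma2a * rhs * rhs / (sigma2e * (sigma2e + t1))
                    )
                    if lo >= 35:
                        d_new = True
                    elif lo <= -35:
                        d_new = False
                    else:
                        d_new = u[i] < 1.0 / (1.0 + exp_(-lo))
                else:
                    d_new = bool(delta[i])
                if d_new:
                    v = gg + sigma2e / sigma2a
                    a_new = rhs / v + sqrt_(sigma2e / v) * z[i]
                else:
                    a_new = 0.0
                if a_new != a_old:
                    r += (a_old - a_new) * gi
                alpha[i] = a_new
                delta[i] = d_new

        # fixed effects: flat prior, normal full conditional
        resid_b = r + X @ b
        mean_b = np.linalg.solve(XtX, X.T @ resid_b)
        zq = rng.standard_normal(q)
        b_new = mean_b + math.sqrt(sigma2e) * np.linalg.solve(XtX_chol.T, zq)
        r += X @ (b - b_new)
        b = b_new

        if update_variances:
            sigma2a, sigma2e, fb = sample_variances(
                rng, alpha, delta, r, anchor_sigma2a=anchor_sigma2a
            )
            n_fallback += int(fb)
        if update_pi and p:
            pi = sample_pi(rng, delta)

        if cycle >= cfg.burn_in and (cycle - cfg.burn_in) % cfg.thin == 0 and kept < cfg.n_samples:
            kept += 1
            asum += alpha
            dsum += delta
            bsum += b
            pi_sum += pi
            s2a_sum += sigma2a
            s2e_sum += sigma2e
            if keep_trace:
                trace["pi"].append(pi)
                trace["sigma2a"].append(sigma2a)
                trace["sigma2e"].append(sigma2e)
                trace["k"].append(int(delta.sum()))
                trace["b0"].append(float(b[0]))

    alpha_mean = asum / kept
    summary = PosteriorSummary(
        alpha_mean=alpha_mean,
        incl_prob=dsum / kept,
        pi_mean=pi_sum / kept,
        sigma2a_mean=s2a_sum / kept,
        sigma2e_mean=s2e_sum / kept,
        b_mean=bsum / kept,
        gebv=compute_gebv(data.G, alpha_mean) if p else np.zeros(n),
        n_kept=kept,
        monomorphic=mono,
        n_variance_fallbacks=n_fallback,
        trace={k: np.asarray(v) for k, v in trace.items()} if keep_trace else None,
    )
    return summary


class BayesCPi(RegressorMixin, BaseEstimator):
    """Scikit-learn style wrapper around the mixture-prior Gibbs sampler.

    ``fit(X, y)`` takes the dosage matrix as features; ``predict`` returns
    phenotype-scale predictions (intercept plus genomic value) and
    :meth:`genomic_values` returns centered GEBVs for any dosage matrix.

    Parameters mirror :class:`McmcConfig`; ``random_state`` seeds the chain.
    """

    def __init__(
        self,
        burn_in: int = 2000,
        n_samples: int = 600,
        thin: int = 5,
        random_state: int = 0,
    ):
        self.burn_in = burn_in
        self.n_samples = n_samples
        self.thin = thin
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        data = GsData(y=y, G=X)
        cfg = McmcConfig(
            burn_in=self.burn_in,
            n_samples=self.n_samples,
            thin=self.thin,
            seed=self.random_state,
        )
        self.summary_ = run_sampler(data, cfg)
        self.alpha_mean_ = self.summary_.alpha_mean
        self.incl_prob_ = self.summary_.incl_prob
        self.pi_ = self.summary_.pi_mean
        self.sigma2_alpha_ = self.summary_.sigma2a_mean
        self.sigma2_e_ = self.summary_.sigma2e_mean
        self.col_means_ = X.mean(axis=0)
        self.intercept_ = float(self.summary_.b_mean[0])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "alpha_mean_"):
            raise ValueError("BayesCPi is not fitted yet")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + (X - self.col_means_) @ self.alpha_mean_

    def genomic_values(self, X) -> np.ndarray:
        """Centered GEBVs for the individuals in ``X`` (mean zero over them)."""
        if not hasattr(self, "alpha_mean_"):
            raise ValueError("BayesCPi is not fitted yet")
        return compute_gebv(X, self.alpha_mean_)
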