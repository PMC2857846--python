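"""Two-step genomic evaluation of a longitudinal trait.

Step 1 condenses each phenotyped individual's time series into Gompertz
parameters (A, B, C) by nonlinear least squares.  Step 2 runs the
mixture-prior Gibbs sampler four times — on the fitted A, B and C values and
on the Gompertz-predicted trait at the target time (default t = 600, outside
the observed range) — and produces genomic breeding values for *all*
genotyped individuals, candidates included.

Two routes to a breeding value at the target time are compared:

* method I — evaluate the Gompertz function at each individual's
  population-mean-shifted parameter GEBVs and re-center;
* method II — take the GEBVs from the genomic analysis of the predicted
  target-time phenotypes directly.

Reporting helpers build the Pearson-lower / Spearman-upper correlation table,
rescale per-SNP effects relative to the largest within each analysis, and
score everything against simulated truth when available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth import FittedCurve, GompertzParams, fit_gompertz, gompertz_value
from .mcmc import GsData, McmcConfig, PosteriorSummary, compute_gebv, run_sampler
from .simulate import LongitudinalDataset, SimTruth, tbv_at

logger = logging.getLogger(__name__)

__all__ = [
    "TwoStepResult",
    "fit_training_curves",
    "run_two_step",
    "method_I_gebv",
    "correlation_table",
    "rescale_effects",
    "evaluate_against_truth",
]

ANALYSES = ("A", "B", "C", "t600")
_MIN_POSITIVE = 1e-6  # domain clip for mean-shifted A, B in method I


@dataclass
class TwoStepResult:
    """Everything the two-step pipeline produces for one dataset."""

    fitted: pd.DataFrame  # per-individual A, B, C, residual_ss, r_squared, converged
    posterior: dict  # analysis name -> PosteriorSummary
    gebv: pd.DataFrame  # index individual_id; gebv_A/B/C, gebv_t600_I, gebv_t600_II
    param_means: dict  # {"A": muA, "B": muB, "C": muC} over training fits
    correlation_matrix: pd.DataFrame  # Pearson lower / Spearman upper of the GEBVs
    rescaled_effects: pd.DataFrame  # per-SNP rescaled effect per analysis
    t_target: float
    n_fit_failures: int = 0
    n_domain_clipped: int = 0
    failures: dict = field(default_factory=dict)  # analysis -> error message

    @property
    def gebv_t600_I(self) -> np.ndarray:
        return self.gebv["gebv_t600_I"].to_numpy()

    @property
    def gebv_t600_II(self) -> np.ndarray:
        return self.gebv["gebv_t600_II"].to_numpy()


def fit_training_curves(dataset: LongitudinalDataset) -> tuple[pd.DataFrame, list]:
    """Fit a Gompertz curve per phenotyped individual.

    Returns the per-individual parameter table and the list of excluded
    individuals (non-converged or too few records); exclusions are logged.
    """
    rows, excluded = [], []
    fits: list[FittedCurve] = []
    by_id = dict(tuple(dataset.phenotypes.groupby("individual_id", sort=False)))
    for iid in dataset.training_ids:
        rec = by_id.get(iid)
        if rec is None or rec["time"].nunique() < 3:
            excluded.append(iid)
            continue
        rec = rec.sort_values("time")
        fit = fit_gompertz(
            rec["time"].to_numpy(), rec["yield"].to_numpy(), individual_id=iid
        )
        if not fit.converged:
            excluded.append(iid)
            continue
        fits.append(fit)
        rows.append(
            {
                "individual_id": iid,
                "A": fit.params.A,
                "B": fit.params.B,
                "C": fit.params.C,
                "residual_ss": fit.residual_ss,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    if excluded:
        logger.warning(
            "%d individual(s) excluded from genomic evaluation (failed or "
            "infeasible curve fits)",
            len(excluded),
        )
    return pd.DataFrame(rows), excluded


def method_I_gebv(
    posterior_A: PosteriorSummary,
    posterior_B: PosteriorSummary,
    posterior_C: PosteriorSummary,
    param_means: dict,
    t_target: float,
    gebv_A: np.ndarray | None = None,
    gebv_B: np.ndarray | None = None,
    gebv_C: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Breeding values at ``t_target`` from the parameter GEBVs (method I).

    Evaluates the Gompertz function at the population-mean-shifted parameter
    GEBVs for each individual and centers the result.  Individuals whose
    shifted A or B leaves the valid domain are evaluated at domain-clipped
    values; their count is returned.  GEBV vectors may be supplied directly
    (e.g. recomputed over all genotyped individuals); otherwise the posterior
    summaries' own GEBVs are used.
    """
    ga = posterior_A.gebv if gebv_A is None else np.asarray(gebv_A, float)
    gb = posterior_B.gebv if gebv_B is None else np.asarray(gebv_B, float)
    gc = posterior_C.gebv if gebv_C is None else np.asarray(gebv_C, float)
    if not (ga.size == gb.size == gc.size):
        raise ValueError("parameter GEBV vectors cover different individuals")
    a = param_means["A"] + ga
    b = param_means["B"] + gb
    c = param_means["C"] + gc
    clipped = int(np.sum((a <= 0) | (b <= 0)))
    if clipped:
        logger.warning("method I: %d individual(s) required domain clipping", clipped)
    a = np.maximum(a, _MIN_POSITIVE)
    b = np.maximum(b, _MIN_POSITIVE)
    z = np.clip(b * np.e * (c - t_target) / a, -50.0, 50.0)
    v = a * np.exp(-np.exp(z))
    return v - v.mean(), clipped


def correlation_table(vectors: dict) -> pd.DataFrame:
    """Square table with Pearson below and Spearman above the diagonal.

    Spearman uses average ranks for ties.  A zero-variance vector yields NaN
    entries (undefined, not silently zero).
    """
    names = list(vectors)
    arrs = {k: np.asarray(v, dtype=float).ravel() for k, v in vectors.items()}
    n = {a.size for a in arrs.values()}
    if len(n) != 1:
        raise ValueError("all vectors must have equal length")
    if n.pop() < 3:
        raise ValueError("need at least 3 observations for a correlation table")
    tab = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if j >= i:
                continue
            x, y = arrs[ni], arrs[nj]
            if x.std() == 0 or y.std() == 0:
                pear = spear = float("nan")
            else:
                pear = float(stats.pearsonr(x, y)[0])
                spear = float(stats.spearmanr(x, y)[0])
            tab.iloc[i, j] = pear  # lower triangle: Pearson
            tab.iloc[j, i] = spear  # upper triangle: Spearman
    return tab


def rescale_effects(alpha_mean) -> np.ndarray:
    """Effects rescaled so the largest absolute effect is 1 (signs kept).

    An all-zero vector is returned unchanged with a warning.
    """
    alpha = np.asarray(alpha_mean, dtype=float)
    amax = float(np.max(np.abs(alpha))) if alpha.size else 0.0
    if amax == 0.0:
        warnings.warn("all SNP effects are zero; nothing to rescale", stacklevel=2)
        return alpha.copy()
    return alpha / amax


def run_two_step(
    dataset: LongitudinalDataset,
    t_target: float = 600.0,
    mcmc: McmcConfig | None = None,
) -> TwoStepResult:
    """Run the complete two-step pipeline on one dataset.

    Four univariate genomic analyses are run on the training individuals'
    fitted A, B, C and Gompertz-predicted trait at ``t_target``; GEBVs are
    computed for every genotyped individual.  Deterministic given
    ``mcmc.seed`` (per-analysis chains use independent child seeds derived
    from it).  A failing analysis is recorded in ``result.failures`` and its
    GEBVs reported as NaN rather than aborting the rest.
    """
    mcmc = mcmc or McmcConfig.desk_scale()
    fitted, excluded = fit_training_curves(dataset)
    if fitted.empty:
        raise ValueError("no training individual produced a usable curve fit")

    train_ids = fitted["individual_id"]
    G_train = dataset.genotypes.loc[train_ids].to_numpy(dtype=float)
    G_all = dataset.genotypes.to_numpy(dtype=float)
    all_ids = dataset.genotypes.index

    pred_target = np.array(
        [
            gompertz_value(GompertzParams(r.A, r.B, r.C), t_target)
            for r in fitted.itertuples()
        ]
    )
    phenos = {
        "A": fitted["A"].to_numpy(),
        "B": fitted["B"].to_numpy(),
        "C": fitted["C"].to_numpy(),
        "t600": pred_target,
    }
    param_means = {k: float(fitted[k].mean()) for k in ("A", "B", "C")}

    child_seeds = np.random.SeedSequence(mcmc.seed).generate_state(len(ANALYSES)) % (2**31)
    posterior: dict[str, PosteriorSummary] = {}
    failures: dict[str, str] = {}
    gebv_all: dict[str, np.ndarray] = {}
    nan_vec = np.full(G_all.shape[0], np.nan)
    for name, seed in zip(ANALYSES, child_seeds):
        cfg = McmcConfig(
            burn_in=mcmc.burn_in, n_samples=mcmc.n_samples, thin=mcmc.thin, seed=int(seed)
        )
        try:
            summ = run_sampler(
                GsData(y=phenos[name], G=G_train, snp_map=dataset.snp_map), cfg
            )
            posterior[name] = summ
            gebv_all[name] = compute_gebv(G_all, summ.alpha_mean)
        except Exception as exc:  # record and continue with the other analyses
            logger.error("genomic analysis %r failed: %s", name, exc)
            failures[name] = str(exc)
            gebv_all[name] = nan_vec

    if {"A", "B", "C"} & failures.keys():
        gebv_I, clipped = nan_vec, 0
    else:
        gebv_I, clipped = method_I_gebv(
            posterior["A"],
            posterior["B"],
            posterior["C"],
            param_means,
            t_target,
            gebv_A=gebv_all["A"],
            gebv_B=gebv_all["B"],
            gebv_C=gebv_all["C"],
        )
    gebv_II = gebv_all["t600"]

    gebv = pd.DataFrame(
        {
            "set": dataset.pedigree.set_index("individual_id")["set"].reindex(all_ids),
            "gebv_A": gebv_all["A"],
            "gebv_B": gebv_all["B"],
            "gebv_C": gebv_all["C"],
            "gebv_t600_I": gebv_I,
            "gebv_t600_II": gebv_II,
        },
        index=all_ids,
    )

    vectors = {
        k: gebv[c].to_numpy()
        for k, c in [
            ("GEBV_A", "gebv_A"),
            ("GEBV_B", "gebv_B"),
            ("GEBV_C", "gebv_C"),
            ("GEBV_t600_I", "gebv_t600_I"),
            ("GEBV_t600_II", "gebv_t600_II"),
        ]
        if np.isfinite(gebv[c].to_numpy()).all()
    }
    corr = correlation_table(vectors) if len(vectors) >= 2 else pd.DataFrame()

    resc = {"snp_id": dataset.snp_map["snp_id"].to_numpy()}
    for name in ANALYSES:
        if name in posterior:
            alpha = posterior[name].alpha_mean
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                resc[f"effect_{name}"] = rescale_effects(alpha)
            resc[f"incl_prob_{name}"] = posterior[name].incl_prob
    rescaled = pd.DataFrame(resc)

    return TwoStepResult(
        fitted=fitted,
        posterior=posterior,
        gebv=gebv,
        param_means=param_means,
        correlation_matrix=corr,
        rescaled_effects=rescaled,
        t_target=t_target,
        n_fit_failures=len(excluded),
        n_domain_clipped=clipped,
        failures=failures,
    )


def evaluate_against_truth(
    result: TwoStepResult, truth: SimTruth, pedigree: pd.DataFrame | None = None
) -> dict:
    """Correlation tables of true vs. estimated breeding values.

    Returns ``{"overall": table, "training": table, "candidate": table}``;
    the split tables are produced when a pedigree with a ``set`` column is
    supplied.  Vectors are aligned on individual id; a mismatch between the
    result's and the truth's individuals is an error.
    """
    ids = result.gebv.index
    if not ids.isin(truth.tbv.index).all():
        raise ValueError("result and truth cover different individuals")
    tbv = truth.tbv.loc[ids]
    tbv_target = tbv_at(truth, result.t_target).loc[ids]

    def table_for(mask: np.ndarray) -> pd.DataFrame:
        sub = result.gebv.loc[mask]
        vectors = {
            f"TBV_t{result.t_target:g}": tbv_target.loc[mask].to_numpy(),
            "TBV_asym": tbv.loc[mask, "asym"].to_numpy(),
            "TBV_xmid": tbv.loc[mask, "xmid"].to_numpy(),
            "TBV_scal": tbv.loc[mask, "scal"].to_numpy(),
            "GEBV_t600_I": sub["gebv_t600_I"].to_numpy(),
            "GEBV_t600_II": sub["gebv_t600_II"].to_numpy(),
            "GEBV_A": sub["gebv_A"].to_numpy(),
            "GEBV_B": sub["gebv_B"].to_numpy(),
            "GEBV_C": sub["gebv_C"].to_numpy(),
        }
        return correlation_table(vectors)

    out = {"overall": table_for(np.ones(len(ids), dtype=bool))}
    if pedigree is not None and "set" in pedigree.columns:
        sets = pedigree.set_index("individual_id")["set"].reindex(ids)
        for name in ("training", "candidate"):
            mask = (sets == name).to_numpy()
            if mask.sum() >= 3:
                out[name] = table_for(mask)
    return out
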