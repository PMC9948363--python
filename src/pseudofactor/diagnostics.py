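"""Diagnostics for latent-variable pathologies in pseudo-bulk factor models.

Hidden factors inferred from raw single-cell pseudo-bulk matrices are prone to
spurious behavior: strong pairwise correlation among factors (which should be
close to independent), redundant near-duplicate factors, and a single factor
that swamps the decomposition. These pathologies intensify at small sample
sizes. This module quantifies them (pairwise Pearson correlations among the
leading factors, optionally alongside known covariates), raises named flags
with remediation hints, and runs the down-sampling experiment that exposes the
sample-size dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import CovariateTable, ValidationError, logger
from .latent import FactorSet, ard_fa, pca

__all__ = [
    "CorrelationReport",
    "DownsampleResult",
    "correlation_report",
    "flag_pathology",
    "downsample_experiment",
]


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations among leading factors (and covariates)."""

    pairwise_r: pd.DataFrame  # symmetric, diagonal 1
    mean_abs_offdiag: float  # over factor-factor pairs only
    redundant_pairs: list[tuple[str, str, float]]
    p_values: pd.DataFrame | None = None
    n_excluded_constant: int = 0


def correlation_report(
    fs: FactorSet,
    m: int = 10,
    covariates: CovariateTable | None = None,
    redundancy_threshold: float = 0.99,
    start: int = 1,
) -> CorrelationReport:
    """Correlations among ``m`` consecutive factor score vectors from ``start``.

    By default the first ``m`` factors. ``mean_abs_offdiag`` is the mean of
    |r| over the m(m-1)/2 factor pairs — the magnitude summary used to judge
    whether factors behave like the near-independent quantities they are
    meant to be. Covariate columns, if given, are appended to the correlation
    matrix but never enter the mean. Constant columns (correlation undefined)
    are excluded with a warning. Pairs with |r| >= ``redundancy_threshold``
    are reported as redundant. ``start=2`` with ``m=9`` summarizes factors
    2-10, the form used when the dominant first factor should be set aside.
    """
    if start < 1 or start - 1 + m > fs.K:
        raise ValidationError(f"factors {start}..{start - 1 + m} unavailable with K = {fs.K}")
    cols: dict[str, np.ndarray] = {f"factor_{k + 1}": fs.scores[:, k] for k in range(start - 1, start - 1 + m)}
    factor_names = list(cols)
    if covariates is not None:
        for c in covariates.table.columns:
            cols[str(c)] = covariates.table[c].to_numpy(dtype=float)
    df = pd.DataFrame(cols)
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        logger.warning("correlation_report: excluding %d constant columns: %s", len(const), const)
        df = df.drop(columns=const)
        factor_names = [f for f in factor_names if f not in const]
    n = len(df)
    corr = df.corr(method="pearson")

    fac = corr.loc[factor_names, factor_names].to_numpy()
    iu = np.triu_indices(len(factor_names), k=1)
    mean_abs = float(np.abs(fac[iu]).mean()) if iu[0].size else 0.0

    redundant = []
    names = list(corr.columns)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if names[i] in factor_names and names[j] in factor_names:
                r = corr.iloc[i, j]
                if abs(r) >= redundancy_threshold:
                    redundant.append((names[i], names[j], float(r)))

    # two-sided t-test p-values for the rendered report
    rmat = corr.to_numpy(copy=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rmat * np.sqrt((n - 2) / np.clip(1 - rmat**2, 1e-300, None))
        pvals = 2 * scipy.stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(pvals, np.nan)
    return CorrelationReport(
        pairwise_r=corr,
        mean_abs_offdiag=mean_abs,
        redundant_pairs=redundant,
        p_values=pd.DataFrame(pvals, index=corr.index, columns=corr.columns),
        n_excluded_constant=len(const),
    )


_RECOMMENDATIONS = {
    "REDUNDANT_FACTORS": "near-duplicate factors: re-run QC/transformation grid and reduce K",
    "HIGH_MEAN_CORR": "mean pairwise |r| among leading factors > threshold: re-run QC "
    "(filter high-pi0 genes, log1p + standardize) and check sample size",
    "DOMINANT_FIRST_FACTOR": "one factor holds most relevance: input likely unscaled or "
    "dominated by a few genes; standardize per gene",
}


def flag_pathology(
    report: CorrelationReport,
    profile: dict,
    mean_corr_threshold: float = 0.5,
) -> list[dict]:
    """Named pathology flags with remediation hints.

    HIGH_MEAN_CORR fires when the mean pairwise |r| among leading factors
    exceeds ``mean_corr_threshold`` (default 0.5, the level marking the
    pathological regime); REDUNDANT_FACTORS when any pair is near-duplicate;
    DOMINANT_FIRST_FACTOR comes from the factor-weight profile.
    """
    flags = []
    if report.redundant_pairs:
        flags.append({"flag": "REDUNDANT_FACTORS", "detail": report.redundant_pairs})
    if report.mean_abs_offdiag > mean_corr_threshold:
        flags.append({"flag": "HIGH_MEAN_CORR", "detail": report.mean_abs_offdiag})
    if profile.get("dominant_first_factor"):
        flags.append({"flag": "DOMINANT_FIRST_FACTOR", "detail": float(profile["shares"][0])})
    for f in flags:
        f["recommendation"] = _RECOMMENDATIONS[f["flag"]]
    return flags


@dataclass
class DownsampleResult:
    """Mean pairwise |r| among leading factors across down-sampling replicates."""

    n_target: int
    n_reps: int
    mean_abs_offdiag: np.ndarray  # one value per replicate
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_abs_offdiag = np.asarray(self.mean_abs_offdiag, dtype=float)
        self.summary = {
            "median": float(np.median(self.mean_abs_offdiag)),
            "min": float(self.mean_abs_offdiag.min()),
            "max": float(self.mean_abs_offdiag.max()),
        }


def downsample_experiment(
    matrix: np.ndarray,
    n_target: int,
    n_reps: int = 30,
    method: str = "ard_fa",
    K: int | None = None,
    m: int = 10,
    seed: int = 0,
    **factor_kwargs,
) -> DownsampleResult:
    """Re-infer factors on random subsets of individuals and score correlation.

    For each of ``n_reps`` replicates, ``n_target`` individuals are sampled
    without replacement, factors re-inferred (K defaults to min(50, n_target)),
    and the mean pairwise |r| among the first ``m`` factors recorded. The
    distribution over replicates shows how factor pathology grows as sample
    size shrinks. Seed-deterministic; replicates use independent draws.
    """
    X = np.asarray(matrix, dtype=float)
    N = X.shape[0]
    if n_target >= N:
        raise ValidationError(f"n_target = {n_target} must be < {N} individuals")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    K = K if K is not None else min(50, n_target)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_reps):
        idx = rng.choice(N, size=n_target, replace=False)
        sub = X[idx]
        if method == "pca":
            fs = pca(sub, K=min(K, n_target - 1, sub.shape[1]))
        elif method == "ard_fa":
            fs = ard_fa(sub, K=min(K, n_target), **factor_kwargs)
        else:
            raise ValidationError(f"unknown method {method!r}")
        rep = correlation_report(fs, m=min(m, fs.K))
        vals.append(rep.mean_abs_offdiag)
    return DownsampleResult(n_target=n_target, n_reps=n_reps, mean_abs_offdiag=np.asarray(vals))
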