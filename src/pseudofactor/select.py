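"""Choosing how many latent factors to fit in the eQTL model.

Four tools:

* :func:`sensitivity_scan` — re-run the cis-eQTL scan with 0..k_max factors as
  covariates and record the eGene count at each k (the power curve).
* :func:`local_greedy` — LOESS-smooth the per-increment percentage change in
  eGenes against k and pick the scanned k immediately before the smooth first
  turns negative. Rationale: once eGene discovery saturates, the percentage
  change scatters symmetrically around zero, so the first negative stretch of
  the smooth marks the point where extra factors stop paying for themselves.
* :func:`elbow` — scree-based automatic elbow: the factor index maximizing the
  perpendicular distance to the chord joining the first and last scree points.
* :func:`be_algorithm` — Buja–Eyuboglu parallel analysis: permute each gene
  column independently B times, compare the observed variance-explained scree
  against the permuted ones, and keep factors sequentially while the
  permutation p-value stays at or below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .eqtl import MapConfig, cis_pairs, fit_associations, local_fdr, call_egenes
from .io import ValidationError, logger

__all__ = [
    "SensitivityCurve",
    "SelectionResult",
    "sensitivity_scan",
    "local_greedy",
    "elbow",
    "be_algorithm",
    "compare_selectors",
]


@dataclass
class SensitivityCurve:
    """eGene counts as a function of the number of fitted factors."""

    k_values: np.ndarray  # increasing, starting at 0
    egene_counts: np.ndarray

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.egene_counts = np.asarray(self.egene_counts, dtype=int)
        if len(self.k_values) != len(self.egene_counts):
            raise ValidationError("k_values and egene_counts lengths differ")
        if (np.diff(self.k_values) <= 0).any():
            raise ValidationError("k_values must be strictly increasing")

    @property
    def pct_change(self) -> np.ndarray:
        """100 * (G_k - G_{k-1}) / G_{k-1} per increment; NaN where G_{k-1} = 0."""
        g = self.egene_counts.astype(float)
        prev = g[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = 100.0 * (g[1:] - prev) / prev
        pc[prev == 0] = np.nan
        return pc

    def to_frame(self) -> pd.DataFrame:
        pc = np.concatenate([[np.nan], self.pct_change])
        return pd.DataFrame({"k": self.k_values, "egenes": self.egene_counts, "pct_change": pc})


@dataclass
class SelectionResult:
    """Chosen number of factors plus method-specific diagnostics."""

    method: str  # local_greedy | elbow | be
    k_opt: int
    diagnostics: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def sensitivity_scan(
    tm,
    gt,
    cov,
    fs,
    ann=None,
    k_max: int = 50,
    k_step: int = 1,
    cfg: MapConfig = MapConfig(),
    pairs: pd.DataFrame | None = None,
) -> SensitivityCurve:
    """eGene count for each k in 0..k_max (step k_step) fitted factors.

    The (gene, SNP) pairing is computed once and reused across k; each k runs
    the full association + per-chromosome lfdr + eGene call path.
    """
    if k_max > fs.K:
        raise ValidationError(f"k_max = {k_max} exceeds available factors ({fs.K})")
    if pairs is None:
        if ann is None:
            raise ValidationError("need gene annotation (or precomputed pairs)")
        pairs = cis_pairs(ann, gt, cfg)
    ks = list(range(0, k_max + 1, k_step))
    counts = []
    for k in ks:
        assoc = fit_associations(tm, gt, cov, fs, k, pairs, cfg)
        assoc = local_fdr(assoc, cfg)
        eg = call_egenes(assoc, cfg)
        counts.append(int(eg["is_egene"].sum()) if len(eg) else 0)
    return SensitivityCurve(np.asarray(ks), np.asarray(counts))


def local_greedy(curve: SensitivityCurve, span: float = 0.75) -> SelectionResult:
    """LOESS the percentage-change series and stop just before it turns negative.

    The smooth is a tricube-weighted local linear fit (span = fraction of
    points in each window) evaluated at the scanned k values with defined
    percentage change. k_opt is the scanned k immediately before the first k
    whose fitted value is strictly negative (fitted values of exactly zero
    count as non-negative); if the smooth never goes negative the largest
    scanned k is returned with a NEVER_NEGATIVE warning.
    """
    pc = curve.pct_change
    ks = curve.k_values[1:]  # increment k-1 -> k is indexed by k
    ok = np.isfinite(pc)
    if ok.sum() < 4:
        raise ValidationError("local_greedy needs >= 4 increments with defined pct_change")
    x = ks[ok].astype(float)
    y = pc[ok]
    fitted = lowess(y, x, frac=span, it=0, return_sorted=False)
    neg = np.flatnonzero(fitted < 0)
    warnings = []
    if neg.size == 0:
        k_opt = int(curve.k_values[-1])
        warnings.append("NEVER_NEGATIVE")
    else:
        k_star = x[neg[0]]
        below = curve.k_values[curve.k_values < k_star]
        k_opt = int(below[-1]) if below.size else 0
    return SelectionResult(
        method="local_greedy",
        k_opt=k_opt,
        diagnostics={"k": x, "pct_change": y, "fitted": fitted, "span": span},
        warnings=warnings,
    )


def elbow(relevance: np.ndarray) -> SelectionResult:
    """Elbow of the scree curve by maximum perpendicular chord distance.

    The scree points (k, relevance_k), k = 1..K, are joined first-to-last by a
    chord; k_opt is the k maximizing the perpendicular distance to it. A scree
    indistinguishable from the chord (all distances ~ 0) yields a NO_ELBOW
    warning; a constant scree is an error.
    """
    r = np.asarray(relevance, dtype=float)
    K = len(r)
    if K < 3:
        raise ValidationError("elbow needs >= 3 factors")
    if np.allclose(r, r[0]):
        raise ValidationError("constant scree; elbow undefined")
    pts = np.column_stack([np.arange(1, K + 1, dtype=float), r])
    p0, p1 = pts[0], pts[-1]
    chord = p1 - p0
    norm = np.hypot(*chord)
    d = np.abs(chord[0] * (p0[1] - pts[:, 1]) - (p0[0] - pts[:, 0]) * chord[1]) / norm
    k_opt = int(np.argmax(d) + 1)
    warnings = [] if d.max() > 1e-12 else ["NO_ELBOW"]
    return SelectionResult(method="elbow", k_opt=k_opt, diagnostics={"distances": d}, warnings=warnings)


def be_algorithm(tm, B: int = 20, alpha: float = 0.05, seed: int = 0) -> SelectionResult:
    """Buja–Eyuboglu permutation parallel analysis for the number of components.

    For b = 1..B, each gene column is permuted independently across
    individuals and the variance-explained scree of the permuted matrix
    recorded. p_k = (1 + #{b : permuted_k >= observed_k}) / (B + 1); factors
    are kept sequentially while p_k <= alpha, and k_opt is the last kept index
    (0 if the first factor already fails). Seed-deterministic.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    X = tm.values if hasattr(tm, "values") and not isinstance(tm, np.ndarray) else np.asarray(tm, float)
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    if n < 3 or g < 2 or X.std(axis=0).sum() == 0:
        raise ValidationError("degenerate matrix for parallel analysis")
    n_comp = min(n - 1, g)
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    obs = (s**2) / (s**2).sum()
    obs = obs[:n_comp]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_comp)
    for _ in range(B):
        perm = np.empty_like(X)
        for j in range(g):
            perm[:, j] = X[rng.permutation(n), j]
        permc = perm - perm.mean(axis=0)
        sp_ = np.linalg.svd(permc, compute_uv=False)
        rel = (sp_**2) / (sp_**2).sum()
        exceed += rel[:n_comp] >= obs
    pvals = (1.0 + exceed) / (B + 1.0)
    k_opt = 0
    for k in range(n_comp):
        if pvals[k] <= alpha:
            k_opt = k + 1
        else:
            break
    return SelectionResult(
        method="be",
        k_opt=k_opt,
        diagnostics={"p_values": pvals, "observed_relevance": obs, "B": B, "alpha": alpha},
    )


def compare_selectors(curve: SensitivityCurve, results: list[SelectionResult]) -> pd.DataFrame:
    """Side-by-side comparison of selector choices on one sensitivity curve.

    For each method: k_opt, eGenes at k_opt, percentage of the maximum eGene
    count over the scan, and percentage of the maximum power gain over the
    k = 0 baseline that the choice retains. A k_opt outside the scanned grid
    snaps to the nearest scanned k with a warning.
    """
    g = curve.egene_counts.astype(float)
    g0 = g[0]
    gmax = g.max()
    rows = []
    for res in results:
        k = res.k_opt
        if k not in set(curve.k_values.tolist()):
            nearest = int(curve.k_values[np.argmin(np.abs(curve.k_values - k))])
            logger.warning("compare_selectors: k_opt=%d not scanned; using nearest k=%d", k, nearest)
            k = nearest
        gk = float(g[np.flatnonzero(curve.k_values == k)[0]])
        pct_max = 100.0 * gk / gmax if gmax > 0 else np.nan
        gain = gmax - g0
        pct_gain = 100.0 * (gk - g0) / gain if gain > 0 else np.nan
        rows.append(
            {
                "method": res.method,
                "k_opt": res.k_opt,
                "egenes_at_k_opt": int(gk),
                "pct_of_max_egenes": pct_max,
                "pct_of_max_gain_retained": pct_gain,
            }
        )
    return pd.DataFrame(rows)
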