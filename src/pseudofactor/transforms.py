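"""QC / transformation grid for pseudo-bulk matrices before factor inference.

Thirteen canonical options combine a zero-proportion filter (drop genes with
pi0 >= 0.9, or with pi0 = 1, or no filter), a per-gene log(x+1), per-gene
z-scoring (mean 0, sd 1), a rank-based inverse normal transformation (RINT,
Blom offset 3/8), and restriction to the top 2000 inter-individual HVGs:

====== ========== ====== ===== ====== ========
option pi0 filter log1p  STD   RINT   HVG2000
====== ========== ====== ===== ====== ========
1      none       .      .     .      .
2      = 1        .      .     .      .
3      >= 0.9     .      .     .      .
4      = 1        x      .     .      .
5      >= 0.9     x      .     .      .
6      = 1        .      x     .      .
7      >= 0.9     .      x     .      .
8      = 1        .      .     x      .
9      >= 0.9     .      .     x      .
10     = 1        x      x     .      .
11     >= 0.9     x      x     .      .
12     = 1        .      x     .      x
13     >= 0.9     .      x     .      x
====== ========== ====== ===== ====== ========

Application order is fixed:
pi0 filter, HVG restriction, log1p, then standardize or RINT, so that HVG
ranking always sees untransformed values. Standardize and RINT are mutually
exclusive within the grid; arbitrary combinations are only reachable by
constructing a custom :class:`TransformOption`.

Quantile normalization across individuals (each individual's vector mapped to
the mean order-statistic reference) is provided for the alternative
quantile-normalize + z-score preprocessing path; it is not part of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .io import ValidationError, logger
from .pseudobulk import PseudobulkMatrix, select_hvg

__all__ = [
    "TransformOption",
    "TransformedMatrix",
    "GRID",
    "get_option",
    "filter_pi0",
    "log1p_transform",
    "standardize",
    "rint",
    "quantile_normalize",
    "apply_option",
]


@dataclass(frozen=True)
class TransformOption:
    """One row of the QC/transformation grid."""

    option_id: int
    pi0_filter: str  # none | ge_0.9 | eq_1
    log1p: bool = False
    standardize: bool = False
    rint: bool = False
    hvg2000: bool = False

    def __post_init__(self) -> None:
        if self.pi0_filter not in {"none", "ge_0.9", "eq_1"}:
            raise ValidationError(f"unknown pi0 filter {self.pi0_filter!r}")
        if self.standardize and self.rint:
            raise ValidationError("standardize and rint are mutually exclusive")


GRID: dict[int, TransformOption] = {
    1: TransformOption(1, "none"),
    2: TransformOption(2, "eq_1"),
    3: TransformOption(3, "ge_0.9"),
    4: TransformOption(4, "eq_1", log1p=True),
    5: TransformOption(5, "ge_0.9", log1p=True),
    6: TransformOption(6, "eq_1", standardize=True),
    7: TransformOption(7, "ge_0.9", standardize=True),
    8: TransformOption(8, "eq_1", rint=True),
    9: TransformOption(9, "ge_0.9", rint=True),
    10: TransformOption(10, "eq_1", log1p=True, standardize=True),
    11: TransformOption(11, "ge_0.9", log1p=True, standardize=True),
    12: TransformOption(12, "eq_1", standardize=True, hvg2000=True),
    13: TransformOption(13, "ge_0.9", standardize=True, hvg2000=True),
}


def get_option(option_id: int) -> TransformOption:
    if option_id not in GRID:
        raise ValidationError(f"option_id must be 1-13, got {option_id}")
    return GRID[option_id]


@dataclass
class TransformedMatrix:
    """Individuals x genes after filtering/transformation."""

    values: np.ndarray
    individual_ids: np.ndarray
    gene_ids: np.ndarray
    applied: TransformOption | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("transformed matrix contains non-finite values")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def retained_genes(self) -> list[str]:
        return list(self.gene_ids)


def filter_pi0(pb: PseudobulkMatrix, stats, mode: str) -> PseudobulkMatrix:
    """Drop genes by zero-proportion: ge_0.9 removes pi0 >= 0.9, eq_1 removes pi0 = 1."""
    if mode == "none":
        return pb
    pi0 = np.asarray(stats.loc[pb.gene_ids, "pi0"], dtype=float)
    if mode == "ge_0.9":
        keep = pi0 < 0.9
    elif mode == "eq_1":
        keep = pi0 < 1.0
    else:
        raise ValidationError(f"unknown pi0 filter mode {mode!r}")
    return pb.subset_genes(keep)


def log1p_transform(m: np.ndarray) -> np.ndarray:
    """Elementwise natural log(x + 1); requires non-negative input."""
    m = np.asarray(m, dtype=float)
    if m.size and m.min() < 0:
        raise ValidationError("log1p requires non-negative values")
    return np.log1p(m)


def standardize(m: np.ndarray) -> np.ndarray:
    """Z-score each column to mean 0 and sample SD 1 (n-1 denominator).

    Constant columns cannot be standardized; callers drop them beforehand
    (apply_option does). An all-constant matrix is an error.
    """
    m = np.asarray(m, dtype=float)
    sd = m.std(axis=0, ddof=1)
    if (sd == 0).all():
        raise ValidationError("all columns constant; nothing to standardize")
    if (sd == 0).any():
        raise ValidationError("constant columns present; drop them before standardizing")
    return (m - m.mean(axis=0)) / sd


def rint(m: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform per column.

    value -> Phi^{-1}((rank - offset) / (n - 2*offset + 1)), with average ranks
    for ties and the Blom offset 3/8 by default (so the denominator is n + 1/4).
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if n < 2:
        raise ValidationError("rint requires >= 2 rows")
    ranks = scipy.stats.rankdata(m, axis=0, method="average")
    return scipy.stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


def quantile_normalize(m: np.ndarray) -> np.ndarray:
    """Quantile-normalize across individuals (rows).

    Each row's values are replaced by the reference distribution (the mean of
    order statistics across rows) at that row's ranks; after the transform
    every row has an identical sorted vector. Average ranks share the mean of
    the tied reference positions.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[0] < 2:
        raise ValidationError("quantile normalization requires >= 2 individuals")
    reference = np.sort(m, axis=1).mean(axis=0)
    ranks = scipy.stats.rankdata(m, axis=1, method="average")  # 1-based, may be half-integers
    lo = np.floor(ranks).astype(int) - 1
    hi = np.ceil(ranks).astype(int) - 1
    return (reference[lo] + reference[hi]) / 2.0


def apply_option(pb: PseudobulkMatrix, stats, opt: TransformOption | int) -> TransformedMatrix:
    """Apply one grid option: pi0 filter -> HVG2000 -> log1p -> STD or RINT.

    Genes constant across individuals that survive the filters are dropped with
    a warning before standardize/RINT (they cannot be scaled).
    """
    if isinstance(opt, int):
        opt = get_option(opt)
    cur = filter_pi0(pb, stats, opt.pi0_filter)
    if opt.hvg2000:
        hvgs = select_hvg(pb, stats, top_n=2000)
        hvgs = [g for g in hvgs if g in set(cur.gene_ids)]
        cur = cur.subset_genes(hvgs)
    values = cur.values
    if opt.log1p:
        values = log1p_transform(values)
    gene_ids = cur.gene_ids
    if opt.standardize or opt.rint:
        sd = values.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            logger.warning("apply_option: dropping %d constant genes before scaling", int(const.sum()))
            values = values[:, ~const]
            gene_ids = gene_ids[~const]
        if values.shape[1] == 0:
            raise ValidationError("no genes left to scale")
        values = standardize(values) if opt.standardize else rint(values)
    return TransformedMatrix(values, cur.individual_ids, gene_ids, applied=opt)
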