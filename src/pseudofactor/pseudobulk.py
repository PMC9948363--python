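"""Pseudo-bulk aggregation and per-gene QC statistics.

Pseudo-bulk expression for an individual is the arithmetic mean of raw counts
over that individual's cells (of the requested cell type). Per-gene QC
statistics are computed across individuals on the pseudo-bulk scale:

* ``pi0`` — proportion of individuals with exactly zero pseudo-bulk expression,
* ``mean`` / ``variance`` — inter-individual mean and unbiased (n-1) variance,
* ``fano`` — variance-to-mean ratio (Fano factor),
* ``skewness`` — Pearson's moment coefficient, m3 / m2^{3/2} with population
  (denominator n) central moments.

Highly variable genes (HVGs) are ranked by Fano factor on the *untransformed*
pseudo-bulk after pre-excluding near-silent genes (pi0 > 0.9 or mean < 0.001).
Note these are inter-individual HVGs, not the cell-level HVGs of single-cell QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellMatrix, ValidationError, logger

__all__ = ["PseudobulkMatrix", "aggregate", "gene_stats", "select_hvg"]


@dataclass
class PseudobulkMatrix:
    """Individual x gene mean counts plus cells-per-individual."""

    values: np.ndarray  # individuals x genes
    individual_ids: np.ndarray
    gene_ids: np.ndarray
    cell_counts: np.ndarray  # cells per individual

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=str)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.cell_counts = np.asarray(self.cell_counts, dtype=np.int64)
        if not np.all(np.isfinite(self.values)) or (self.values.size and self.values.min() < 0):
            raise ValidationError("pseudo-bulk values must be finite and >= 0")
        if (self.cell_counts < 1).any():
            raise ValidationError("every retained individual needs >= 1 cell")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, mask_or_ids) -> "PseudobulkMatrix":
        if np.asarray(mask_or_ids).dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in mask_or_ids], dtype=int)
        return PseudobulkMatrix(self.values[:, idx], self.individual_ids, self.gene_ids[idx], self.cell_counts)

    def subset_individuals(self, ids) -> "PseudobulkMatrix":
        pos = {i: k for k, i in enumerate(self.individual_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return PseudobulkMatrix(self.values[idx], self.individual_ids[idx], self.gene_ids, self.cell_counts[idx])


def aggregate(cm: CellMatrix, cell_type: str = "all") -> PseudobulkMatrix:
    """Mean counts per individual per gene, over cells of ``cell_type``.

    ``cell_type="all"`` pools every cell. Individuals left with zero cells of
    the requested type are dropped with a warning. Permutation-invariant to
    cell order: output rows follow first-appearance order of individuals in
    the (possibly filtered) matrix.
    """
    if cell_type != "all":
        available = set(np.unique(cm.cell_type))
        if cell_type not in available:
            raise ValidationError(f"unknown cell type {cell_type!r}; available: {sorted(available)}")
        mask = cm.cell_type == cell_type
    else:
        mask = np.ones(cm.n_cells, dtype=bool)

    all_individuals = cm.individuals
    ind = cm.cell_to_individual[mask]
    counts = cm.counts[mask]
    kept, kept_idx = np.unique(ind, return_inverse=True)
    # re-order to first-appearance order among retained individuals
    order = [i for i in all_individuals if i in set(kept)]
    n_dropped = len(all_individuals) - len(order)
    if n_dropped:
        logger.warning("aggregate: dropping %d individuals with no cells of type %r", n_dropped, cell_type)
    if not order:
        raise ValidationError("no individuals retained after cell-type filtering")

    pos = {v: i for i, v in enumerate(kept)}
    rows = np.array([pos[i] for i in order], dtype=int)
    # group sums via sparse indicator
    indicator = np.zeros((len(kept), counts.shape[0]))
    indicator[kept_idx, np.arange(counts.shape[0])] = 1.0
    sums = indicator @ counts.toarray()
    n_cells = indicator.sum(axis=1)
    values = (sums / n_cells[:, None])[rows]
    return PseudobulkMatrix(values, np.asarray(order), cm.gene_ids, n_cells[rows].astype(int))


def gene_stats(pb: PseudobulkMatrix) -> pd.DataFrame:
    """Per-gene QC statistics across individuals.

    Returns a DataFrame indexed by gene with columns pi0, mean, variance, fano,
    skewness. Fano and skewness are NaN (undefined) for genes with zero mean or
    zero variance. Requires >= 3 individuals (skewness needs three points).
    """
    x = pb.values
    n = x.shape[0]
    if n < 3:
        raise ValidationError("gene_stats requires >= 3 individuals")
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    pi0 = (x == 0).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where((mean > 0) & (var > 0), var / np.where(mean > 0, mean, 1.0), np.nan)
        centered = x - mean
        m2 = (centered**2).mean(axis=0)
        m3 = (centered**3).mean(axis=0)
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, np.nan)
    return pd.DataFrame(
        {"pi0": pi0, "mean": mean, "variance": var, "fano": fano, "skewness": skew},
        index=pd.Index(pb.gene_ids, name="gene"),
    )


def select_hvg(
    pb: PseudobulkMatrix,
    stats: pd.DataFrame,
    top_n: int = 2000,
    pi0_exclude: float = 0.9,
    mean_exclude: float = 0.001,
) -> list[str]:
    """Top ``top_n`` highly variable genes by Fano factor.

    Genes with pi0 > ``pi0_exclude`` or mean < ``mean_exclude`` are pre-excluded;
    the remainder are ranked by Fano descending (undefined Fano ranks last; ties
    broken by gene id for determinism). The ranking uses the untransformed
    pseudo-bulk statistics.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    stats = stats.loc[pb.gene_ids]
    keep = ~((stats["pi0"] > pi0_exclude) | (stats["mean"] < mean_exclude))
    retained = stats[keep]
    if retained.empty:
        logger.warning("select_hvg: all genes excluded by pi0/mean filters")
        return []
    fano_key = retained["fano"].fillna(-np.inf)  # undefined ranks last
    order = sorted(retained.index, key=lambda g: (-fano_key[g], g))
    return list(order[:top_n])
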