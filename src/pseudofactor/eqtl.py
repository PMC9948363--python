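"""Covariate-adjusted cis-eQTL mapping with per-chromosome local FDR.

For every gene, SNPs within a symmetric cis window (default 1 Mb upstream or
downstream of the gene body, 1-based inclusive) and above a minor-allele
frequency floor (default 5%) are tested by ordinary least squares of
expression on dosage plus a covariate block (intercept, sex/age-style
covariates, genotype PCs, and the first k latent factors). Inference is exact
small-sample t with n - p degrees of freedom, p counting every design column.
The implementation residualizes expression and dosage on the covariate block
once and correlates the residuals (Frisch-Waugh-Lovell), which is
algebraically identical to per-pair OLS.

Local false discovery rates are estimated per chromosome: Storey's smoothed
pi0 (lambda grid 0.05..0.95, cubic smoother evaluated at the largest lambda),
a probit-scale kernel density estimate of the p-value distribution, lfdr(p) =
pi0 * phi(z) / f(z) with z = Phi^{-1}(p), clipped to [0, 1] and forced
monotone non-decreasing in p. A gene is an eGene when its smallest lfdr falls
strictly below the threshold (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CovariateTable, GeneAnnotation, GenotypeMatrix, ValidationError, logger
from .latent import FactorSet
from .transforms import TransformedMatrix

__all__ = ["MapConfig", "cis_pairs", "fit_associations", "local_fdr", "call_egenes", "map_cis"]

_TINY = np.finfo(float).tiny  # smallest positive normal float; p-value floor


@dataclass(frozen=True)
class MapConfig:
    """Cis-eQTL mapping settings."""

    cis_window: int = 1_000_000
    maf_min: float = 0.05
    lfdr_threshold: float = 0.05
    min_group_size: int = 100  # chromosomes with fewer p-values fall back to pooled lfdr

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValidationError("cis_window must be > 0")
        if not (0 < self.maf_min < 0.5):
            raise ValidationError("maf_min must be in (0, 0.5)")


def cis_pairs(ann: GeneAnnotation, gt: GenotypeMatrix, cfg: MapConfig = MapConfig()) -> pd.DataFrame:
    """All testable (gene, SNP) pairs: same chromosome, within the cis window,
    MAF >= maf_min.

    A pair is included iff ``gene.start - w <= pos <= gene.end + w`` (1-based,
    inclusive on both boundaries). The MAF filter is applied genome-wide before
    pairing. Returns a DataFrame with columns gene, snp, chrom, pos, snp_idx,
    gene order following the annotation.
    """
    maf = gt.maf()
    snp_ok = maf >= cfg.maf_min
    rows = []
    snps = pd.DataFrame(
        {"snp": gt.snp_ids, "chrom": gt.chrom, "pos": gt.pos, "snp_idx": np.arange(gt.n_snps)}
    )[snp_ok]
    by_chrom = {c: g for c, g in snps.groupby("chrom", sort=False)}
    for gene, rec in ann.table.iterrows():
        grp = by_chrom.get(str(rec["chrom"]))
        if grp is None:
            continue
        lo = rec["start"] - cfg.cis_window
        hi = rec["end"] + cfg.cis_window
        hit = grp[(grp["pos"] >= lo) & (grp["pos"] <= hi)]
        for _, s in hit.iterrows():
            rows.append((gene, s["snp"], s["chrom"], s["pos"], s["snp_idx"]))
    if not rows:
        logger.warning("cis_pairs: no testable pairs")
        return pd.DataFrame(columns=["gene", "snp", "chrom", "pos", "snp_idx"])
    return pd.DataFrame(rows, columns=["gene", "snp", "chrom", "pos", "snp_idx"])


def _design_block(
    n: int,
    cov: CovariateTable | None,
    fs: FactorSet | None,
    k_factors: int,
) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if cov is not None:
        cols.append(cov.values())
    if k_factors:
        if fs is None or k_factors > fs.K:
            raise ValidationError("k_factors exceeds available factors")
        cols.append(fs.scores[:, :k_factors])
    Q = np.column_stack(cols)
    # drop exactly-zero columns (contract: adding a zero covariate changes nothing)
    nz = np.ptp(Q, axis=0) > 0
    nz[0] = True  # keep intercept
    Q = Q[:, nz]
    # collinearity check on column-normalized design so that heavily shrunk
    # (tiny-scale but independent) factor columns are not mistaken for rank loss
    norms = np.linalg.norm(Q, axis=0)
    if np.linalg.matrix_rank(Q / norms, tol=1e-8) < Q.shape[1]:
        names = ["intercept"]
        if cov is not None:
            names += list(cov.table.columns)
        names += [f"factor_{i + 1}" for i in range(k_factors)]
        raise ValidationError(f"rank-deficient covariate design (columns: {names})")
    return Q


def fit_associations(
    tm: TransformedMatrix,
    gt: GenotypeMatrix,
    cov: CovariateTable | None,
    fs: FactorSet | None,
    k_factors: int,
    pairs: pd.DataFrame,
    cfg: MapConfig = MapConfig(),
) -> pd.DataFrame:
    """OLS association per (gene, SNP) pair with the shared covariate block.

    Expression and dosage are residualized on the covariate block once per
    gene/SNP; beta, se, t and the two-sided p from t_{n-p} then match per-pair
    OLS exactly (Frisch-Waugh-Lovell). Perfect fits are reported with the t
    statistic capped at the largest finite float and p floored at the smallest
    positive normal number.
    """
    Y = tm.values
    n = Y.shape[0]
    if gt.n_individuals != n:
        raise ValidationError("genotype and expression individuals differ; intersect first")
    gene_pos = {g: i for i, g in enumerate(tm.gene_ids)}
    Q = _design_block(n, cov, fs, k_factors)
    p_cols = Q.shape[1] + 1  # + dosage
    df = n - p_cols
    if df <= 0:
        raise ValidationError(f"not enough individuals ({n}) for {p_cols} design columns")

    # residualize once via an orthonormal basis of the covariate block
    Qb, _ = np.linalg.qr(Q / np.linalg.norm(Q, axis=0))

    if pairs.empty:
        return pd.DataFrame(columns=["gene", "snp", "chrom", "pos", "beta", "se", "t", "p"])

    used_snps = np.unique(pairs["snp_idx"].to_numpy(dtype=int))
    snp_col = {s: i for i, s in enumerate(used_snps)}
    G = gt.dosages[:, used_snps]
    G_res = G - Qb @ (Qb.T @ G)
    used_genes = [g for g in dict.fromkeys(pairs["gene"]) if g in gene_pos]
    missing = set(pairs["gene"]) - set(used_genes)
    if missing:
        logger.debug("fit_associations: %d genes in pairs absent from expression; skipped", len(missing))
    Yg = Y[:, [gene_pos[g] for g in used_genes]]
    Y_res = Yg - Qb @ (Qb.T @ Yg)
    gene_col = {g: i for i, g in enumerate(used_genes)}

    sub = pairs[pairs["gene"].isin(gene_col)]
    gi = sub["gene"].map(gene_col).to_numpy(dtype=int)
    si = sub["snp_idx"].map(snp_col).to_numpy(dtype=int)
    gTg = (G_res**2).sum(axis=0)
    yTy = (Y_res**2).sum(axis=0)
    gTy = np.einsum("ij,ij->j", G_res[:, si], Y_res[:, gi])
    denom = gTg[si]
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gTy / denom
        rss = yTy[gi] - beta * gTy
        # numerically perfect fits (rss at rounding level) -> capped t, floored p
        perfect = rss <= yTy[gi] * 1e-12
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / denom)
        ok = (se > 0) & ~perfect
        t = np.where(ok, beta / np.where(ok, se, 1.0), np.sign(beta) * np.finfo(float).max)
    pvals = 2.0 * scipy.stats.t.sf(np.abs(t), df=df)
    pvals = np.clip(pvals, _TINY, 1.0)
    pvals[perfect] = _TINY
    res = pd.DataFrame(
        {
            "gene": sub["gene"].to_numpy(),
            "snp": sub["snp"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "t": t,
            "p": pvals,
        }
    )
    res = res[np.isfinite(res["beta"])]  # drop zero-variance dosage pairs
    n_dropped = len(sub) - len(res)
    if n_dropped:
        logger.warning("fit_associations: dropped %d pairs with zero residual dosage variance", n_dropped)
    return res.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Local false discovery rate
# ---------------------------------------------------------------------------

def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoothed estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the lambda grid
    0.05..0.95 (step 0.05); a cubic smoother is fit through the curve and
    evaluated at the largest lambda; the result is clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = len(p)
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def _lfdr_from_p(p: np.ndarray, kde_adjust: float = 1.5) -> np.ndarray:
    """Density-based lfdr for one group of p-values (probit-scale KDE)."""
    p = np.clip(np.asarray(p, dtype=float), _TINY, 1.0 - 1e-16)
    if len(np.unique(p)) < 2:
        raise ValidationError("local_fdr needs >= 2 distinct p-values")
    pi0 = storey_pi0(p)
    z = scipy.stats.norm.ppf(p)
    kde = scipy.stats.gaussian_kde(z)
    kde.set_bandwidth(kde.factor * kde_adjust)
    fz = np.clip(kde(z), 1e-300, None)
    lfdr = pi0 * scipy.stats.norm.pdf(z) / fz
    lfdr = np.clip(lfdr, 0.0, 1.0)
    # p-values in the pi0-estimation tail are null by construction; without
    # this, a degenerate pile-up of p near 1 would get spuriously low lfdr
    lfdr[p >= 0.95] = 1.0
    # isotonic in p: lfdr must be non-decreasing with increasing p
    order = np.argsort(p, kind="stable")
    lfdr[order] = np.maximum.accumulate(lfdr[order])
    return lfdr


def local_fdr(table: pd.DataFrame, cfg: MapConfig = MapConfig(), by_chrom: bool = True) -> pd.DataFrame:
    """Append an ``lfdr`` column, estimated within each chromosome.

    Chromosomes with fewer than ``cfg.min_group_size`` p-values fall back to a
    pooled estimate over all pairs (with a warning): density estimation is
    unstable in tiny groups.
    """
    if table.empty:
        out = table.copy()
        out["lfdr"] = np.array([], dtype=float)
        return out
    out = table.copy()
    p_all = out["p"].to_numpy(dtype=float)
    lfdr = np.full(len(out), np.nan)
    pooled_mask = np.zeros(len(out), dtype=bool)
    if by_chrom:
        for chrom, idx in out.groupby("chrom", sort=False).groups.items():
            idx = np.asarray(idx)
            if len(idx) >= cfg.min_group_size:
                lfdr[out.index.get_indexer(idx)] = _lfdr_from_p(p_all[out.index.get_indexer(idx)])
            else:
                pooled_mask[out.index.get_indexer(idx)] = True
        if pooled_mask.any():
            logger.warning(
                "local_fdr: %d pairs on small chromosomes use pooled estimation", int(pooled_mask.sum())
            )
    else:
        pooled_mask[:] = True
    if pooled_mask.any():
        lfdr[pooled_mask] = _lfdr_from_p(p_all)[pooled_mask] if pooled_mask.all() else _lfdr_from_p(p_all[pooled_mask])
    out["lfdr"] = lfdr
    return out


def call_egenes(table: pd.DataFrame, cfg: MapConfig = MapConfig()) -> pd.DataFrame:
    """Per-gene summary: eGene iff min lfdr over the gene's pairs is strictly
    below the threshold; n_significant counts pairs below it."""
    if table.empty:
        return pd.DataFrame(columns=["gene", "n_significant", "min_lfdr", "is_egene"])
    grp = table.groupby("gene", sort=True)
    min_lfdr = grp["lfdr"].min()
    n_sig = grp["lfdr"].apply(lambda s: int((s < cfg.lfdr_threshold).sum()))
    return pd.DataFrame(
        {
            "gene": min_lfdr.index,
            "n_significant": n_sig.values,
            "min_lfdr": min_lfdr.values,
            "is_egene": (min_lfdr < cfg.lfdr_threshold).values,
        }
    ).reset_index(drop=True)


def map_cis(
    tm: TransformedMatrix,
    gt: GenotypeMatrix,
    ann: GeneAnnotation,
    cov: CovariateTable | None = None,
    fs: FactorSet | None = None,
    k_factors: int = 0,
    cfg: MapConfig = MapConfig(),
    pairs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cis scan: pairing, association, lfdr, eGene calls.

    Returns (EqtlTable with lfdr, per-gene eGene table).
    """
    if pairs is None:
        pairs = cis_pairs(ann, gt, cfg)
    assoc = fit_associations(tm, gt, cov, fs, k_factors, pairs, cfg)
    assoc = local_fdr(assoc, cfg)
    return assoc, call_egenes(assoc, cfg)
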