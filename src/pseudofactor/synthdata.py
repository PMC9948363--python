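"""Population-scale single-cell simulator with the pathologies that break
latent-factor inference on pseudo-bulk matrices.

The generator produces a cell x gene count matrix, genotypes, covariates,
gene annotation and ground truth, with these deliberately planted features:

* **Sparsity** — per-gene structural-zero probabilities spanning
  ``zero_inflation_range`` plus a right-skewed baseline expression spectrum,
  giving a spread of pseudo-bulk zero-proportions pi0.
* **Right-skewed inter-individual expression** — individual-level means are
  log-normal-like (multiplicative latent/covariate effects on a log-normal
  baseline).
* **Intra-individual mean-variance dependency** — counts are point-Gamma:
  with probability z_g a structural zero, otherwise Poisson with a
  Gamma(shape_g) distributed rate, so variance grows with the mean.
* **Latent confounders** — ``n_latent_factors`` standard-normal per-individual
  scores act multiplicatively on all genes; ``confounder_strength`` is the
  fraction of log-scale inter-individual biological variance they carry.
* **Planted cis-eQTLs** — ``n_true_eqtl_genes`` genes receive a per-allele
  log-scale shift of ``eqtl_effect_size`` gene-SD units from a SNP placed
  inside the gene's cis window.

Genes sit on two synthetic chromosomes on a 1-based grid with 100 kb spacing
(gene body 10 kb), so cis-window arithmetic has exact expected answers. All
randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellMatrix, CovariateTable, GeneAnnotation, GenotypeMatrix, ValidationError
from .pseudobulk import aggregate, gene_stats

__all__ = ["SimConfig", "SimTruth", "simulate", "skew_and_sparsity_report"]

GENE_SPACING = 100_000
GENE_LENGTH = 10_000
FIRST_GENE_START = 1_000_000


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults give a desk-scale confounded cohort."""

    n_individuals: int = 100
    n_genes: int = 500
    n_cells_per_individual: float = 100.0  # Poisson mean
    n_latent_factors: int = 5
    n_snps: int = 1000
    n_true_eqtl_genes: int = 50
    eqtl_effect_size: float = 1.0  # per-allele shift in units of gene (log-scale) SD
    zero_inflation_range: tuple[float, float] = (0.0, 0.9)
    gamma_shape_range: tuple[float, float] = (0.3, 3.0)
    confounder_strength: float = 0.5  # fraction of log-scale biological variance
    maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0
    # shape of the baseline expression spectrum and fixed covariate effects
    baseline_log_mean: float = -1.2
    baseline_log_sd: float = 2.0
    bio_log_sd: float = 0.8  # total log-scale inter-individual biological SD
    sex_effect: float = 0.1
    age_effect: float = 0.005  # per year, around age 45

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_genes, self.n_snps, self.n_latent_factors) < 1:
            raise ValidationError("counts must be positive")
        if self.n_true_eqtl_genes > self.n_genes:
            raise ValidationError("more true eQTL genes than genes")
        if self.n_true_eqtl_genes > self.n_snps:
            raise ValidationError("more true eQTL genes than SNPs")
        for lo, hi in (self.zero_inflation_range, self.maf_range):
            if not (0 <= lo <= hi <= 1):
                raise ValidationError("probability ranges must satisfy 0 <= lo <= hi <= 1")
        if not (0 <= self.confounder_strength <= 1):
            raise ValidationError("confounder_strength must be in [0, 1]")


@dataclass
class SimTruth:
    """Everything the generator planted, for downstream recovery checks."""

    latent_scores: np.ndarray  # individuals x L
    latent_loadings: np.ndarray  # genes x L (log-scale)
    eqtl_pairs: pd.DataFrame  # gene, snp, beta (log-scale per-allele shift)
    gene_params: pd.DataFrame  # baseline, zero_inflation, gamma_shape per gene
    config: SimConfig


def _gene_layout(n_genes: int) -> pd.DataFrame:
    """Two chromosomes, 100 kb spacing, 10 kb gene bodies, 1-based."""
    half = (n_genes + 1) // 2
    chrom = np.where(np.arange(n_genes) < half, "1", "2")
    within = np.concatenate([np.arange(half), np.arange(n_genes - half)])
    start = FIRST_GENE_START + within * GENE_SPACING
    return pd.DataFrame(
        {"chrom": chrom, "start": start, "end": start + GENE_LENGTH - 1},
        index=pd.Index([f"gene_{i:04d}" for i in range(n_genes)], name="gene_id"),
    )


def simulate(config: SimConfig) -> tuple[CellMatrix, GenotypeMatrix, CovariateTable, GeneAnnotation, SimTruth]:
    """Draw one synthetic cohort. Deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    N, G, L = cfg.n_individuals, cfg.n_genes, cfg.n_latent_factors

    ann_df = _gene_layout(G)
    gene_ids = ann_df.index.to_numpy(dtype=str)
    individual_ids = np.array([f"ind_{i:04d}" for i in range(N)])

    # --- genotypes: eQTL SNPs inside their gene's cis window, rest uniform --
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    snp_ids = np.array([f"snp_{j:05d}" for j in range(cfg.n_snps)])
    eqtl_genes = rng.choice(G, size=cfg.n_true_eqtl_genes, replace=False)
    snp_chrom = np.empty(cfg.n_snps, dtype=object)
    snp_pos = np.empty(cfg.n_snps, dtype=np.int64)
    for j, gi in enumerate(eqtl_genes):
        rec = ann_df.iloc[gi]
        lo = max(1, rec["start"] - 900_000)
        hi = rec["end"] + 900_000
        snp_chrom[j] = rec["chrom"]
        snp_pos[j] = rng.integers(lo, hi + 1)
    span_hi = int(ann_df["start"].max()) + 1_500_000
    for j in range(cfg.n_true_eqtl_genes, cfg.n_snps):
        snp_chrom[j] = rng.choice(["1", "2"])
        snp_pos[j] = rng.integers(1, span_hi)
    dosages = rng.binomial(2, mafs[None, :], size=(N, cfg.n_snps)).astype(float)
    gt = GenotypeMatrix(dosages, individual_ids, snp_ids, snp_chrom.astype(str), snp_pos)

    # --- covariates: sex, age, first six genotype PCs ----------------------
    sex = rng.integers(0, 2, size=N).astype(float)
    age = rng.uniform(20, 70, size=N)
    dc = dosages - dosages.mean(axis=0)
    U, s, _ = np.linalg.svd(dc, full_matrices=False)
    n_pc = min(6, len(s))
    gpcs = U[:, :n_pc] * s[:n_pc]
    cov_df = pd.DataFrame({"sex": sex, "age": age}, index=pd.Index(individual_ids, name="individual_id"))
    for k in range(n_pc):
        cov_df[f"genotype_pc{k + 1}"] = gpcs[:, k]
    cov = CovariateTable(cov_df)

    # --- per-gene parameters ------------------------------------------------
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=G))
    z_gene = rng.uniform(*cfg.zero_inflation_range, size=G)
    shape_gene = rng.uniform(*cfg.gamma_shape_range, size=G)

    # latent confounders: per-gene loading norm carries confounder_strength of
    # the log-scale biological variance; the rest is unshared individual noise
    scores = rng.standard_normal((N, L))
    raw = rng.standard_normal((G, L))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    loadings = raw * (np.sqrt(cfg.confounder_strength) * cfg.bio_log_sd)
    noise_sd = np.sqrt(1.0 - cfg.confounder_strength) * cfg.bio_log_sd

    # per-allele shift in units of the gene's total inter-individual SD on the
    # log scale: biological SD plus delta-method sampling noise of the
    # pseudo-bulk mean (finite cells, zero inflation, Gamma-Poisson counts)
    z_safe = np.clip(z_gene, 0.0, 0.99)
    sampling_var = (1.0 / baseline + 1.0 / shape_gene + z_safe) / (
        cfg.n_cells_per_individual * (1.0 - z_safe)
    )
    # cap at 3 log-units per allele: near-silent genes would otherwise demand
    # astronomically large shifts to move their (mostly sampling-noise) SD
    gene_log_sd = np.minimum(np.sqrt(cfg.bio_log_sd**2 + sampling_var), 3.0)
    beta_log = np.zeros(G)
    beta_log[eqtl_genes] = cfg.eqtl_effect_size * gene_log_sd[eqtl_genes]
    eqtl_dosage = dosages[:, : cfg.n_true_eqtl_genes]  # SNP j is the eQTL of eqtl_genes[j]
    eqtl_term = np.zeros((N, G))
    eqtl_term[:, eqtl_genes] = eqtl_dosage * beta_log[eqtl_genes][None, :]

    log_mu = (
        np.log(baseline)[None, :]
        + scores @ loadings.T
        + eqtl_term
        + cfg.sex_effect * sex[:, None]
        + cfg.age_effect * (age[:, None] - 45.0)
        + rng.normal(0.0, noise_sd, size=(N, G))
    )
    mu = np.exp(np.clip(log_mu, None, 25.0))  # individual x gene latent mean; clip guards overflow

    # --- cells: point-Gamma counts -----------------------------------------
    n_cells = np.maximum(1, rng.poisson(cfg.n_cells_per_individual, size=N))
    blocks, cell_ids, cell_ind = [], [], []
    for i in range(N):
        ci = int(n_cells[i])
        rate = rng.gamma(shape_gene[None, :], mu[i][None, :] / shape_gene[None, :], size=(ci, G))
        counts = rng.poisson(rate)
        zero_gate = rng.random((ci, G)) < z_gene[None, :]
        counts[zero_gate] = 0
        blocks.append(sp.csr_matrix(counts))
        cell_ids.extend(f"{individual_ids[i]}_cell{j:04d}" for j in range(ci))
        cell_ind.extend([individual_ids[i]] * ci)
    cm = CellMatrix(
        counts=sp.vstack(blocks, format="csr"),
        cell_ids=np.asarray(cell_ids),
        gene_ids=gene_ids,
        cell_to_individual=np.asarray(cell_ind),
        cell_type=np.asarray(["typeA"] * len(cell_ids)),
    )

    truth = SimTruth(
        latent_scores=scores,
        latent_loadings=loadings,
        eqtl_pairs=pd.DataFrame(
            {
                "gene": gene_ids[eqtl_genes],
                "snp": snp_ids[: cfg.n_true_eqtl_genes],
                "beta": beta_log[eqtl_genes],
            }
        ),
        gene_params=pd.DataFrame(
            {"baseline": baseline, "zero_inflation": z_gene, "gamma_shape": shape_gene},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        config=cfg,
    )
    return cm, gt, cov, GeneAnnotation(ann_df), truth


def skew_and_sparsity_report(cm: CellMatrix) -> pd.DataFrame:
    """Per-gene pi0, mean, variance, Fano and skewness of the pseudo-bulk.

    Convenience wrapper (aggregate over all cells, then per-gene stats) used to
    check that generated data shows the intended sparsity spectrum, skewness
    and mean-variance dependency.
    """
    return gene_stats(aggregate(cm, "all"))
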