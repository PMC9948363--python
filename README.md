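# pseudofactor

Latent-factor quality control and cis-eQTL mapping for single-cell pseudo-bulk
expression.

## The problem

Population-scale single-cell RNA-seq studies map expression quantitative trait
loci (eQTLs) on *pseudo-bulk* matrices: for each individual, counts are
averaged over that individual's cells, giving an individuals × genes matrix.
Hidden confounders (batch, ancestry, cell-state composition) are then absorbed
by fitting latent factors — PEER-style Bayesian factor analysis or principal
components — as covariates in the association model.

Pseudo-bulk matrices are not bulk RNA-seq, however. They are sparse (many
genes have zero expression in most individuals), strongly right-skewed across
individuals, and show a tight intra-individual mean–variance dependency. On
such input, latent-factor inference misbehaves: inferred factors become
strongly correlated with one another (pairwise Pearson |r| up to 1 — literal
duplicate factors), a single factor swamps the decomposition, and the
pathology worsens sharply at small sample sizes. Factors like these are
useless as covariates and can silently cost eQTL discovery power.

`pseudofactor` implements the full workflow for detecting and avoiding these
pathologies:

1. **Pseudo-bulk construction** — intra-individual mean counts per gene, with
   per-gene QC statistics: zero proportion π₀, inter-individual mean,
   variance, Fano factor (variance/mean), and Pearson's moment skewness
   m₃/m₂^{3/2}.
2. **A 13-option QC/transformation grid** combining π₀ filters (drop genes
   with π₀ ≥ 0.9 or π₀ = 1), log(x+1), per-gene z-scoring, rank-based inverse
   normal transformation (RINT, Blom offset: Φ⁻¹((rank − 3/8)/(n + 1/4))), and
   restriction to the top 2000 inter-individual highly variable genes ranked
   by Fano factor. Option #11 (π₀ ≥ 0.9 filter + log1p + standardize) is the
   recommended default.
3. **Latent factor inference** — PCA, and a variational Bayesian factor
   analysis with per-factor automatic-relevance-determination (ARD) priors:
   Y ≈ SWᵀ + CBᵀ + E with w_gk ~ N(0, α_k⁻¹), α_k ~ Gamma(a₀, b₀), per-gene
   Gaussian noise, optional unpenalized known covariates C, and a provably
   non-decreasing evidence lower bound. Factor relevance is 1/E[α_k].
4. **Diagnostics** — pairwise factor correlation reports, named pathology
   flags (`HIGH_MEAN_CORR`, `REDUNDANT_FACTORS`, `DOMINANT_FIRST_FACTOR`), and
   a down-sampling experiment quantifying how factor correlation inflates as
   the cohort shrinks.
5. **cis-eQTL mapping** — OLS of expression on SNP dosage plus covariates
   (sex, age, genotype PCs, the first k factors), cis window ±1 Mb around the
   gene body, MAF ≥ 5%, exact t inference with n − p degrees of freedom, and
   per-chromosome local false discovery rates (Storey's smoothed π₀ estimate
   plus a probit-scale density estimate, isotonically monotonized). A gene is
   an *eGene* if any of its cis SNPs reaches LFDR < 0.05.
6. **Choosing the number of factors** — an eGene sensitivity scan over
   k = 0..K, the *local greedy* rule (LOESS-smooth the per-increment
   percentage change in eGene count against k and stop just before the smooth
   turns negative), automatic elbow detection on the scree, and the
   Buja–Eyuboglu permutation parallel analysis (B = 20, α = 0.05).

A fully seeded synthetic-data generator (`pseudofactor.simulate`) produces
cohorts with all the pathologies above — point-Gamma counts with structural
zeros, log-normal baselines spanning silent to abundant genes, multiplicative
latent confounders, and planted cis-eQTLs with known effect sizes — so every
claim the package makes is testable without any external data.

## Worked example

```python
import pseudofactor as pf

cfg = pf.SimConfig(n_individuals=100, n_genes=300, n_cells_per_individual=50,
                   n_snps=600, n_true_eqtl_genes=40, confounder_strength=0.6, seed=1)
cm, gt, cov, ann, truth = pf.simulate(cfg)

pb = pf.aggregate(cm, "all")                 # individuals x genes mean counts
stats = pf.gene_stats(pb)                    # pi0, mean, variance, fano, skewness
tm = pf.apply_option(pb, stats, 11)          # pi0 filter + log1p + standardize
fs = pf.ard_fa(tm, K=15)                     # ARD factor analysis
rep = pf.correlation_report(fs, m=10)

curve = pf.sensitivity_scan(tm, gt, cov, fs, ann=ann, k_max=10)
res = pf.local_greedy(curve)
table, egenes = pf.map_cis(tm, gt, ann, cov, fs, k_factors=res.k_opt)
```

Output of the run above:

```
pseudo-bulk: 100 individuals x 300 genes, median skewness 2.29
option #11 retained 297 genes
ARD-FA converged in 89 sweeps; mean |r| among first 10 factors = 0.012
eGenes for k = 0..10 factors: [35, 35, 38, 40, 39, 39, 40, 39, 39, 38, 38]
local greedy selects k = 5
39 eGenes at LFDR < 0.05 with 5 factors
```

Reading the numbers: after option #11 QC the inferred factors are essentially
uncorrelated (mean |r| = 0.012 — healthy; the `HIGH_MEAN_CORR` flag fires
above 0.5). The eGene count rises from 35 with no factors to ~40, saturates
around k = 3–6, and drifts down as overfitting sets in; the local greedy rule
stops at k = 5 — matching the 5 confounders the generator actually planted —
and keeps 39 of the planted 40 eGene signals. Running `ard_fa` on the *raw*
pseudo-bulk of a sparse cohort instead reproduces the pathology: at N = 30
the mean pairwise |r| among factors 2–10 reaches 0.8–1.0 and the diagnostics
flag it.

The same pipeline is scriptable from the shell:

```bash
pseudofactor simulate --config sim.yaml --out sim/
pseudofactor pseudobulk --counts sim/counts --metadata sim/counts/cell_metadata.tsv --out run/
pseudofactor transform --pseudobulk run/pseudobulk.tsv --option 11 --out run/
pseudofactor factors --transformed run/transformed.tsv --method ard_fa --k 15 --out run/
pseudofactor diagnose --factors run/ --out run/
pseudofactor map-eqtl --transformed run/transformed.tsv --genotypes sim/dosages.tsv \
    --annotation sim/gene_annotation.tsv --covariates sim/covariates.tsv \
    --factors run/ --k 5 --out run/
pseudofactor scan  --transformed run/transformed.tsv --genotypes sim/dosages.tsv \
    --annotation sim/gene_annotation.tsv --covariates sim/covariates.tsv \
    --factors run/ --k-max 10 --out run/
pseudofactor select --method local_greedy --curve run/sensitivity_curve.tsv --out run/
```

All outputs are deterministic TSVs: re-running with the same seed and config
reproduces them byte for byte.

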