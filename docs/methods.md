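# Methods

This note documents the models and procedures implemented in `pseudofactor`,
the choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Pseudo-bulk and per-gene QC statistics

Pseudo-bulk expression for individual *i* and gene *g* is the arithmetic mean
of raw counts over *i*'s cells (optionally restricted to one cell type).
Individuals with no cells of the requested type are dropped with a warning.

Per-gene statistics are computed across individuals on the pseudo-bulk scale:

* π₀ — proportion of individuals with exactly zero pseudo-bulk expression;
* mean and variance — the variance uses the unbiased n−1 denominator;
* Fano factor — variance/mean, undefined (NaN) when mean or variance is zero;
* skewness — Pearson's moment coefficient m₃/m₂^{3/2} with population
  (denominator-n) central moments, i.e. no small-sample bias correction,
  since the moment coefficient itself is the quantity of interest; undefined
  for constant genes.

Highly variable genes (HVGs) are ranked by Fano factor on the *untransformed*
pseudo-bulk after pre-excluding genes with π₀ > 0.9 (strict) or mean < 0.001.
Ties are broken by gene id, and genes with undefined Fano rank last; both
rules exist purely for determinism. Note these inter-individual HVGs are a
different concept from the cell-level HVGs of single-cell preprocessing. The
HVG pre-exclusion threshold (π₀ > 0.9, strict) and the grid filter
(π₀ ≥ 0.9, inclusive) differ deliberately at the boundary: each code path
implements its own stated rule exactly.

## The transformation grid

Thirteen canonical options combine, in fixed order: π₀ filter → HVG2000
restriction → log(x+1) → per-gene z-scoring *or* RINT. The order guarantees
that HVG ranking always sees untransformed values. Within the grid,
standardization and RINT are mutually exclusive; free-form combinations are
possible only by constructing a `TransformOption` directly.

RINT maps each column through Φ⁻¹((rank − c)/(n − 2c + 1)) with the Blom
offset c = 3/8 (denominator n + 1/4) and average ranks for ties — the default
of the widely used RankNorm implementation. Constant genes that survive
filtering are dropped with a warning before any scaling step (they cannot be
scaled; the alternative — erroring out — would make option behavior depend on
unrelated genes).

Quantile normalization across individuals (each individual's vector replaced
by the mean order-statistic reference at its ranks, tied ranks averaging the
two neighboring reference values) is provided for the alternative
quantile-normalize + z-score preprocessing path; it is not part of the grid.

## ARD factor analysis

The factor model is linear-Gaussian:

    y_ig ~ N(c_iᵀ b_g + s_iᵀ w_g, τ_g⁻¹),   s_i ~ N(0, I_K)

with per-factor ARD priors w_gk ~ N(0, α_k⁻¹), α_k ~ Gamma(a₀, b₀), per-gene
noise precisions τ_g ~ Gamma(c₀, d₀), and an optional block of known
covariates (plus an optional mean column) whose effects carry a fixed broad
Gaussian prior (precision 10⁻⁶), i.e. effectively unpenalized. Hyperpriors
default to the standard uninformative a₀ = b₀ = c₀ = d₀ = 10⁻³; all are
arguments.

Inference is mean-field variational Bayes with closed-form coordinate
updates in the order q(W,B) → q(α) → q(S) → q(τ); the per-gene weight
covariances share one eigendecomposition per sweep (they differ only through
the scalar E[τ_g]), so a sweep costs O(NGD + D³) with D = K + covariates. The
full ELBO — including all entropy terms — is evaluated once per sweep and is
non-decreasing up to 10⁻⁸ relative slack; the test suite asserts this on
every fixture. Iteration stops at a relative ELBO change below `tol`
(default 10⁻⁵) or at `max_iter` (default 2000, with K defaulting to 50,
matching common practice for this analysis).

Choices worth flagging:

* **No mean term by default.** The reference factor-analysis tool fits no
  intercept unless asked; on raw (uncentered) input the factors themselves
  must then absorb the gene means. Since diagnosing raw-input behavior is the
  point of this package, the default matches (`include_mean=False`).
* **Deterministic initialization.** Scores initialize from the PCA of the
  input scaled to unit variance. Results are therefore reproducible without
  seed bookkeeping; the `seed` argument is accepted so `pca`/`ard_fa` can be
  called uniformly, and randomized initialization was found to converge to
  the same optima on all test fixtures anyway.
* **Relevance** is 1/E[α_k] — the prior variance ARD grants a factor's
  weights. Factors are reported in descending relevance with a deterministic
  sign convention (largest-|weight| entry positive). On pure-noise input ARD
  prunes everything (all relevances ≲ 10⁻² of the unit gene variance), but
  the ratios *among* pruned relevances are not uniform — the top sample
  eigenvalue direction is always least-shrunk — so dominance should be judged
  by `factor_weight_profile` (share > 0.9), not by comparing pruned factors
  to one another.
* PCA relevance is the fraction of total variance per component, computed
  from the SVD of the column-centered matrix; columns are centered, never
  rescaled.

## Diagnostics

`correlation_report` computes pairwise Pearson correlations among m
consecutive factor score vectors (default the first 10; `start=2, m=9` gives
factors 2–10 when the first factor is a known size/mean factor). The summary
statistic is the mean of |r| over factor pairs — a magnitude summary, since
both strong positive and strong negative correlation are pathological.
Constant score vectors (fully pruned factors) are excluded with a warning.
Known covariates can be appended to the matrix but never enter the factor
summary. Significance stars in the rendered report come from the two-sided
t test on r with n − 2 degrees of freedom.

`flag_pathology` raises `HIGH_MEAN_CORR` above mean |r| = 0.5 (the level
marking the pathological regime), `REDUNDANT_FACTORS` for any pair at
|r| ≥ 0.99 (near-duplicate factors; configurable), and
`DOMINANT_FIRST_FACTOR` when one factor holds > 0.9 of total relevance. The
remedy in every case is upstream: re-run the transformation grid, reduce K,
or collect more individuals — the package deliberately does not "fix"
factors automatically.

`downsample_experiment` re-infers factors on `n_reps` random subsets of
`n_target` individuals (independent draws from one seeded generator) and
returns the distribution of mean |r|; K defaults to min(50, n_target).

## cis-eQTL mapping

Testable pairs: SNP and gene on the same chromosome, SNP position within
gene start − w .. gene end + w (w = 1 Mb, 1-based inclusive at both edges —
the window anchors at the annotated gene body, not the TSS), and minor allele
frequency min(f, 1−f) ≥ 0.05 with f = mean(dosage)/2, applied genome-wide
before pairing.

Association per pair is OLS of expression on dosage plus the covariate block
(intercept, covariates, the first k factor scores). The implementation
residualizes expression and dosage on an orthonormal basis of the covariate
block once and correlates residuals (Frisch–Waugh–Lovell); the test suite
verifies equality with a per-pair normal-equations solver to 10⁻⁸. Degrees of
freedom are n − p with p counting every design column including the dosage.
Exactly-zero covariate columns are dropped (they cannot affect the fit);
genuine collinearity is an error naming the columns. Numerically perfect fits
report the t statistic capped at the largest finite float and p floored at
the smallest positive normal double, so downstream log/probit transforms
never see zero.

Local FDR is estimated within each chromosome (groups under 100 p-values
fall back to a pooled estimate — kernel density estimation is unstable in
tiny groups): Storey's π₀ from the λ grid 0.05..0.95 (step 0.05) with a
cubic polynomial smoother evaluated at λ = 0.95 and clipped to (0, 1]; the
p-value density via a Gaussian KDE on the probit scale (bandwidth factor
1.5); lfdr(p) = π₀·φ(z)/f̂(z) with z = Φ⁻¹(p), clipped to [0, 1]. Two
safeguards: p-values in the π₀-estimation tail (p ≥ 0.95) are assigned
lfdr = 1 (exact under a uniform null; prevents a degenerate pile-up of
p-values near 1 from receiving spuriously low lfdr), and lfdr is forced
monotone non-decreasing in p by a running-maximum pass in p-order. A gene is
an eGene when its minimum lfdr is strictly below 0.05.

## Choosing the number of factors

The sensitivity scan re-runs association + lfdr + eGene calling for each
k = 0..k_max (the gene–SNP pairing is computed once and reused) and records
the eGene count G_k and the percentage change 100·(G_k − G_{k−1})/G_{k−1}
(undefined when G_{k−1} = 0; such increments are skipped in the smooth).

* **Local greedy**: LOESS (tricube-weighted local linear, span 0.75,
  evaluated at the scanned k grid; span and grid configurable) of the
  percentage change against k; k_opt is the largest scanned k strictly below
  the first k whose fitted value is negative (fitted values of exactly zero
  count as non-negative). If the smooth never goes negative, the largest
  scanned k is returned with a `NEVER_NEGATIVE` warning. Rationale: once
  eGene discovery saturates, the percentage change scatters symmetrically
  around zero.
* **Elbow**: the scree index maximizing perpendicular distance to the chord
  joining the first and last scree points; a scree collinear with the chord
  warns `NO_ELBOW`. This is one of several "automatic elbow" conventions; it
  was chosen for having no tuning parameter.
* **Buja–Eyuboglu**: each gene column permuted independently across
  individuals, B = 20 replicates; p_k = (1 + #{permuted relevance_k ≥
  observed})/(B + 1); factors kept sequentially while p_k ≤ α = 0.05
  (classical sequential stopping at the first failure).

`compare_selectors` reports, per method, the eGene count at k_opt, the share
of the scan's maximum eGene count, and the share of the maximum power gain
over the k = 0 baseline retained.

## The synthetic-data generator

`simulate` draws, from a single seeded generator: SNP dosages
Binomial(2, f) with f uniform on `maf_range`; sex ~ Bernoulli(0.5) and age
~ U(20, 70) with small multiplicative effects; six genotype PCs (computed
from the simulated dosages) as covariates; per-gene log-normal baselines
(`baseline_log_mean`, `baseline_log_sd`); latent confounders as
standard-normal per-individual scores with unit-direction gene loadings
scaled so they carry a `confounder_strength` fraction of the log-scale
biological variance (`bio_log_sd`, default 0.8); and planted cis-eQTLs.
Individual-level means are exponential in the sum of these log-scale terms;
counts per cell are point-Gamma: a structural zero with probability z_g
(uniform on `zero_inflation_range`), otherwise Poisson with a
Gamma(shape_g)-distributed rate — integer counts with zero inflation and
mean–variance dependence. Genes occupy two synthetic chromosomes at 100 kb
spacing (10 kb bodies) so cis-window arithmetic has exact expected answers;
each planted eQTL SNP lies within its gene's window.

The planted effect size is "per-allele shift in units of gene SD": the
log-scale shift is `eqtl_effect_size` times the gene's *total* expected
log-SD — biological SD plus the delta-method sampling variance of the
pseudo-bulk mean given finite cells, zero inflation and Gamma-Poisson
counts — capped at 3 log-units (near-silent genes would otherwise demand
astronomically large shifts). Without the sampling-variance term the
realized effect in pseudo-bulk SD units falls well below its nominal value
for noisy genes.

Two default regimes are used throughout the tests:

* the **expressed-panel** default (`baseline_log_mean = −1.2`,
  `baseline_log_sd = 2.0`) — a moderately expressed gene panel where most
  genes are quantifiable; used for eQTL power and selector studies;
* the **sparse-transcriptome** configuration (`baseline_log_mean = −3.0`,
  strong confounding) — emulating an unfiltered single-cell pseudo-bulk in
  which a large block of genes is near-silent (π₀ near 1). This is the
  regime in which raw, untransformed input provokes the factor pathologies:
  at N = 30 the mean pairwise |r| among leading ARD factors reaches 0.8–1.0
  (duplicate factors), at N = 100 it is far lower, and option-#11 input
  stays near zero at either N.

What the generator does *not* emulate — library-size variation between
cells, doublets, ambient RNA, batch structure between sequencing runs, linkage
disequilibrium among SNPs, and realistic gene-length/GC effects. Passing
tests therefore establish that the methods behave as specified under the
modeled pathologies (sparsity, skew, mean–variance coupling, shared latent
structure), not that they are robust to every artifact of real single-cell
data.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full suite
and script each finish in minutes on one CPU: cohorts of 40–200 individuals,
100–1000 genes, 25–50 cells per individual, scans over k = 0..15 with up to
1000 SNPs, and 5 seeded replicates for stochastic properties. `ard_fa` is
typically given `max_iter` 120–500 in these runs; with `tol = 10⁻⁵` it
converges well before the cap (the 2000-iteration default is kept for
library use). Down-sampling experiments use 5 replicates rather than the
30 used in full-scale practice.

## Known limitations

* The ARD factor analysis is this package's own variational implementation;
  it reproduces the reference tool's model family and qualitative behavior,
  but not its exact hyperpriors or update schedule, so factor values are not
  numerically interchangeable with other implementations.
* Storey-π₀ smoothing uses a cubic polynomial rather than a smoothing
  spline; on the 19-point λ grid the two are practically indistinguishable.
* The local-FDR density estimate degrades below ~100 p-values per group;
  the pooled fallback handles small chromosomes.
* Cis windows anchor at gene bodies; TSS-anchored windows would need
  strand-aware annotation, which the plumbing carries but the pairing does
  not use.
* The sensitivity scan refits associations per k; the fixed-covariate
  residualization is shared, but for very large K·pairs workloads a
  dedicated incremental scheme would be faster.
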