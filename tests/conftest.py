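"""Shared fixtures: small simulated cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import pseudofactor as pf


@pytest.fixture(scope="session")
def small_cohort():
    """60 individuals x 200 genes, moderate confounding, planted eQTLs."""
    cfg = pf.SimConfig(
        n_individuals=60,
        n_genes=200,
        n_cells_per_individual=50,
        n_snps=300,
        n_true_eqtl_genes=20,
        eqtl_effect_size=1.0,
        seed=7,
    )
    return pf.simulate(cfg)


@pytest.fixture(scope="session")
def small_pseudobulk(small_cohort):
    cm, gt, cov, ann, truth = small_cohort
    pb = pf.aggregate(cm, "all")
    stats = pf.gene_stats(pb)
    return pb, stats


def sparse_cohort_config(seed: int, n_individuals: int = 100, n_genes: int = 600) -> pf.SimConfig:
    """PBMC-like sparse regime: many near-silent genes, strong confounding.

    This is the regime in which raw (untransformed) input provokes the
    latent-factor pathologies; used by the diagnostics and acceptance tests.
    """
    return pf.SimConfig(
        n_individuals=n_individuals,
        n_genes=n_genes,
        n_cells_per_individual=50,
        n_snps=100,
        n_true_eqtl_genes=20,
        confounder_strength=0.8,
        baseline_log_mean=-3.0,
        baseline_log_sd=2.0,
        seed=seed,
    )


def loess_oracle(x, y, span: float):
    """Independent tricube-weighted local-linear smoother (test oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = int(np.ceil(span * n))
    out = []
    for xi in x:
        d = np.abs(x - xi)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        w = np.ones(k) if dmax == 0 else np.clip(1 - (d[idx] / dmax) ** 3, 0, None) ** 3
        X = np.column_stack([np.ones(k), x[idx]])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y[idx]))
        out.append(beta[0] + beta[1] * xi)
    return np.asarray(out)
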