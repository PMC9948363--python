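r"""Latent factor inference: PCA and ARD-regularized Bayesian factor analysis.

The factor-analysis model is the PEER-style linear Gaussian model

.. math::

    y_{ig} \sim \mathcal N\!\left(c_i^\top b_g + s_i^\top w_g,\; \tau_g^{-1}\right)

with standard-normal latent scores :math:`s_i \in \mathbb R^K`, per-factor
automatic-relevance-determination (ARD) priors on the weights
(:math:`w_{gk} \sim \mathcal N(0, \alpha_k^{-1})`,
:math:`\alpha_k \sim \mathrm{Gamma}(a_0, b_0)`), per-gene Gamma-prior noise
precisions :math:`\tau_g`, and optional known covariates :math:`c_i` (plus an optional
mean term) whose effects :math:`b_g` carry a fixed broad Gaussian prior, i.e.
they are effectively unpenalized. By default no mean term is fitted, matching
the usual PEER invocation: on uncentered input the factors themselves must
absorb the gene means, which is part of the pathology this package
diagnoses. Inference is mean-field
variational Bayes with closed-form coordinate updates; the evidence lower
bound (ELBO) is non-decreasing across sweeps, which the implementation tracks
and tests rely on. Factor relevance is reported as
:math:`1/\mathbb E[\alpha_k]`, the prior variance ARD assigns to that factor's
weights: irrelevant factors are shrunk toward zero relevance.

PCA is provided as the non-Bayesian alternative: columns are centered (not
rescaled) and relevance is the fraction of total variance explained.

Both methods return a :class:`FactorSet` with factors ordered by descending
relevance and a deterministic sign convention (the largest-magnitude weight of
each factor is positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .io import CovariateTable, ValidationError, logger
from .transforms import TransformedMatrix

__all__ = ["FactorSet", "pca", "ard_fa", "factor_weight_profile"]


@dataclass
class FactorSet:
    """Latent factor scores, gene weights and per-factor relevance."""

    scores: np.ndarray  # individuals x K
    weights: np.ndarray  # genes x K
    relevance: np.ndarray  # K, >= 0, descending
    method: str  # pca | ard_fa
    K: int
    converged: bool = True
    n_iter: int = 0
    individual_ids: np.ndarray | None = None
    gene_ids: np.ndarray | None = None
    elbo_trace: np.ndarray | None = None
    covariate_effects: np.ndarray | None = None  # genes x P (intercept first)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.relevance = np.asarray(self.relevance, dtype=float)
        if self.scores.shape[1] != self.K or self.weights.shape[1] != self.K:
            raise ValidationError("scores/weights column count must equal K")
        if (self.relevance < 0).any():
            raise ValidationError("relevance must be >= 0")


def _as_matrix(tm) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    if isinstance(tm, TransformedMatrix):
        return tm.values, tm.individual_ids, tm.gene_ids
    return np.asarray(tm, dtype=float), None, None


def _sign_fix(scores: np.ndarray, weights: np.ndarray) -> None:
    """Flip each factor so its largest-|weight| element is positive (in place)."""
    for k in range(weights.shape[1]):
        col = weights[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            weights[:, k] *= -1.0
            scores[:, k] *= -1.0


def pca(tm, K: int) -> FactorSet:
    """Principal components of the column-centered matrix.

    Scores are PC scores (mutually orthogonal); relevance_k is the fraction of
    total variance carried by component k.
    """
    Y, ind_ids, gene_ids = _as_matrix(tm)
    n, g = Y.shape
    if not (1 <= K <= min(n - 1, g)):
        raise ValidationError(f"K must be in [1, min(n-1, genes)] = [1, {min(n - 1, g)}]")
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValidationError("zero-variance input")
    scores = U[:, :K] * s[:K]
    weights = Vt[:K].T
    relevance = (s[:K] ** 2) / total
    _sign_fix(scores, weights)
    return FactorSet(
        scores=scores, weights=weights, relevance=relevance, method="pca", K=K,
        individual_ids=ind_ids, gene_ids=gene_ids,
    )


def ard_fa(
    tm,
    K: int = 50,
    covariates: CovariateTable | np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-5,
    seed: int = 0,
    prior_shape: float = 1e-3,
    prior_rate: float = 1e-3,
    unpenalized_precision: float = 1e-6,
    include_mean: bool = False,
) -> FactorSet:
    """Variational Bayes factor analysis with per-factor ARD priors.

    Parameters mirror the usual PEER invocation: ``K`` hidden factors
    (default 50) learned jointly with unpenalized effects for any known
    covariates (and a mean term if ``include_mean``), for at most ``max_iter``
    sweeps (default 2000), stopping when the relative ELBO change drops below
    ``tol``. No mean term is fitted by default.

    Initialization is deterministic (PCA of the input), so results do not
    depend on ``seed``; the argument exists so that callers can treat the two
    factor methods uniformly.

    Returns a :class:`FactorSet` whose ``relevance`` is :math:`1/E[\\alpha_k]`
    and whose ``elbo_trace`` records the (non-decreasing) ELBO per sweep.
    """
    del seed  # deterministic initialization; see docstring
    Y, ind_ids, gene_ids = _as_matrix(tm)
    N, G = Y.shape
    if K > N:
        raise ValidationError(f"K = {K} exceeds the number of individuals ({N})")
    if K < 1:
        raise ValidationError("K must be >= 1")
    if float(Y.var(axis=0).sum()) == 0.0:
        raise ValidationError("zero-variance input")

    blocks = [np.ones((N, 1))] if include_mean else []
    if covariates is not None:
        Cx = covariates.values() if isinstance(covariates, CovariateTable) else np.asarray(covariates, float)
        if Cx.ndim == 1:
            Cx = Cx[:, None]
        if Cx.shape[0] != N:
            raise ValidationError("covariate rows must match individuals")
        blocks.append(Cx)
    C = np.column_stack(blocks) if blocks else np.empty((N, 0))
    P = C.shape[1]
    D = P + K
    a0, b0 = prior_shape, prior_rate
    c0, d0 = prior_shape, prior_rate
    lam0 = unpenalized_precision

    # --- deterministic initialization from PCA ------------------------------
    Yc = Y - Y.mean(axis=0)
    U0, s0, _ = np.linalg.svd(Yc, full_matrices=False)
    M = np.zeros((N, K))
    k0 = min(K, len(s0))
    with np.errstate(invalid="ignore", divide="ignore"):
        sc = U0[:, :k0] * s0[:k0]
        sd = sc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        M[:, :k0] = sc / sd  # unit-variance score init
    Sigma_S = np.eye(K) * 1e-3
    E_alpha = np.ones(K)
    gene_var = Y.var(axis=0, ddof=1)
    E_tau = 1.0 / np.clip(gene_var, 1e-6, None)
    a_hat = a0 + G / 2.0
    c_hat = c0 + N / 2.0
    b_hat = np.full(K, b0)
    d_hat = np.full(G, d0)
    Y2 = (Y**2).sum(axis=0)

    mu = np.zeros((D, G))
    elbos: list[float] = []
    converged = False
    n_iter = 0

    def _A_matrix() -> np.ndarray:
        Stil = np.column_stack([C, M])
        A = Stil.T @ Stil
        A[P:, P:] += N * Sigma_S
        return A

    for it in range(1, max_iter + 1):
        n_iter = it
        t = E_tau  # E[tau_g] used for this sweep's W and S updates

        # --- q(W~) per gene: Sigma_g = (t_g A + Dprior)^-1 ------------------
        A = _A_matrix()
        Dprior = np.concatenate([np.full(P, lam0), E_alpha])
        Dm12 = 1.0 / np.sqrt(Dprior)
        lam, Q = np.linalg.eigh(Dm12[:, None] * A * Dm12[None, :])
        lam = np.clip(lam, 0.0, None)
        Uw = Dm12[:, None] * Q  # Sigma_g = Uw diag(1/(t_g lam + 1)) Uw^T
        Stil = np.column_stack([C, M])
        R = Stil.T @ Y  # D x G
        inv_fac = 1.0 / (np.outer(lam, t) + 1.0)  # D x G
        mu = Uw @ ((Uw.T @ R) * (inv_fac * t[None, :]))
        tg_w = t.copy()  # record the tau used to parameterize Sigma_g
        csum = inv_fac.sum(axis=1)  # sum_g 1/(t_g lam_j + 1), per eigendirection

        # second-moment sums: Sk = sum_g E[w_gk^2] for latent k, and cov block
        SigW_sum = (Uw * csum[None, :]) @ Uw.T  # sum_g Sigma_g
        Ew2_sum = (mu**2).sum(axis=1) + np.diag(SigW_sum)

        # --- q(alpha) -------------------------------------------------------
        b_hat = b0 + 0.5 * Ew2_sum[P:]
        E_alpha = a_hat / b_hat
        E_log_alpha = digamma(a_hat) - np.log(b_hat)

        # --- q(S) -----------------------------------------------------------
        s_t = (inv_fac * t[None, :]).sum(axis=1)  # sum_g t_g/(t_g lam_j + 1)
        SigW_t = (Uw * s_t[None, :]) @ Uw.T  # sum_g t_g Sigma_g
        W2 = (mu * t[None, :]) @ mu.T + SigW_t  # sum_g t_g E[w~ w~^T], D x D
        Sigma_S = np.linalg.inv(np.eye(K) + W2[P:, P:])
        Sigma_S = (Sigma_S + Sigma_S.T) / 2.0
        M = (Y @ (mu[P:] * t[None, :]).T - C @ W2[P:, :P].T) @ Sigma_S

        # --- q(tau): expected residual with updated q(S) --------------------
        A = _A_matrix()
        Stil = np.column_stack([C, M])
        R = Stil.T @ Y
        aj = np.einsum("ji,jk,ki->i", Uw, A, Uw)  # u_j^T A u_j under new A
        quad = np.einsum("ig,ij,jg->g", mu, A, mu)
        tr_ASig = (1.0 / (np.outer(lam, tg_w) + 1.0) * aj[:, None]).sum(axis=0)
        resid = Y2 - 2.0 * (mu * R).sum(axis=0) + quad + tr_ASig
        resid = np.clip(resid, 1e-12, None)
        d_hat = d0 + 0.5 * resid
        E_tau = c_hat / d_hat
        E_log_tau = digamma(c_hat) - np.log(d_hat)

        # --- ELBO -----------------------------------------------------------
        ll = 0.5 * (N * (E_log_tau - np.log(2 * np.pi)) - E_tau * resid).sum()
        lpS = -0.5 * N * K * np.log(2 * np.pi) - 0.5 * ((M**2).sum() + N * np.trace(Sigma_S))
        sign, logdet_S = np.linalg.slogdet(Sigma_S)
        hS = 0.5 * N * (K * (1 + np.log(2 * np.pi)) + logdet_S)
        lpW = 0.5 * (G * (E_log_alpha - np.log(2 * np.pi)) - E_alpha * Ew2_sum[P:]).sum()
        lpW += 0.5 * (G * P * (np.log(lam0) - np.log(2 * np.pi)) - lam0 * Ew2_sum[:P].sum())
        # logdet Sigma_g = -sum(log Dprior) - sum_j log(t_g lam_j + 1)
        logdets = -np.log(Dprior).sum() - np.log(np.outer(lam, tg_w) + 1.0).sum(axis=0)
        hW = 0.5 * (D * (1 + np.log(2 * np.pi)) * G + logdets.sum())
        lp_alpha = (a0 * np.log(b0) - gammaln(a0) + (a0 - 1) * E_log_alpha - b0 * E_alpha).sum()
        h_alpha = (a_hat - np.log(b_hat) + gammaln(a_hat) + (1 - a_hat) * digamma(a_hat)).sum()
        lp_tau = (c0 * np.log(d0) - gammaln(c0) + (c0 - 1) * E_log_tau - d0 * E_tau).sum()
        h_tau = (c_hat - np.log(d_hat) + gammaln(c_hat) + (1 - c_hat) * digamma(c_hat)).sum()
        elbo = float(ll + lpS + hS + lpW + hW + lp_alpha + h_alpha + lp_tau + h_tau)
        elbos.append(elbo)

        if it > 1:
            delta = elbos[-1] - elbos[-2]
            if abs(delta) / (1.0 + abs(elbos[-1])) < tol:
                converged = True
                break

    relevance = b_hat / a_hat  # 1 / E[alpha_k]
    order = np.argsort(-relevance, kind="stable")
    scores = M[:, order]
    weights = mu[P:].T[:, order]
    relevance = relevance[order]
    _sign_fix(scores, weights)
    if not converged:
        logger.warning("ard_fa did not converge in %d iterations", max_iter)
    return FactorSet(
        scores=scores,
        weights=weights,
        relevance=relevance,
        method="ard_fa",
        K=K,
        converged=converged,
        n_iter=n_iter,
        individual_ids=ind_ids,
        gene_ids=gene_ids,
        elbo_trace=np.asarray(elbos),
        covariate_effects=mu[:P].T,
    )


def factor_weight_profile(fs: FactorSet, dominant_threshold: float = 0.9) -> dict:
    """Per-factor share of total relevance, with a dominant-first-factor flag.

    Mirrors the scree-style factor-weight diagnostic: a single factor holding
    more than ``dominant_threshold`` of total relevance marks the pathological
    regime where one component swamps the decomposition.
    """
    if fs.K < 1:
        raise ValidationError("need at least one factor")
    total = float(fs.relevance.sum())
    if total == 0:
        raise ValidationError("all-zero relevance; shares undefined")
    shares = fs.relevance / total
    return {
        "shares": shares,
        "dominant_first_factor": bool(shares[0] > dominant_threshold),
    }
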