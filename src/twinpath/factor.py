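"""Probabilistic factor analysis with observed covariates.

The model is Y = C B + X W^T + eps, with per-gene noise variances
(optionally shared across genes), unit-Gaussian latent factor scores X,
and an automatic relevance determination (ARD) prior on the weight
columns: w_gk ~ N(0, 1/alpha_k) with a Gamma(shape, rate) hyperprior on
each per-factor precision alpha_k, so uninformative factors are shrunk
toward zero. Covariates are unpenalized fixed effects.

Fitting is MAP expectation-maximization: the E-step integrates over X,
the M-step updates W (ridge per gene), the noise variances, the covariate
effects and the ARD precisions in turn. The penalized marginal
log-likelihood is recorded each iteration and is non-decreasing.
Initialization is deterministic (top-K singular vectors of the
covariate-adjusted matrix), so a fit is reproducible without a seed.

After fitting, factor scores are standardized to unit variance (weights
absorb the scale) and each factor's sign is fixed so its largest-|weight|
gene loads positively.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

_PSI_FLOOR_REL = 1e-12
# cap on ARD precisions; an irrelevant factor is frozen once its weight
# norm is negligible (its score direction, a leading residual-variation
# direction, then stays representable instead of collapsing to zero)
_ALPHA_CAP = 1e4
_SCORE_SD_FLOOR = 1e-12


@dataclasses.dataclass
class FactorFit:
    """Result of :func:`fit_factor_model`."""

    k: int
    weights: np.ndarray  # genes x K
    scores: np.ndarray  # samples x K, unit variance per live factor
    covariate_effects: np.ndarray  # covariates x genes
    covariates: np.ndarray  # samples x covariates (design used in the fit)
    covariate_names: list[str]
    gene_noise_variances: np.ndarray
    ard_precisions: np.ndarray
    log_marginal_trace: np.ndarray
    variance_explained_total: float
    per_factor_variance: np.ndarray
    converged: bool
    n_iter: int
    sample_ids: list[str]
    gene_ids: list[str]


def _prepare_covariates(
    covariates: np.ndarray | None, n: int
) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValidationError("covariate design rows must match samples")
    return C, [f"cov{j}" for j in range(C.shape[1])]


def fit_factor_model(
    Y: ExpressionMatrix,
    covariates: np.ndarray | None = None,
    k: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
    ard: bool = True,
    shared_noise: bool = False,
    ard_shape: float = 1e-3,
    ard_rate: float = 1e-3,
) -> FactorFit:
    """Fit the covariate-adjusted Bayesian factor model with K factors.

    ``ard=False`` with ``shared_noise=True`` is the flat-prior
    configuration: probabilistic PCA, whose fitted score subspace matches
    the top-K left singular vectors of the covariate-adjusted matrix.
    ``k=0`` collapses the model to ordinary least-squares covariate
    adjustment.
    """
    values = Y.values
    n, G = values.shape
    C, cov_names = _prepare_covariates(covariates, n)
    q = C.shape[1]
    if k < 0:
        raise ValidationError("k must be >= 0")
    if k > min(n - q, G):
        raise ValidationError(
            f"k={k} exceeds feasible rank (n={n}, covariates={q}, genes={G})"
        )
    if n < k + q + 2:
        raise ValidationError(f"need at least k + covariates + 2 = {k + q + 2} samples")

    Cpinv = np.linalg.pinv(C)
    B = Cpinv @ values
    R = values - C @ B

    if k == 0:
        psi = np.maximum(R.var(axis=0), _PSI_FLOOR_REL)
        obj = float(
            -0.5 * n * (G * np.log(2 * np.pi) + np.sum(np.log(psi)))
            - 0.5 * np.sum(R**2 / psi)
        )
        return FactorFit(
            k=0,
            weights=np.zeros((G, 0)),
            scores=np.zeros((n, 0)),
            covariate_effects=B,
            covariates=C,
            covariate_names=cov_names,
            gene_noise_variances=psi,
            ard_precisions=np.zeros(0),
            log_marginal_trace=np.array([obj]),
            variance_explained_total=0.0,
            per_factor_variance=np.zeros(0),
            converged=True,
            n_iter=0,
            sample_ids=Y.sample_ids,
            gene_ids=Y.gene_ids,
        )

    # deterministic initialization from the truncated SVD of the adjusted data
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    W = (Vt[:k].T * S[:k]) / np.sqrt(n)
    X = np.sqrt(n) * U[:, :k]
    resid0 = R - X @ W.T
    scale = max(float(R.var()), 1e-12)
    psi_floor = _PSI_FLOOR_REL * scale
    psi = np.maximum(resid0.var(axis=0), psi_floor)
    if shared_noise:
        psi = np.full(G, max(float(psi.mean()), psi_floor))
    alpha = np.ones(k)
    # factors whose ARD precision saturates with negligible weight norm are
    # frozen (their coordinates stop updating): the MAP for an irrelevant
    # factor is exactly zero, but freezing keeps a representable score
    # direction and skipping a coordinate update preserves EM monotonicity
    frozen = np.zeros(k, dtype=bool)
    dead_norm2 = 1e-8 * G * scale

    trace: list[float] = []
    converged = False
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        Wp = W / psi[:, None]  # Psi^-1 W
        M = np.eye(k) + W.T @ Wp
        Minv = np.linalg.inv(M)
        t = R @ Wp  # n x K

        # penalized marginal log-likelihood at current parameters
        sign, logdetM = np.linalg.slogdet(M)
        quad = float(np.sum(R**2 / psi) - np.einsum("ik,kl,il->", t, Minv, t))
        obj = -0.5 * (n * (G * np.log(2 * np.pi) + np.sum(np.log(psi)) + logdetM) + quad)
        if ard:
            obj += float(
                np.sum(
                    (G / 2 + ard_shape - 1) * np.log(alpha)
                    - alpha * (0.5 * np.sum(W**2, axis=0) + ard_rate)
                )
            )
        trace.append(obj)
        if np.isfinite(prev) and abs(obj - prev) < tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = obj

        # E-step
        XE = t @ Minv
        Sxx = n * Minv + XE.T @ XE
        b = XE.T @ R  # K x G

        # M-step: weights (per-gene ridge when ARD precisions differ)
        W_old = W
        if ard:
            A = Sxx[None, :, :] + psi[:, None, None] * np.diag(alpha)[None, :, :]
            W = np.linalg.solve(A, b.T[:, :, None])[:, :, 0]
        else:
            W = np.linalg.solve(Sxx, b).T
        if frozen.any():
            W[:, frozen] = W_old[:, frozen]

        # M-step: noise variances
        rr = np.sum(R**2, axis=0)
        quad_w = np.einsum("gk,kl,gl->g", W, Sxx, W)
        psi = (rr - 2 * np.sum(W * b.T, axis=1) + quad_w) / n
        psi = np.maximum(psi, psi_floor)
        if shared_noise:
            psi = np.full(G, max(float(psi.mean()), psi_floor))

        # M-step: ARD precisions (MAP under the gamma hyperprior)
        if ard:
            alpha_new = (G + 2 * (ard_shape - 1)) / (np.sum(W**2, axis=0) + 2 * ard_rate)
            alpha_new = np.clip(alpha_new, 1e-10, _ALPHA_CAP)
            alpha_new[frozen] = alpha[frozen]
            alpha = alpha_new
            frozen |= np.sum(W**2, axis=0) < dead_norm2

        # M-step: covariate effects
        XE = (R @ (W / psi[:, None])) @ np.linalg.inv(np.eye(k) + (W / psi[:, None]).T @ W)
        B = Cpinv @ (values - XE @ W.T)
        R = values - C @ B

    if not converged:
        logger.warning("factor model did not converge in %d iterations", max_iter)

    # final posterior scores, standardization and sign convention
    Wp = W / psi[:, None]
    M = np.eye(k) + W.T @ Wp
    X = (R @ Wp) @ np.linalg.inv(M)
    sd = X.std(axis=0)
    live = sd > _SCORE_SD_FLOOR
    X[:, live] /= sd[live]
    W[:, live] *= sd[live]
    for j in range(k):
        if W[:, j].any():
            g_star = int(np.argmax(np.abs(W[:, j])))
            if W[g_star, j] < 0:
                W[:, j] *= -1
                X[:, j] *= -1

    Yadj = values - C @ B
    sstot = float(np.sum(Yadj**2))
    F = X @ W.T
    per_factor = np.empty(k)
    rest = 2 * Yadj - F
    for j in range(k):
        Fj = np.outer(X[:, j], W[:, j])
        per_factor[j] = float(np.sum(Fj * rest)) / sstot if sstot > 0 else 0.0
    total = float(per_factor.sum())

    return FactorFit(
        k=k,
        weights=W,
        scores=X,
        covariate_effects=B,
        covariates=C,
        covariate_names=cov_names,
        gene_noise_variances=psi,
        ard_precisions=alpha,
        log_marginal_trace=np.asarray(trace),
        variance_explained_total=min(max(total, 0.0), 1.0),
        per_factor_variance=per_factor,
        converged=converged,
        n_iter=it,
        sample_ids=Y.sample_ids,
        gene_ids=Y.gene_ids,
    )


def residualize(Y: ExpressionMatrix, fit: FactorFit) -> ExpressionMatrix:
    """Regress the fitted factor scores and covariates out of Y.

    The factors are treated as nuisance covariates: the returned residual
    is the exact least-squares residual of Y on [covariates, scores], so
    every residual gene vector is numerically orthogonal to every factor
    score and covariate column.
    """
    if fit.sample_ids != Y.sample_ids:
        raise ValidationError("fit and matrix sample rosters differ")
    design = np.hstack([fit.covariates, fit.scores])
    coef, *_ = np.linalg.lstsq(design, Y.values, rcond=None)
    resid = Y.values - design @ coef
    return ExpressionMatrix.from_arrays(resid, Y.sample_ids, Y.gene_ids)


def variance_explained(fit: FactorFit, Y: ExpressionMatrix) -> float:
    """Fraction of covariate-adjusted variance captured by the factors:
    1 - SS_residual / SS_total."""
    if fit.sample_ids != Y.sample_ids or fit.gene_ids != Y.gene_ids:
        raise ValidationError("fit and matrix dimensions differ")
    Yadj = Y.values - fit.covariates @ fit.covariate_effects
    sstot = float(np.sum(Yadj**2))
    if sstot <= 1e-20 * max(1.0, float(np.sum(Y.values**2))):
        raise ValidationError("zero total variance after covariate adjustment")
    ssres = float(np.sum((Yadj - fit.scores @ fit.weights.T) ** 2))
    return min(max(1.0 - ssres / sstot, 0.0), 1.0)
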