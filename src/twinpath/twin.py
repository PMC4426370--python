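"""Twin linear mixed model: ML fit, age LRT, and variance decomposition.

The model for a phenotype y measured on a cohort of MZ / DZ twin pairs
and singletons is

    y_ij = beta_0 + beta_age * age_ij + f_i + m_i * [MZ] + e_ij

with a pair-shared random effect f ~ N(0, sigma2_pair), an extra effect
m ~ N(0, sigma2_mz_extra) shared only by MZ co-twins, and iid residual
e ~ N(0, sigma2_resid). Implied covariances: cov(DZ pair) = sigma2_pair,
cov(MZ pair) = sigma2_pair + sigma2_mz_extra, so twice the extra MZ
covariance is the additive-genetic variance in the classical twin design.

Fitting maximizes the exact family-block Gaussian likelihood (ML, not
REML — the age test compares models differing in a fixed effect) by
profiling the fixed effects out with GLS and optimizing the three
variance parameters with a bounded quasi-Newton method, analytic
gradients, and three deterministic starts.

The variance decomposition divides total variance (age fixed-effect
variance + the three random components) into genetic, shared-environment,
unique-environment and age shares; negative implied shares are clipped at
zero and the four shares renormalized to sum to one, so every reported
proportion lies in [0, 1].
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .containers import DZ, MZ, TwinCohort, ValidationError

_SE_FLOOR_REL = 1e-8


class IdentifiabilityError(ValidationError):
    """The requested model is not identifiable on this cohort."""


@dataclasses.dataclass
class TwinFit:
    beta_0: float
    beta_age: float
    sigma2_pair: float
    sigma2_mz_extra: float
    sigma2_resid: float
    loglik: float
    converged: bool
    include_age: bool
    n_individuals: int
    n_families: int


@dataclasses.dataclass
class VarianceDecomposition:
    h2: float
    c2: float
    e2: float
    age_share_total: float
    age_share_env: float


@dataclasses.dataclass
class LRTResult:
    statistic: float
    p_value: float
    fit_full: TwinFit
    fit_null: TwinFit

    @property
    def converged(self) -> bool:
        return self.fit_full.converged and self.fit_null.converged


class CohortBlocks:
    """Family-block index structure; build once, reuse across phenotypes."""

    def __init__(self, cohort: TwinCohort) -> None:
        units = cohort.family_units()
        pos = {s: i for i, s in enumerate(cohort.sample_ids)}
        self.mz = np.array(
            [[pos[a], pos[b]] for a, b in units[MZ]], dtype=int
        ).reshape(-1, 2)
        self.dz = np.array(
            [[pos[a], pos[b]] for a, b in units[DZ]], dtype=int
        ).reshape(-1, 2)
        self.singles = np.array(
            [pos[u[0]] for u in units["singleton"]], dtype=int
        )
        self.ages = cohort.ages
        self.n = cohort.n_individuals
        self.n_families = len(units[MZ]) + len(units[DZ]) + len(units["singleton"])

    def design(self, include_age: bool) -> np.ndarray:
        if include_age:
            return np.column_stack([np.ones(self.n), self.ages])
        return np.ones((self.n, 1))


def _pair_ll_grad(
    d: np.ndarray, idx: np.ndarray, v: float, c: float
) -> tuple[float, float, float]:
    """Log-likelihood and d/dv, d/dc over pairs with common (v, c)."""
    if idx.size == 0:
        return 0.0, 0.0, 0.0
    d1, d2 = d[idx[:, 0]], d[idx[:, 1]]
    det = v * v - c * c
    m = idx.shape[0]
    quad = (v * (d1**2 + d2**2) - 2 * c * d1 * d2) / det
    ll = m * (-np.log(2 * np.pi) - 0.5 * np.log(det)) - 0.5 * float(np.sum(quad))
    e1 = (v * d1 - c * d2) / det
    e2 = (v * d2 - c * d1) / det
    dv = -m * v / det + 0.5 * float(np.sum(e1**2 + e2**2))
    dc = m * c / det + float(np.sum(e1 * e2))
    return ll, dv, dc


def _profile(
    theta: np.ndarray, blocks: CohortBlocks, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Profiled negative log-likelihood, its gradient, and the GLS betas."""
    sp, sm, se = theta
    v_mz, c_mz = sp + sm + se, sp + sm
    v_dz, c_dz = sp + se, sp
    v_s = sp + se

    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for idx, v, c in ((blocks.mz, v_mz, c_mz), (blocks.dz, v_dz, c_dz)):
        if idx.size == 0:
            continue
        det = v * v - c * c
        X1, X2 = X[idx[:, 0]], X[idx[:, 1]]
        y1, y2 = y[idx[:, 0]], y[idx[:, 1]]
        A += (v * (X1.T @ X1 + X2.T @ X2) - c * (X1.T @ X2 + X2.T @ X1)) / det
        b += (v * (X1.T @ y1 + X2.T @ y2) - c * (X1.T @ y2 + X2.T @ y1)) / det
    if blocks.singles.size:
        Xs, ys = X[blocks.singles], y[blocks.singles]
        A += Xs.T @ Xs / v_s
        b += Xs.T @ ys / v_s
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise IdentifiabilityError("singular fixed-effect design") from exc

    d = y - X @ beta
    ll = 0.0
    grad = np.zeros(3)  # d/d(sp, sm, se)
    llm, dv, dc = _pair_ll_grad(d, blocks.mz, v_mz, c_mz)
    ll += llm
    grad += np.array([dv + dc, dv + dc, dv])
    lld, dv, dc = _pair_ll_grad(d, blocks.dz, v_dz, c_dz)
    ll += lld
    grad += np.array([dv + dc, 0.0, dv])
    if blocks.singles.size:
        ds = d[blocks.singles]
        ll += float(
            np.sum(-0.5 * (np.log(2 * np.pi * v_s) + ds**2 / v_s))
        )
        g = float(np.sum(-0.5 / v_s + ds**2 / (2 * v_s**2)))
        grad += np.array([g, 0.0, g])
    return -ll, -grad, beta


def twin_loglik(
    phenotype: np.ndarray,
    cohort: TwinCohort,
    beta_0: float,
    beta_age: float,
    sigma2_pair: float,
    sigma2_mz_extra: float,
    sigma2_resid: float,
) -> float:
    """Exact Gaussian log-likelihood, computed family block by block."""
    y = np.asarray(phenotype, dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("phenotype contains non-finite values")
    if min(sigma2_pair, sigma2_mz_extra) < 0 or sigma2_resid <= 0:
        raise ValidationError("variance parameters out of range")
    blocks = CohortBlocks(cohort)
    d = y - beta_0 - beta_age * blocks.ages
    sp, sm, se = sigma2_pair, sigma2_mz_extra, sigma2_resid
    ll = 0.0
    ll += _pair_ll_grad(d, blocks.mz, sp + sm + se, sp + sm)[0]
    ll += _pair_ll_grad(d, blocks.dz, sp + se, sp)[0]
    if blocks.singles.size:
        v = sp + se
        ds = d[blocks.singles]
        ll += float(np.sum(-0.5 * (np.log(2 * np.pi * v) + ds**2 / v)))
    return ll


def _moment_start(blocks: CohortBlocks, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Method-of-moments start from OLS residual co-twin covariances."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    d = y - X @ beta
    s2 = float(d.var())
    cov_mz = (
        float(np.mean(d[blocks.mz[:, 0]] * d[blocks.mz[:, 1]]))
        if blocks.mz.size
        else 0.0
    )
    cov_dz = (
        float(np.mean(d[blocks.dz[:, 0]] * d[blocks.dz[:, 1]]))
        if blocks.dz.size
        else 0.0
    )
    sp = min(max(cov_dz, 0.0), s2)
    sm = min(max(cov_mz - cov_dz, 0.0), s2)
    se = max(s2 - sp - sm, 0.05 * s2)
    return np.array([sp, sm, se])


def fit_twin_model(
    phenotype: np.ndarray,
    cohort: TwinCohort,
    include_age: bool = True,
    blocks: CohortBlocks | None = None,
) -> TwinFit:
    """Maximum-likelihood fit of the twin mixed model.

    Variances are constrained non-negative (boundary estimates allowed).
    ``include_age=False`` forces beta_age = 0 (the null model of the age
    LRT). Deterministic: three fixed starts, best likelihood kept.
    """
    y = np.asarray(phenotype, dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("phenotype contains non-finite values")
    if blocks is None:
        blocks = CohortBlocks(cohort)
    if len(y) != blocks.n:
        raise ValidationError("phenotype length does not match cohort")
    s2 = float(y.var())
    if s2 <= 0:
        raise ValidationError("phenotype has zero variance")
    if include_age and np.ptp(blocks.ages) == 0:
        raise IdentifiabilityError("age effect unidentifiable: all ages equal")

    X = blocks.design(include_age)
    se_floor = _SE_FLOOR_REL * s2
    ub = 20.0 * s2
    bounds = [(0.0, ub), (0.0, ub), (se_floor, ub)]
    starts = [
        _moment_start(blocks, X, y),
        np.array([s2 / 3, s2 / 3, s2 / 3]),
        np.array([0.0, 0.0, s2]),
    ]

    best = None
    any_success = False
    for x0 in starts:
        x0 = np.clip(x0, [0.0, 0.0, se_floor], ub)
        res = optimize.minimize(
            lambda th: _profile(th, blocks, X, y)[:2],
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
        )
        # strict improvement beyond noise, so ties keep the moments start
        if best is None or res.fun < best.fun - 1e-9 * (1.0 + abs(best.fun)):
            best = res
        any_success = any_success or bool(res.success)

    _, _, beta = _profile(best.x, blocks, X, y)
    sp, sm, se = (float(v) for v in best.x)
    return TwinFit(
        beta_0=float(beta[0]),
        beta_age=float(beta[1]) if include_age else 0.0,
        sigma2_pair=sp,
        sigma2_mz_extra=sm,
        sigma2_resid=se,
        loglik=-float(best.fun),
        converged=any_success,
        include_age=include_age,
        n_individuals=blocks.n,
        n_families=blocks.n_families,
    )


def lrt_age(
    phenotype: np.ndarray,
    cohort: TwinCohort,
    blocks: CohortBlocks | None = None,
) -> LRTResult:
    """Likelihood-ratio test for the age fixed effect.

    statistic = 2 * (loglik_full - loglik_null), floored at zero and
    referred to chi-square with one degree of freedom.
    """
    if blocks is None:
        blocks = CohortBlocks(cohort)
    fit_full = fit_twin_model(phenotype, cohort, include_age=True, blocks=blocks)
    fit_null = fit_twin_model(phenotype, cohort, include_age=False, blocks=blocks)
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    p = float(chi2.sf(stat, df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return LRTResult(statistic=stat, p_value=p, fit_full=fit_full, fit_null=fit_null)


def decompose_variance(fit_full: TwinFit, cohort: TwinCohort) -> VarianceDecomposition:
    """Partition phenotypic variance into genetic / shared-environment /
    unique-environment / age shares.

    Genetic variance is twice the extra MZ covariance (2 * sigma2_mz_extra,
    the classical twice-the-MZ-minus-DZ-correlation estimator on the
    standardized scale); shared environment is sigma2_pair -
    sigma2_mz_extra; unique environment is the residual variance; the age
    share is the population variance of beta_age * age over the cohort.
    Negative implied shares are clipped at zero and the four shares
    renormalized to sum to one. The proportion of environmental variance
    explained by age is age_share / (1 - h2).
    """
    ages = cohort.ages
    age_var = float(np.var(fit_full.beta_age * ages))
    total = age_var + fit_full.sigma2_pair + fit_full.sigma2_mz_extra + fit_full.sigma2_resid
    if total <= 0:
        raise ValidationError("total model-implied variance is zero")
    genetic = 2.0 * fit_full.sigma2_mz_extra
    shared = fit_full.sigma2_pair - fit_full.sigma2_mz_extra
    unique = fit_full.sigma2_resid
    raw = np.array([genetic, shared, unique, age_var]) / total
    clipped = np.clip(raw, 0.0, 1.0)
    shares = clipped / clipped.sum()
    h2, c2, e2, age_total = (float(v) for v in shares)
    age_env = age_total / (1.0 - h2) if h2 < 1.0 else 0.0
    return VarianceDecomposition(
        h2=h2, c2=c2, e2=e2, age_share_total=age_total, age_share_env=float(age_env)
    )
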