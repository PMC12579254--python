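"""Random-intercept linear mixed models fitted by profiled REML.

The models used throughout the package are small: a handful of fixed
effects plus one or two random intercepts (study, and optionally patient
nested within study).  For a single random intercept the marginal
covariance ``V = sigma^2 (I + lambda Z Z')`` is block diagonal with an
analytic inverse per group, so the REML criterion can be profiled down to
a one-dimensional search over the variance ratio ``lambda = tau^2/sigma^2``.
With two intercepts the same profiling is done over two ratios with a
Nelder-Mead search, using dense per-block Cholesky factorizations (blocks
are the connected components of the grouping factors).

Wald p-values use the normal approximation, which is accurate at the
group counts this package targets (>= 4 studies, tens of samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMResult", "fit_random_intercept", "fit_random_intercepts"]

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


@dataclass
class LMMResult:
    """Fitted random-intercept model."""

    beta: np.ndarray            # fixed-effect estimates (order of X columns)
    se: np.ndarray              # Wald standard errors
    pvalues: np.ndarray         # two-sided normal-approximation p-values
    sigma2: float               # residual variance
    tau2: np.ndarray            # random-intercept variance(s), one per factor
    loglik: float               # REML log-likelihood (up to a constant)
    fitted_marginal: np.ndarray     # X beta
    fitted_conditional: np.ndarray  # X beta + BLUPs
    r2_marginal: float          # var(X beta) / total variance (Nakagawa)
    r2_conditional: float       # (var(X beta) + sum tau2) / total variance
    var_prop_random: np.ndarray = field(default=None)  # tau2 / total variance

    @property
    def study_variance_proportion(self) -> float:
        return float(self.var_prop_random[0])


def _group_index(groups) -> tuple[np.ndarray, int]:
    _, idx = np.unique(np.asarray(groups), return_inverse=True)
    return idx, int(idx.max()) + 1


def _reml_pieces_single(y, X, idx, n_groups, lam):
    """GLS quantities for V = I + lam * Z Z' with one grouping factor."""
    n, p = X.shape
    sizes = np.bincount(idx, minlength=n_groups).astype(float)
    shrink = lam / (1.0 + lam * sizes)  # per-group rank-1 correction weight
    # V^{-1} M = M - shrink_g * 1 1' M within each group
    Xg = np.zeros((n_groups, p))
    yg = np.zeros(n_groups)
    np.add.at(Xg, idx, X)
    np.add.at(yg, idx, y)
    XtVX = X.T @ X - (Xg * shrink[:, None]).T @ Xg
    XtVy = X.T @ y - (Xg * shrink[:, None]).T @ yg
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    rg = np.zeros(n_groups)
    np.add.at(rg, idx, r)
    quad = float(r @ r - shrink @ rg**2)
    logdetV = float(np.sum(np.log1p(lam * sizes)))
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    return beta, XtVX, quad, logdetV, logdetXtVX, rg, shrink


def fit_random_intercept(y, X, groups, reml: bool = True) -> LMMResult:
    """Fit ``y = X beta + b_group + eps`` with ``b ~ N(0, tau^2)``.

    Profiled REML: for each variance ratio lambda the GLS estimate and the
    residual variance have closed forms; a bounded scalar search over
    log(lambda) yields the REML solution.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    idx, n_groups = _group_index(groups)
    dof = n - p if reml else n

    def neg_criterion(loglam):
        lam = np.exp(loglam)
        _, _, quad, logdetV, logdetXtVX, _, _ = _reml_pieces_single(
            y, X, idx, n_groups, lam
        )
        crit = logdetV + dof * np.log(max(quad, 1e-300))
        if reml:
            crit += logdetXtVX
        return crit

    res = optimize.minimize_scalar(
        neg_criterion, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    # boundary: essentially zero random variance
    if res.x <= _LOG_LAMBDA_BOUNDS[0] + 1e-6:
        lam = 0.0
    beta, XtVX, quad, logdetV, logdetXtVX, rg, shrink = _reml_pieces_single(
        y, X, idx, n_groups, lam
    )
    sigma2 = quad / dof
    tau2 = lam * sigma2
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvalues = 2.0 * stats.norm.sf(np.abs(z))
    loglik = -0.5 * (logdetV + dof * np.log(max(quad, 1e-300))
                     + (logdetXtVX if reml else 0.0))
    fitted = X @ beta
    blup = (shrink * rg)[idx] if lam > 0 else np.zeros(n)
    var_fixed = float(np.var(fitted))
    total = var_fixed + tau2 + sigma2
    return LMMResult(
        beta=beta, se=se, pvalues=pvalues, sigma2=float(sigma2),
        tau2=np.array([tau2]), loglik=float(loglik),
        fitted_marginal=fitted, fitted_conditional=fitted + blup,
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + tau2) / total,
        var_prop_random=np.array([tau2 / total]),
    )


def fit_random_intercepts(y, X, factors, reml: bool = True) -> LMMResult:
    """Fit a model with one or two random intercepts.

    ``factors`` is a list of grouping vectors. With one factor this
    dispatches to the fast closed-form path; with two, the REML criterion
    is profiled over both variance ratios using dense per-block algebra.
    """
    if len(factors) == 1:
        return fit_random_intercept(y, X, factors[0], reml=reml)
    if len(factors) != 2:
        raise ValueError("only one or two random intercepts are supported")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    idx1, k1 = _group_index(factors[0])
    idx2, k2 = _group_index(factors[1])
    dof = n - p if reml else n

    # Woodbury: V = I + Z diag(lam) Z' with Z the stacked indicator
    # columns of both factors (q = k1 + k2 columns); all Gram matrices
    # are precomputed so each criterion evaluation costs O(q^3).
    q = k1 + k2
    Z = np.zeros((n, q))
    Z[np.arange(n), idx1] = 1.0
    Z[np.arange(n), k1 + idx2] = 1.0
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y

    def pieces(lam1, lam2):
        d = np.r_[np.full(k1, lam1), np.full(k2, lam2)]
        s = np.sqrt(d)
        M = np.eye(q) + (s[:, None] * ZtZ) * s[None, :]
        cho = np.linalg.cholesky(M)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cho))))
        # V^{-1} A = A - Z s M^{-1} s Z' A for any A
        SZtX = s[:, None] * ZtX
        SZty = s * Zty
        Minv_SZtX = np.linalg.solve(M, SZtX)
        Minv_SZty = np.linalg.solve(M, SZty)
        XtVX = XtX - SZtX.T @ Minv_SZtX
        XtVy = Xty - SZtX.T @ Minv_SZty
        beta = np.linalg.solve(XtVX, XtVy)
        # quad = r' V^{-1} r expanded through the same identity
        yty = float(y @ y)
        ytVy = yty - float(SZty @ Minv_SZty)
        ytVXb = float(XtVy @ beta)
        quad = ytVy - 2.0 * ytVXb + float(beta @ XtVX @ beta)
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        return beta, XtVX, quad, logdetV, logdetXtVX, (d, s, M)

    def neg_criterion(loglams):
        lam1, lam2 = np.exp(np.clip(loglams, *_LOG_LAMBDA_BOUNDS))
        _, _, quad, logdetV, logdetXtVX, _ = pieces(lam1, lam2)
        crit = logdetV + dof * np.log(max(quad, 1e-300))
        if reml:
            crit += logdetXtVX
        return crit

    res = optimize.minimize(
        neg_criterion, x0=np.array([-1.0, -1.0]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
    )
    loglams = np.clip(res.x, *_LOG_LAMBDA_BOUNDS)
    lams = np.exp(loglams)
    lams[loglams <= _LOG_LAMBDA_BOUNDS[0] + 1e-6] = 0.0
    beta, XtVX, quad, logdetV, logdetXtVX, (d, s, M) = pieces(*lams)
    # conditional fit: X beta + Z b with BLUP b = diag(lam) Z' V^{-1} r
    r = y - X @ beta
    Vinv_r = r - Z @ (s * np.linalg.solve(M, s * (Z.T @ r)))
    cond_fit = X @ beta + Z @ (d * (Z.T @ Vinv_r))
    sigma2 = quad / dof
    tau2 = lams * sigma2
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvalues = 2.0 * stats.norm.sf(np.abs(z))
    loglik = -0.5 * (logdetV + dof * np.log(max(quad, 1e-300))
                     + (logdetXtVX if reml else 0.0))
    fitted = X @ beta
    var_fixed = float(np.var(fitted))
    total = var_fixed + tau2.sum() + sigma2
    return LMMResult(
        beta=beta, se=se, pvalues=pvalues, sigma2=float(sigma2),
        tau2=tau2, loglik=float(loglik),
        fitted_marginal=fitted, fitted_conditional=cond_fit,
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + tau2.sum()) / total,
        var_prop_random=tau2 / total,
    )
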