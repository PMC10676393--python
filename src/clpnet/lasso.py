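"""L1-penalized logistic regression with a warm-started coordinate-descent path.

This is the node-wise estimator behind the cross-lagged panel networks and
the Ising fits: each symptom at wave t+1 (or each item cross-sectionally)
is regressed on the remaining variables under a lasso penalty, so that small
coefficients are set exactly to zero.  The objective is the glmnet one,

    (1/n) * sum_i -loglik_i(b0 + x_i' b)  +  lam * ||b||_1 ,

with the intercept unpenalized and predictors internally standardized
(coefficients are reported back on the original 0/1 predictor scale).
The penalty is tuned by stratified K-fold cross-validated deviance
(minimum rule by default, one-standard-error rule optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "PenalizedLogisticFit",
    "DegenerateOutcomeError",
    "fit_penalized_logistic",
    "lasso_logistic_path",
    "newton_logistic",
    "stratified_folds",
]


class DegenerateOutcomeError(ValueError):
    """Raised when the outcome has a single class and no model is estimable."""


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _cd_path(X, y, lambdas, tol, max_outer, max_inner):
    """Coordinate descent over a descending lambda path with warm starts.

    X must be standardized and Fortran-ordered (the caller handles both).
    Returns slope matrix (n_lambdas x p) and intercepts (n_lambdas) on the
    standardized scale.
    """
    n, p = X.shape
    n_lam = lambdas.shape[0]
    betas = np.zeros((n_lam, p))
    b0s = np.zeros(n_lam)

    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))

    eta = np.full(n, b0)
    w = np.empty(n)
    r = np.empty(n)

    for li in range(n_lam):
        lam = lambdas[li]
        for _outer in range(max_outer):
            # IRLS weights and working residual (z - eta at current fit)
            for i in range(n):
                mu = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = mu * (1.0 - mu)
                if wi < 1e-6:
                    wi = 1e-6
                w[i] = wi
                r[i] = (y[i] - mu) / wi

            outer_delta = 0.0
            for _inner in range(max_inner):
                delta = 0.0
                # intercept (unpenalized)
                wsum = 0.0
                wr = 0.0
                for i in range(n):
                    wsum += w[i]
                    wr += w[i] * r[i]
                num = wr / wsum
                if num != 0.0:
                    b0 += num
                    for i in range(n):
                        r[i] -= num
                    if abs(num) > delta:
                        delta = abs(num)
                for j in range(p):
                    bj = beta[j]
                    xj = X[:, j]
                    s_xx = 0.0
                    s_xr = 0.0
                    for i in range(n):
                        t = w[i] * xj[i]
                        s_xx += t * xj[i]
                        s_xr += t * r[i]
                    denom = s_xx / n
                    if denom <= 0.0:
                        continue
                    grad = s_xr / n + denom * bj
                    # soft threshold
                    if grad > lam:
                        bnew = (grad - lam) / denom
                    elif grad < -lam:
                        bnew = (grad + lam) / denom
                    else:
                        bnew = 0.0
                    diff = bnew - bj
                    if diff != 0.0:
                        beta[j] = bnew
                        for i in range(n):
                            r[i] -= diff * xj[i]
                        if abs(diff) > delta:
                            delta = abs(diff)
                if delta > outer_delta:
                    outer_delta = delta
                if delta < tol:
                    break
            # eta = b0 + X beta, maintained via the working residual:
            # r currently holds z - (b0 + X beta), and z = eta_old + r_old
            for i in range(n):
                mu = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = w[i]
                z = eta[i] + (y[i] - mu) / wi
                eta[i] = z - r[i]
            if outer_delta < tol:
                break
        betas[li] = beta
        b0s[li] = b0
    return betas, b0s


@njit(cache=True)
def _deviance_path(X, y, betas, b0s):
    """Total binomial deviance of each path point on (X, y)."""
    n_lam = betas.shape[0]
    n = X.shape[0]
    out = np.empty(n_lam)
    for li in range(n_lam):
        eta = b0s[li] + X @ betas[li]
        dev = 0.0
        for i in range(n):
            # -2 loglik, numerically safe
            e = eta[i]
            if e > 30.0:
                lse = e
            elif e < -30.0:
                lse = 0.0
            else:
                lse = np.log(1.0 + np.exp(e))
            dev += 2.0 * (lse - y[i] * e)
        out[li] = dev
    return out


# ---------------------------------------------------------------------------
# pure-python drivers
# ---------------------------------------------------------------------------

def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # divisor n
    sd_safe = np.where(sd > 0, sd, 1.0)
    return np.asfortranarray((X - mean) / sd_safe), mean, sd_safe


def lambda_max(X_std, y):
    """Smallest penalty at which all slopes are zero (standardized scale)."""
    n = len(y)
    return np.abs(X_std.T @ (y - y.mean())).max() / n


def _lambda_grid(lmax, n_lambdas, min_ratio):
    # start a hair above lambda_max so the first path point is the exact
    # null model even after the intercept refines within IRLS
    lmax = lmax * (1 + 1e-4)
    return np.exp(np.linspace(np.log(lmax), np.log(lmax * min_ratio), n_lambdas))


def lasso_logistic_path(
    X, y, lambdas=None, n_lambdas=30, lambda_min_ratio=1e-3, tol=1e-7
):
    """Fit the full lasso-logistic path; coefficients on the original scale.

    Returns (lambdas, coefs[n_lam, p], intercepts[n_lam]).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    X_std, mean, sd = _standardize(X)
    if lambdas is None:
        lambdas = _lambda_grid(lambda_max(X_std, y), n_lambdas, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    betas, b0s = _cd_path(X_std, y, lambdas, tol, 50, 200)
    coefs = betas / sd
    intercepts = b0s - coefs @ mean
    return lambdas, coefs, intercepts


def newton_logistic(X, y, ridge=0.0, tol=1e-10, max_iter=100, add_intercept=True):
    """Unpenalized (optionally ridge-stabilized) logistic MLE by Newton-Raphson.

    Returns (coef, intercept) when add_intercept, else the full coefficient
    vector.  Used for the penalty-zero limit and for imputation models.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if add_intercept:
        Xd = np.column_stack([np.ones(n), X])
    else:
        Xd = X
    p = Xd.shape[1]
    beta = np.zeros(p)
    ybar = y.mean()
    if add_intercept:
        beta[0] = np.log(ybar / (1 - ybar))
    pen = np.full(p, ridge)
    if add_intercept:
        pen[0] = 0.0
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = Xd.T @ (y - mu) - pen * beta
        H = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    if add_intercept:
        return beta[1:], beta[0]
    return beta


def stratified_folds(y, n_folds, seed):
    """Fold assignment stratified by outcome class, from a seeded permutation."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    fold = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


@dataclass
class PenalizedLogisticFit:
    """One node-wise fit: selected-penalty coefficients plus tuning metadata."""

    coef: np.ndarray            # slopes, original predictor scale
    intercept: float
    lambda_selected: float
    selection_rule: str
    n: int
    lambda_path: np.ndarray = field(repr=False)
    cv_mean_deviance: np.ndarray | None = field(default=None, repr=False)
    cv_se_deviance: np.ndarray | None = field(default=None, repr=False)
    path_coefs: np.ndarray | None = field(default=None, repr=False)

    def predict_proba(self, X):
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def fit_penalized_logistic(
    X,
    y,
    n_folds: int = 10,
    selection_rule: str = "min",
    seed: int = 0,
    penalty: float | None = None,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 1e-3,
) -> PenalizedLogisticFit:
    """Lasso-logistic fit with the penalty chosen by K-fold CV deviance.

    Parameters
    ----------
    X, y
        Complete predictor matrix and 0/1 outcome (missingness handled
        upstream by imputation or complete-case selection).
    n_folds
        Cross-validation folds; assignment is stratified by outcome class
        from a seeded permutation.
    selection_rule
        ``"min"`` picks the penalty minimizing mean CV deviance;
        ``"1se"`` the largest penalty within one standard error of it.
    penalty
        Bypass CV and fit at this penalty; ``0.0`` gives the unpenalized
        maximum-likelihood fit.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed; impute upstream")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if len(classes) < 2:
        raise DegenerateOutcomeError("degenerate outcome: single class")
    n = len(y)

    if penalty is not None and penalty == 0.0:
        coef, intercept = newton_logistic(X, y)
        # constant columns: Newton keeps them at 0 only if exactly collinear
        # with the intercept; zero them explicitly for the contract.
        sd = X.std(axis=0)
        coef = np.where(sd > 0, coef, 0.0)
        return PenalizedLogisticFit(
            coef=coef, intercept=float(intercept), lambda_selected=0.0,
            selection_rule="fixed", n=n, lambda_path=np.array([0.0]),
        )

    X_std, mean, sd = _standardize(X)
    lmax = lambda_max(X_std, y)
    if lmax <= 0:
        lmax = 1e-3
    grid = _lambda_grid(lmax, n_lambdas, lambda_min_ratio)

    if penalty is not None:
        # warm-started descent down to the requested penalty
        lams = np.append(grid[grid > penalty], penalty)
        betas, b0s = _cd_path(X_std, y, lams, 1e-7, 50, 200)
        coef = betas[-1] / sd
        intercept = b0s[-1] - coef @ mean
        return PenalizedLogisticFit(
            coef=coef, intercept=float(intercept), lambda_selected=float(penalty),
            selection_rule="fixed", n=n, lambda_path=lams,
        )

    fold = stratified_folds(y, n_folds, seed)
    # per-observation deviance, summed per fold then averaged over folds
    fold_dev = np.empty((n_folds, n_lambdas))
    for k in range(n_folds):
        tr = fold != k
        te = ~tr
        # fold fits only feed the deviance curve; a looser tolerance is
        # harmless for selection and much faster
        betas, b0s = _cd_path(np.asfortranarray(X_std[tr]), y[tr], grid, 1e-5, 50, 200)
        fold_dev[k] = _deviance_path(X_std[te], y[te], betas, b0s) / te.sum()
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)

    i_min = int(np.argmin(cv_mean))
    if selection_rule == "min":
        i_sel = i_min
    elif selection_rule == "1se":
        thresh = cv_mean[i_min] + cv_se[i_min]
        i_sel = int(np.flatnonzero(cv_mean <= thresh)[0])  # grid is descending
    else:
        raise ValueError(f"unknown selection rule {selection_rule!r}")

    betas, b0s = _cd_path(X_std, y, grid, 1e-7, 50, 200)
    coefs = betas / sd
    intercepts = b0s - coefs @ mean
    return PenalizedLogisticFit(
        coef=coefs[i_sel],
        intercept=float(intercepts[i_sel]),
        lambda_selected=float(grid[i_sel]),
        selection_rule=selection_rule,
        n=n,
        lambda_path=grid,
        cv_mean_deviance=cv_mean,
        cv_se_deviance=cv_se,
        path_coefs=coefs,
    )
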