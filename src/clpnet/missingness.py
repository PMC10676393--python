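"""Missing-data stage: MCAR testing, dropout modelling, chained-equation imputation.

Little's MCAR test compares per-missingness-pattern means against the EM
estimate of a common multivariate-normal mean/covariance; applying it to
binary items treats them as numeric, the standard applied practice (the
reference method assumes normality — a documented caveat).  Imputation is
fully conditional specification with logistic draws: each incomplete
binary variable is regressed on all others, the coefficients are perturbed
by a draw from their asymptotic normal distribution, and missing entries
are redrawn as Bernoulli.  One imputed dataset is retained by default
(network estimation is not compatible with multiple-imputation pooling);
``n_datasets`` can emit more for sensitivity use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .descriptives import sum_scores
from .lasso import newton_logistic
from .types import MCARTestResult, PanelDataset

__all__ = [
    "little_mcar_test",
    "dropout_model",
    "impute_chained",
    "panel_to_wide_matrix",
]


# ---------------------------------------------------------------------------
# Little's MCAR test
# ---------------------------------------------------------------------------

def _em_normal(y: np.ndarray, max_iter: int = 200, tol: float = 1e-6):
    """EM estimate of (mu, sigma) for multivariate normal data with missing
    values, iterating over missingness patterns."""
    n, p = y.shape
    miss = np.isnan(y)
    mu = np.nanmean(y, axis=0)
    resid = np.where(miss, 0.0, y - mu)
    sigma = np.diag(np.nanvar(y, axis=0))

    # group rows by pattern once
    pattern_ids, inverse = np.unique(miss, axis=0, return_inverse=True)
    groups = [np.flatnonzero(inverse == g) for g in range(len(pattern_ids))]

    for _ in range(max_iter):
        s_y = np.zeros(p)
        s_yy = np.zeros((p, p))
        for g, rows in enumerate(groups):
            mpat = pattern_ids[g]
            obs = ~mpat
            yo = y[rows][:, obs]
            if not mpat.any():
                s_y += yo.sum(axis=0)
                s_yy += yo.T @ yo
                continue
            soo = sigma[np.ix_(obs, obs)]
            smo = sigma[np.ix_(mpat, obs)]
            try:
                reg = smo @ np.linalg.inv(soo)
            except np.linalg.LinAlgError:
                reg = smo @ np.linalg.inv(soo + 1e-8 * np.eye(obs.sum()))
            cond_mean = mu[mpat] + (yo - mu[obs]) @ reg.T         # (n_g, m)
            cond_cov = sigma[np.ix_(mpat, mpat)] - reg @ smo.T
            full = np.zeros((len(rows), p))
            full[:, obs] = yo
            full[:, mpat] = cond_mean
            s_y += full.sum(axis=0)
            s_yy += full.T @ full
            # add conditional covariance for the missing block
            add = np.zeros((p, p))
            add[np.ix_(mpat, mpat)] = len(rows) * cond_cov
            s_yy += add
        mu_new = s_y / n
        sigma_new = s_yy / n - np.outer(mu_new, mu_new)
        if np.abs(mu_new - mu).max() < tol and np.abs(sigma_new - sigma).max() < tol:
            mu, sigma = mu_new, sigma_new
            break
        mu, sigma = mu_new, sigma_new
    return mu, sigma, pattern_ids, groups


def little_mcar_test(data) -> MCARTestResult:
    """Little's chi-square test of missing completely at random.

    ``d2 = sum_j n_j (ybar_j - mu_obs_j)' Sigma_obs_j^-1 (ybar_j -
    mu_obs_j)`` over missingness patterns with at least one observed
    variable, referred to chi-square with ``df = sum_j p_j - p``.
    Complete data (a single pattern) give d2 = 0 with df = 0 and an
    undefined (NaN) p-value.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("data must be n x p with p >= 2")
    mu, sigma, pattern_ids, groups = _em_normal(y)

    d2 = 0.0
    df = 0
    n_patterns = 0
    p = y.shape[1]
    for g, rows in enumerate(groups):
        obs = ~pattern_ids[g]
        if not obs.any():
            continue
        n_patterns += 1
        df += int(obs.sum())
        ybar = y[rows][:, obs].mean(axis=0)
        diff = ybar - mu[obs]
        soo = sigma[np.ix_(obs, obs)]
        try:
            sol = np.linalg.solve(soo, diff)
        except np.linalg.LinAlgError:
            warnings.warn("singular pattern covariance; ridge-stabilized inverse", stacklevel=2)
            sol = np.linalg.solve(soo + 1e-8 * np.eye(obs.sum()), diff)
        d2 += len(rows) * float(diff @ sol)
    df -= p
    if df <= 0:
        return MCARTestResult(d2=float(d2), df=max(df, 0), p_value=float("nan"),
                              n_patterns=n_patterns)
    return MCARTestResult(
        d2=float(d2), df=df, p_value=float(chi2.sf(d2, df)), n_patterns=n_patterns
    )


# ---------------------------------------------------------------------------
# dropout model
# ---------------------------------------------------------------------------

def dropout_model(panel: PanelDataset, extra_predictors: pd.DataFrame | None = None) -> pd.DataFrame:
    """Logistic regression of ever-dropping-out on covariates and baseline severity.

    The outcome is 1 for subjects missing at any wave after baseline.
    Predictors are the panel covariates, the baseline depression sum score,
    and any supplied extra columns.  Complete separation falls back to a
    ridge-penalized fit, flagged in the ``separation`` column.
    """
    import statsmodels.api as sm

    present = panel.observed.any(axis=2)
    dropped = (~present[:, 1:]).any(axis=1).astype(float)
    if dropped.sum() == 0:
        raise ValueError("no events: no subject ever dropped out")

    baseline = sum_scores(panel)[:, 0]
    X = pd.DataFrame(panel.covariates, columns=list(panel.covariate_labels))
    X["baseline_sum_score"] = baseline
    if extra_predictors is not None:
        X = pd.concat([X, extra_predictors.reset_index(drop=True)], axis=1)
    keep = ~X.isna().any(axis=1)
    Xk, yk = X[keep], dropped[keep.to_numpy()]

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # PerfectSeparationWarning -> fallback
            fit = sm.Logit(yk, sm.add_constant(Xk)).fit(disp=0)
        params, se = fit.params.to_numpy(), fit.bse.to_numpy()
    except Exception:
        separation = True
        beta = newton_logistic(Xk.to_numpy(float), yk, ridge=1.0, add_intercept=True)
        coef, intercept = beta
        params = np.concatenate([[intercept], coef])
        Xd = np.column_stack([np.ones(len(yk)), Xk.to_numpy(float)])
        mu = 1 / (1 + np.exp(-(Xd @ params)))
        H = (Xd * (mu * (1 - mu))[:, None]).T @ Xd + np.eye(Xd.shape[1])
        se = np.sqrt(np.diag(np.linalg.inv(H)))
    z = params / se
    pvals = 2 * (1 - _norm_cdf(np.abs(z)))
    return pd.DataFrame({
        "predictor": ["intercept"] + list(Xk.columns),
        "coef": params,
        "se": se,
        "z": z,
        "p_value": pvals,
        "separation": separation,
    })


def _norm_cdf(x):
    from scipy.stats import norm

    return norm.cdf(x)


# ---------------------------------------------------------------------------
# chained-equations imputation
# ---------------------------------------------------------------------------

def panel_to_wide_matrix(panel: PanelDataset) -> tuple[np.ndarray, list[str]]:
    """(n, W*K) float matrix of item columns (NaN = missing) plus names."""
    n, w, k = panel.items.shape
    mat = panel.values_float().reshape(n, w * k)
    names = [f"w{wave}_{item}" for wave in panel.wave_labels for item in panel.item_labels]
    return mat, names


def _perturbed_logistic_draw(X, y, X_missing, rng, ridge):
    """Fit logistic(y ~ X), perturb coefficients by their asymptotic normal
    distribution, and return Bernoulli draws for the missing rows."""
    beta = newton_logistic(X, y, ridge=ridge, add_intercept=False)
    eta = X @ beta
    mu = 1 / (1 + np.exp(-np.clip(eta, -35, 35)))
    H = (X * np.clip(mu * (1 - mu), 1e-10, None)[:, None]).T @ X + ridge * np.eye(X.shape[1])
    cov = np.linalg.inv(H)
    # symmetrize against round-off before the normal draw
    cov = 0.5 * (cov + cov.T)
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky", check_valid="ignore")
    p_star = 1 / (1 + np.exp(-np.clip(X_missing @ beta_star, -35, 35)))
    return (rng.random(len(p_star)) < p_star).astype(float)


def impute_chained(
    panel: PanelDataset,
    auxiliaries: pd.DataFrame | None = None,
    n_iterations: int = 20,
    seed: int = 0,
    n_datasets: int = 1,
    ridge: float = 1e-3,
    return_trace: bool = False,
):
    """Chained-equations imputation of a binary panel by logistic draws.

    Variables are the item columns in wide layout; predictors for each
    incomplete variable are all other item columns, the panel covariates
    and any auxiliary columns.  Initialization draws missing cells from the
    observed marginals; each of ``n_iterations`` sweeps then revisits
    incomplete variables in fixed column order.  A small ridge term
    stabilizes fits against separation in sparse cells.

    Returns one complete :class:`PanelDataset` (or a list when
    ``n_datasets > 1``); observed values are never altered.  With
    ``return_trace`` a per-variable imputed-prevalence trace is attached
    for convergence monitoring.
    """
    mat, names = panel_to_wide_matrix(panel)
    miss = np.isnan(mat)
    if panel.n_subjects and np.any(miss.all(axis=0)):
        bad = [names[j] for j in np.flatnonzero(miss.all(axis=0))]
        raise ValueError(f"variables with no observed values: {bad}")

    extra = panel.covariates.astype(float)
    if auxiliaries is not None:
        extra = np.column_stack([extra, np.asarray(auxiliaries, dtype=float)])

    results = []
    traces = []
    for m_index in range(n_datasets):
        rng = np.random.default_rng([int(seed), 31, m_index])
        filled = mat.copy()
        for j in range(mat.shape[1]):
            mj = miss[:, j]
            if mj.any():
                p_obs = np.nanmean(mat[:, j])
                filled[mj, j] = rng.random(mj.sum()) < p_obs
        trace = []
        incomplete = np.flatnonzero(miss.any(axis=0))
        if incomplete.size:
            for _ in range(n_iterations):
                for j in incomplete:
                    mj = miss[:, j]
                    others = np.delete(np.arange(mat.shape[1]), j)
                    Xfull = np.column_stack([
                        np.ones(len(filled)), filled[:, others], extra,
                    ])
                    filled[mj, j] = _perturbed_logistic_draw(
                        Xfull[~mj], filled[~mj, j], Xfull[mj], rng, ridge
                    )
                trace.append([filled[miss[:, j], j].mean() for j in incomplete])
        traces.append(
            pd.DataFrame(trace, columns=[names[j] for j in incomplete])
        )
        out = panel.copy()
        out.items = filled.reshape(panel.items.shape).astype(np.uint8)
        out.observed = np.ones_like(panel.observed, dtype=bool)
        results.append(out)

    if n_datasets == 1:
        return (results[0], traces[0]) if return_trace else results[0]
    return (results, traces) if return_trace else results
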