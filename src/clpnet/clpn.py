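"""Cross-lagged panel network estimation and expected-influence centrality.

One CLPN per consecutive wave pair: every item at wave t+1 is regressed on
all items at wave t (plus the binary covariates) with an L1 penalty tuned
by stratified 10-fold cross-validation, giving a directed coefficient
matrix on the log-odds scale.  Edges are also reported as odds ratios,
where OR > 1 is a positive lagged association and OR = 1 no association.
"""

from __future__ import annotations

import numpy as np

from .lasso import DegenerateOutcomeError, fit_penalized_logistic
from .types import CentralityTable, CLPNetwork, PanelDataset

__all__ = ["fit_clpn", "fit_all_clpns", "to_odds_ratio", "expected_influence"]


def _child_seed(seed, j: int) -> list[int]:
    """Extend a scalar or sequence seed with one more stream index."""
    if np.isscalar(seed):
        return [int(seed), int(j)]
    return [int(s) for s in seed] + [int(j)]


def _transition_arrays(panel: PanelDataset, wave: int, covariates: bool):
    """Predictor/outcome arrays for the wave -> wave+1 transition.

    Complete-case on the wave pair: only subjects with all items observed
    at both waves contribute (on an imputed panel this is everyone).
    """
    w = panel.wave_labels.index(wave)
    if w + 1 >= panel.n_waves:
        raise ValueError(f"wave {wave} has no successor")
    keep = panel.observed[:, w, :].all(axis=1) & panel.observed[:, w + 1, :].all(axis=1)
    X_items = panel.items[keep, w, :].astype(float)
    Y = panel.items[keep, w + 1, :].astype(float)
    labels = list(panel.item_labels)
    cov_rows: tuple[int, ...] = ()
    if covariates and len(panel.covariate_labels):
        X = np.column_stack([X_items, panel.covariates[keep].astype(float)])
        cov_rows = tuple(range(len(labels), len(labels) + len(panel.covariate_labels)))
        labels += list(panel.covariate_labels)
    else:
        X = X_items
    return X, Y, tuple(labels), cov_rows


def fit_clpn(
    panel: PanelDataset,
    wave: int,
    covariates: bool = True,
    selection_rule: str = "1se",
    n_folds: int = 10,
    seed: int = 0,
    penalties=None,
    n_lambdas: int = 30,
) -> CLPNetwork:
    """Estimate the CLPN for the transition ``wave -> wave + 1``.

    ``penalties`` fixes the per-outcome penalty (skipping CV), e.g. to
    refit bootstrap replicates at the full-sample selection; otherwise the
    penalty is re-selected per outcome by CV deviance under
    ``selection_rule``.
    """
    X, Y, predictor_labels, cov_rows = _transition_arrays(panel, wave, covariates)
    k = Y.shape[1]
    coef = np.zeros((X.shape[1], k))
    intercepts = np.zeros(k)
    lams = np.zeros(k)
    for j in range(k):
        try:
            fit = fit_penalized_logistic(
                X,
                Y[:, j],
                n_folds=n_folds,
                selection_rule=selection_rule,
                seed=_child_seed(seed, j),
                penalty=None if penalties is None else float(np.asarray(penalties)[j]),
                n_lambdas=n_lambdas,
            )
        except DegenerateOutcomeError as e:
            raise DegenerateOutcomeError(
                f"outcome {panel.item_labels[j]!r}: {e}"
            ) from e
        coef[:, j] = fit.coef
        intercepts[j] = fit.intercept
        lams[j] = fit.lambda_selected
    return CLPNetwork(
        predictor_labels=predictor_labels,
        outcome_labels=panel.item_labels,
        coef=coef,
        intercepts=intercepts,
        penalties=lams,
        n=X.shape[0],
        scale="log_odds",
        covariate_rows=cov_rows,
        label=f"t{wave}_t{wave + 1}",
        selection_rule="fixed" if penalties is not None else selection_rule,
    )


def fit_all_clpns(panel: PanelDataset, seed: int = 0, **options) -> list[CLPNetwork]:
    """One CLPN per consecutive wave pair (W-1 networks for a W-wave panel)."""
    return [
        fit_clpn(panel, wave, seed=_child_seed(seed, wi), **options)
        for wi, wave in enumerate(panel.wave_labels[:-1])
    ]


def to_odds_ratio(network: CLPNetwork) -> CLPNetwork:
    """Elementwise exp of the log-odds edge weights; the input is unchanged."""
    if network.scale != "log_odds":
        raise ValueError("network is not on the log-odds scale")
    out = CLPNetwork(
        predictor_labels=network.predictor_labels,
        outcome_labels=network.outcome_labels,
        coef=np.exp(network.coef),
        intercepts=network.intercepts.copy(),
        penalties=network.penalties.copy(),
        n=network.n,
        scale="or",
        covariate_rows=network.covariate_rows,
        label=network.label,
        selection_rule=network.selection_rule,
    )
    return out


def expected_influence(network: CLPNetwork) -> CentralityTable:
    """Cross-lagged in-/out-expected-influence per item.

    in-EI(k) = sum over items j != k of coef[j, k]; out-EI(j) the row
    counterpart.  Autoregressive (diagonal) and covariate entries are
    excluded; sums run on the log-odds scale, where an absent edge
    contributes 0.  z-scores standardize across the items (SD divisor n).
    """
    if network.scale != "log_odds":
        raise ValueError("expected influence is defined on the log-odds scale")
    cross = network.cross_lagged()
    in_ei = cross.sum(axis=0)
    out_ei = cross.sum(axis=1)

    def z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    return CentralityTable(
        item_labels=network.outcome_labels,
        in_ei=in_ei,
        out_ei=out_ei,
        in_ei_z=z(in_ei),
        out_ei_z=z(out_ei),
        network_label=network.label,
    )
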