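"""Bootstrap accuracy, case-drop stability and difference tests for CLPNs.

Accuracy: nonparametric bootstrap (subjects resampled with replacement,
network refit per replicate) giving percentile 95% CIs per edge.
Stability: case-drop bootstrap (subjects subsampled without replacement at
fixed drop proportions) summarized by the CS-coefficient — the largest
drop proportion at which the centrality order still correlates >= 0.7 with
the full-sample order in >= 95% of subsamples.  Difference tests compare
two edges (or two items' centralities) by the percentile interval of the
bootstrap distribution of their difference; following the convention of
the bootstrap-network framework, no multiplicity correction is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ConstantInputWarning, pearsonr, spearmanr

from .clpn import _child_seed, expected_influence, fit_clpn
from .lasso import DegenerateOutcomeError
from .types import (
    BootstrapDistribution,
    CLPNetwork,
    DifferenceTestResult,
    PanelDataset,
    StabilityResult,
)

__all__ = [
    "bootstrap_edges",
    "edge_difference_test",
    "centrality_difference_test",
    "casedrop_stability",
]

_STREAM_BOOT = 21
_STREAM_CASEDROP = 22


def _subset_panel(panel: PanelDataset, idx: np.ndarray) -> PanelDataset:
    return PanelDataset(
        subject_ids=np.arange(len(idx)),
        items=panel.items[idx],
        observed=panel.observed[idx],
        covariates=panel.covariates[idx],
        item_labels=panel.item_labels,
        wave_labels=panel.wave_labels,
        covariate_labels=panel.covariate_labels,
    )


def bootstrap_edges(
    panel: PanelDataset,
    wave: int,
    B: int = 1000,
    refit_penalty: str = "reselect",
    seed: int = 0,
    **clpn_options,
) -> tuple[BootstrapDistribution, pd.DataFrame]:
    """Nonparametric bootstrap of one wave-pair CLPN with percentile CIs.

    ``refit_penalty="reselect"`` re-runs CV penalty selection in every
    replicate (reflecting the full uncertainty of the procedure);
    ``"fixed"`` reuses the per-outcome penalties selected on the full
    sample.  Replicates with a degenerate (single-class) outcome are
    skipped and logged in ``failures``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if refit_penalty not in ("reselect", "fixed"):
        raise ValueError("refit_penalty must be 'reselect' or 'fixed'")

    full = fit_clpn(panel, wave, seed=_child_seed(seed, 0), **clpn_options)
    penalties = full.penalties if refit_penalty == "fixed" else None

    n = panel.n_subjects
    coefs, in_eis, out_eis, failures = [], [], [], []
    for b in range(B):
        rng = np.random.default_rng(_child_seed(seed, _STREAM_BOOT) + [b])
        idx = rng.integers(0, n, size=n)
        sub = _subset_panel(panel, idx)
        try:
            net = fit_clpn(
                sub, wave, seed=_child_seed(seed, _STREAM_BOOT) + [b],
                penalties=penalties, **clpn_options,
            )
        except DegenerateOutcomeError as e:
            failures.append({"replicate": b, "cause": str(e)})
            continue
        ei = expected_influence(net)
        coefs.append(net.coef)
        in_eis.append(ei.in_ei)
        out_eis.append(ei.out_ei)

    dist = BootstrapDistribution(
        kind="nonparametric",
        n_requested=B,
        coefs=np.array(coefs),
        in_ei=np.array(in_eis),
        out_ei=np.array(out_eis),
        predictor_labels=full.predictor_labels,
        outcome_labels=full.outcome_labels,
        covariate_rows=full.covariate_rows,
        seed=seed,
        failures=failures,
    )

    lo = np.percentile(dist.coefs, 2.5, axis=0)
    hi = np.percentile(dist.coefs, 97.5, axis=0)
    rows = []
    for i, pl in enumerate(full.predictor_labels):
        for j, ol in enumerate(full.outcome_labels):
            rows.append({
                "predictor": pl,
                "outcome": ol,
                "estimate": full.coef[i, j],
                "ci_low": lo[i, j],
                "ci_high": hi[i, j],
                "or_estimate": np.exp(full.coef[i, j]),
                "or_ci_low": np.exp(lo[i, j]),
                "or_ci_high": np.exp(hi[i, j]),
            })
    return dist, pd.DataFrame(rows)


def _cross_lagged_replicates(dist: BootstrapDistribution):
    """(B, m) matrix of cross-lagged edge values plus their labels."""
    item_rows = np.setdiff1d(
        np.arange(len(dist.predictor_labels)), np.asarray(dist.covariate_rows, dtype=int)
    )
    k = len(dist.outcome_labels)
    vals, labels = [], []
    for a_pos, a_row in enumerate(item_rows):
        for b in range(k):
            if a_pos == b:
                continue  # autoregressive
            vals.append(dist.coefs[:, a_row, b])
            labels.append(f"{dist.predictor_labels[a_row]}->{dist.outcome_labels[b]}")
    return np.array(vals).T, tuple(labels)


def _pairwise_difference(values: np.ndarray, labels, alpha: float) -> DifferenceTestResult:
    """Percentile bootstrap difference test over the columns of (B, m)."""
    m = values.shape[1]
    lo = np.zeros((m, m))
    hi = np.zeros((m, m))
    sig = np.zeros((m, m), dtype=bool)
    q = (100 * alpha / 2, 100 * (1 - alpha / 2))
    for i in range(m):
        d = values[:, i][:, None] - values  # (B, m)
        l_i = np.percentile(d, q[0], axis=0)
        h_i = np.percentile(d, q[1], axis=0)
        lo[i], hi[i] = l_i, h_i
        sig[i] = (l_i > 0) | (h_i < 0)
    np.fill_diagonal(sig, False)
    sig = sig & sig.T  # enforce exact symmetry under percentile asymmetries
    return DifferenceTestResult(
        labels=tuple(labels), significant=sig, ci_low=lo, ci_high=hi, alpha=alpha
    )


def edge_difference_test(dist: BootstrapDistribution, alpha: float = 0.05) -> DifferenceTestResult:
    """Are some cross-lagged edges significantly stronger than others?"""
    values, labels = _cross_lagged_replicates(dist)
    return _pairwise_difference(values, labels, alpha)


def centrality_difference_test(
    dist: BootstrapDistribution, index: str = "in", alpha: float = 0.05
) -> DifferenceTestResult:
    """Are some items significantly more central than others?"""
    if index not in ("in", "out"):
        raise ValueError("index must be 'in' or 'out'")
    values = dist.in_ei if index == "in" else dist.out_ei
    return _pairwise_difference(values, dist.outcome_labels, alpha)


def casedrop_stability(
    panel: PanelDataset,
    wave: int,
    proportions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    B: int = 1000,
    seed: int = 0,
    correlation: str = "spearman",
    cs_threshold: float = 0.7,
    cs_confidence: float = 0.95,
    **clpn_options,
) -> StabilityResult:
    """Case-drop bootstrap of the centrality indices with CS-coefficients.

    A drop proportion of 0 reuses the full-sample estimate (the subsample
    is the full sample), so its correlation is identically 1.
    """
    proportions = np.asarray(sorted(proportions), dtype=float)
    if np.any(proportions < 0) or np.any(proportions >= 1):
        raise ValueError("drop proportions must lie in [0, 1)")
    corr_fn = {"spearman": spearmanr, "pearson": pearsonr}[correlation]

    full = fit_clpn(panel, wave, seed=_child_seed(seed, 0), **clpn_options)
    full_ei = expected_influence(full)
    n = panel.n_subjects

    corr_in = np.full((len(proportions), B), np.nan)
    corr_out = np.full((len(proportions), B), np.nan)
    for pi, prop in enumerate(proportions):
        keep = int(round((1.0 - prop) * n))
        for b in range(B):
            if keep >= n:
                corr_in[pi, b] = 1.0
                corr_out[pi, b] = 1.0
                continue
            rng = np.random.default_rng(_child_seed(seed, _STREAM_CASEDROP) + [pi, b])
            idx = rng.choice(n, size=keep, replace=False)
            try:
                net = fit_clpn(
                    _subset_panel(panel, idx), wave,
                    seed=_child_seed(seed, _STREAM_CASEDROP) + [pi, b],
                    **clpn_options,
                )
            except DegenerateOutcomeError:
                continue
            ei = expected_influence(net)
            with warnings.catch_warnings():
                # constant centrality vectors (empty networks) yield NaN,
                # which the CS computation already treats as a failure
                warnings.simplefilter("ignore", ConstantInputWarning)
                corr_in[pi, b] = corr_fn(full_ei.in_ei, ei.in_ei)[0]
                corr_out[pi, b] = corr_fn(full_ei.out_ei, ei.out_ei)[0]

    def cs(corrs: np.ndarray) -> float:
        best = 0.0
        for pi, prop in enumerate(proportions):
            row = corrs[pi]
            ok = np.nan_to_num(row, nan=-1.0) >= cs_threshold
            if ok.mean() >= cs_confidence:
                best = max(best, float(prop))
        return best

    return StabilityResult(
        proportions=proportions,
        correlations_in=corr_in,
        correlations_out=corr_out,
        cs_in=cs(corr_in),
        cs_out=cs(corr_out),
        correlation_type=correlation,
    )
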