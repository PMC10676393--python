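"""Cross-network consistency statistics.

A cross-lagged edge counts as replicated when it is nonzero with the same
sign in both networks.  The replication percentage depends on the chosen
denominator: edges nonzero in the first network ("first", the default and
not symmetric in the arguments), edges nonzero in at least one network
("union"), or the order-invariant average of the two directed percentages
("either").  Edge-weight correlations run over the fixed enumeration of
all off-diagonal item positions on the log-odds scale with zeros included
(restricting to jointly nonzero entries would conflate replication and
correlation); centrality correlations run over the items.
"""

from __future__ import annotations

import numpy as np

from .clpn import expected_influence
from .types import CLPNetwork, NetworkComparison

__all__ = ["compare_networks", "compare_consecutive"]


def _safe_corr(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compare_networks(
    a: CLPNetwork,
    b: CLPNetwork,
    replication_denominator: str = "first",
    jointly_nonzero_only: bool = False,
) -> NetworkComparison:
    """Replication percentage and correlation statistics for two CLPNs."""
    if a.outcome_labels != b.outcome_labels:
        raise ValueError("networks must share an identical item set")
    if a.scale != "log_odds" or b.scale != "log_odds":
        raise ValueError("comparison runs on the log-odds scale")
    if replication_denominator not in ("first", "union", "either"):
        raise ValueError("replication_denominator must be first|union|either")

    ca, cb = a.cross_lagged(), b.cross_lagged()
    k = ca.shape[0]
    off = ~np.eye(k, dtype=bool)        # fixed row-major enumeration
    wa, wb = ca[off], cb[off]

    nz_a, nz_b = wa != 0, wb != 0
    replicated = nz_a & nz_b & (np.sign(wa) == np.sign(wb))
    n_rep = int(replicated.sum())

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    pct_first = pct(n_rep, nz_a.sum())
    pct_union = pct(n_rep, (nz_a | nz_b).sum())
    pct_either = float(np.mean([pct(n_rep, nz_a.sum()), pct(n_rep, nz_b.sum())]))

    if jointly_nonzero_only:
        sel = nz_a & nz_b
        edge_r = _safe_corr(wa[sel], wb[sel]) if sel.sum() >= 2 else float("nan")
    else:
        edge_r = _safe_corr(wa, wb)

    ei_a, ei_b = expected_influence(a), expected_influence(b)
    return NetworkComparison(
        label_a=a.label,
        label_b=b.label,
        replication_pct_first=pct_first,
        replication_pct_union=pct_union,
        replication_pct_either=pct_either,
        edge_weight_r=edge_r,
        in_ei_r=_safe_corr(ei_a.in_ei, ei_b.in_ei),
        out_ei_r=_safe_corr(ei_a.out_ei, ei_b.out_ei),
        n_edges_a=int(nz_a.sum()),
        n_edges_b=int(nz_b.sum()),
        n_replicated=n_rep,
    )


def compare_consecutive(networks, **kwargs) -> list[NetworkComparison]:
    """Pairwise comparison of each consecutive network pair."""
    return [
        compare_networks(networks[i], networks[i + 1], **kwargs)
        for i in range(len(networks) - 1)
    ]
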