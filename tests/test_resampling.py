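"""Bootstrap accuracy, difference tests and case-drop stability."""

import numpy as np
import pytest

from clpnet.resampling import (
    bootstrap_edges,
    casedrop_stability,
    centrality_difference_test,
    edge_difference_test,
)
from clpnet.synthetic import build_ground_truth, default_ground_truth, simulate_panel
from clpnet.types import CESD8_ITEMS


@pytest.fixture(scope="module")
def boot():
    """Small bootstrap distribution on a spec with one strong and one null
    cross-lagged path (fixed-penalty refits keep this quick)."""
    spec = build_ground_truth({
        "n_waves": 2, "autoregressive": 1.0,
        "edges": [("effort", "get_going", 1.2), ("lonely", "sad", 0.8)],
    })
    panel = simulate_panel(spec, 4000, seed=19)
    dist, ci = bootstrap_edges(panel, 1, B=100, seed=19, refit_penalty="fixed")
    return dist, ci


def test_contracts_and_determinism():
    """Same-seed bootstrap is bit-reproducible; self-differences are never
    significant; the case-drop correlation at drop 0 is identically 1."""
    from clpnet.validation import resampling_checks

    res = resampling_checks(n=400, B=20)
    assert res["same_seed_max_abs_diff"] == 0.0
    assert res["self_difference_significant"] == 0
    assert res["casedrop_zero_correlation"] == 1.0


def test_ci_brackets_estimate_and_or_view(boot):
    dist, ci = boot
    assert dist.n_completed == 100
    assert (ci.ci_low <= ci.estimate).all() and (ci.estimate <= ci.ci_high).all()
    assert np.allclose(ci.or_ci_low, np.exp(ci.ci_low))


def test_ci_width_shrinks_with_sample_size():
    """Average per-edge CI width at n = 3,000 is below that at n = 500 for
    data from the same spec (scaled paired design)."""
    spec = default_ground_truth(seed=23, n_waves=2)
    widths = {}
    for n in (500, 3000):
        panel = simulate_panel(spec, n, seed=23)
        _, ci = bootstrap_edges(panel, 1, B=40, seed=23, refit_penalty="fixed")
        widths[n] = (ci.ci_high - ci.ci_low).mean()
    assert widths[3000] < widths[500]


def test_edge_difference_strong_vs_null(boot):
    dist, _ = boot
    res = edge_difference_test(dist)
    labels = list(res.labels)
    strong = labels.index("effort->get_going")
    null = labels.index("depressed->happy")
    assert res.significant[strong, null]
    assert np.array_equal(res.significant, res.significant.T)
    assert not res.significant.diagonal().any()
    # the difference of an edge with itself is identically zero
    assert res.ci_low[strong, strong] == 0.0 == res.ci_high[strong, strong]


def test_centrality_difference(boot):
    dist, _ = boot
    res = centrality_difference_test(dist, index="out")
    labels = list(res.labels)
    # 'lonely' has true out-EI 0.8; 'happy' has 0
    assert res.significant[labels.index("lonely"), labels.index("happy")]
    assert not res.significant.diagonal().any()
    with pytest.raises(ValueError):
        centrality_difference_test(dist, index="total")


def test_casedrop_stable_under_strong_signal():
    """Well-separated spec at moderate n: dropping 30% of cases keeps the
    centrality order correlated >= 0.7 in >= 95% of subsamples."""
    spec = default_ground_truth(seed=29, n_waves=2)
    panel = simulate_panel(spec, 4000, seed=29)
    stab = casedrop_stability(panel, 1, proportions=(0.3,), B=20, seed=29)
    assert stab.cs_in == 0.3
    assert stab.cs_out == 0.3
    assert np.nanmean(stab.correlations_in[0]) > 0.8


def test_casedrop_unstable_under_noise():
    """Null transition structure at small n: the centrality order does not
    survive case dropping (CS-coefficient 0)."""
    spec = build_ground_truth({"n_waves": 2, "autoregressive": 0.8})
    panel = simulate_panel(spec, 300, seed=31)
    stab = casedrop_stability(panel, 1, proportions=(0.3,), B=15, seed=31)
    assert stab.cs_in <= 0.25
    assert stab.cs_out <= 0.25


def test_bad_arguments():
    spec = default_ground_truth(seed=1, n_waves=2)
    panel = simulate_panel(spec, 200, seed=1)
    with pytest.raises(ValueError, match="B must be"):
        bootstrap_edges(panel, 1, B=1)
    with pytest.raises(ValueError, match="refit_penalty"):
        bootstrap_edges(panel, 1, B=2, refit_penalty="warm")
    with pytest.raises(ValueError, match="proportions"):
        casedrop_stability(panel, 1, proportions=(1.0,), B=2)


def test_edge_ci_coverage_under_min_rule():
    """Percentile CI for a true edge of 1.0 log-odds, penalty re-selected
    per replicate under the low-shrinkage "min" CV rule.  Scaled design
    (12 experiments, n = 2,500, B = 30); the assertion is the 3-sigma
    binomial envelope around the 85% working coverage that lasso
    shrinkage permits (the sparser "1se" default trades this coverage
    for false-positive control)."""
    reps, target = 12, 0.85
    hits = 0
    for r in range(reps):
        spec = build_ground_truth({
            "n_waves": 2, "autoregressive": 1.0,
            "edges": [("effort", "get_going", 1.0)], "seed": r,
        })
        panel = simulate_panel(spec, 2500, seed=100 + r)
        _, ci = bootstrap_edges(panel, 1, B=30, seed=r, refit_penalty="reselect",
                                selection_rule="min", n_lambdas=25)
        row = ci[(ci.predictor == "effort") & (ci.outcome == "get_going")].iloc[0]
        hits += row.ci_low <= 1.0 <= row.ci_high
    envelope = 3 * np.sqrt(target * (1 - target) / reps)
    assert hits / reps >= target - envelope
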