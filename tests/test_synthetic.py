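"""Generator contracts: calibration, determinism, attrition behaviour."""

import numpy as np
import pytest
from scipy.special import logit

from clpnet import build_ground_truth, simulate_panel
from clpnet.synthetic import STUDY_ENDORSEMENT_PCT, apply_attrition, default_ground_truth
from clpnet.types import CESD8_ITEMS, GroundTruthSpec


def test_intercepts_solve_logit_of_target():
    spec = build_ground_truth({"endorsement": 0.2})
    assert spec.transition_intercepts == pytest.approx(logit(0.2), abs=1e-10)
    assert spec.wave1_intercepts == pytest.approx(np.full(8, -1.3862944), abs=1e-6)


def test_wave1_prevalence_matches_study_targets():
    """Wave-1 intercepts reproduce the published endorsement column even
    with covariate effects present (integrated out exactly)."""
    spec = default_ground_truth(seed=3, n_waves=2)
    panel = simulate_panel(spec, 50000, seed=3)
    endorsement = panel.items[:, 0, :].mean(axis=0)
    targets = STUDY_ENDORSEMENT_PCT[:, 0] / 100
    se = np.sqrt(targets * (1 - targets) / 50000)
    assert np.all(np.abs(endorsement - targets) < 3.5 * se)


def test_marginal_recovery_under_null_transitions():
    """With B = 0 every wave's endorsement stays at the intercept-implied rate."""
    spec = build_ground_truth({"endorsement": 0.2, "n_waves": 4})
    panel = simulate_panel(spec, 20000, seed=5)
    p = panel.items.mean(axis=0)  # (W, K)
    se = np.sqrt(0.2 * 0.8 / 20000)
    assert np.all(np.abs(p - 0.2) < 4 * se)


def test_edge_list_places_entries():
    spec = build_ground_truth({"edges": [("effort", "get_going", 0.8)]})
    i, j = CESD8_ITEMS.index("effort"), CESD8_ITEMS.index("get_going")
    assert spec.B[i, j] == 0.8
    assert np.count_nonzero(spec.B) == 1


def test_rejects_bad_inputs():
    with pytest.raises(ValueError, match="outside"):
        build_ground_truth({"endorsement": 1.2})
    with pytest.raises(ValueError, match="square"):
        spec = build_ground_truth({})
        GroundTruthSpec(**{**vars(spec), "B": np.zeros((8, 7))})
    with pytest.raises(ValueError):
        simulate_panel(build_ground_truth({}), 0)


def test_seed_determinism_bit_identical():
    spec = default_ground_truth(seed=9, n_waves=4)
    a = simulate_panel(spec, 300, seed=9)
    b = simulate_panel(spec, 300, seed=9)
    assert np.array_equal(a.items, b.items)
    assert np.array_equal(a.covariates, b.covariates)
    aa = apply_attrition(a, spec, seed=9)
    bb = apply_attrition(b, spec, seed=9)
    assert np.array_equal(aa.observed, bb.observed)
    # different seed actually changes the draw
    c = simulate_panel(spec, 300, seed=10)
    assert not np.array_equal(a.items, c.items)


def test_lag1_autoregression_recovers_log_odds_ratio():
    """Diagonal B = 3 and no cross paths: the 2x2 lag-1 table of each item
    has a log odds ratio of ~3 (hand-computed contingency oracle)."""
    spec = build_ground_truth({
        "endorsement": 0.3, "autoregressive": 3.0, "n_waves": 2,
        "center_transitions": False,
    })
    panel = simulate_panel(spec, 50000, seed=21)
    x0, x1 = panel.items[:, 0, 0], panel.items[:, 1, 0]
    n11 = np.sum((x0 == 1) & (x1 == 1))
    n10 = np.sum((x0 == 1) & (x1 == 0))
    n01 = np.sum((x0 == 0) & (x1 == 1))
    n00 = np.sum((x0 == 0) & (x1 == 0))
    log_or = np.log(n11 * n00 / (n10 * n01))
    se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
    assert abs(log_or - 3.0) < 3.5 * se
    # agreement far above the independence baseline
    agree = np.mean(x0 == x1)
    p0, p1 = x0.mean(), x1.mean()
    baseline = p0 * p1 + (1 - p0) * (1 - p1)
    assert agree > baseline + 0.1


class TestAttrition:
    def test_zero_hazard_leaves_panel_unchanged(self):
        spec = default_ground_truth(seed=2, n_waves=4)
        spec.attrition_intercept = -30.0
        spec.attrition_covariate_coefs[:] = 0
        spec.attrition_sumscore_coef = 0.0
        panel = simulate_panel(spec, 500, seed=2)
        out = apply_attrition(panel, spec, seed=2)
        assert out.observed.all()
        assert np.array_equal(out.items, panel.items)

    def test_constant_hazard_geometric_survival(self):
        spec = build_ground_truth({
            "n_waves": 9,
            "attrition_intercept": float(logit(0.10)),
        })
        panel = simulate_panel(spec, 50000, seed=13)
        out = apply_attrition(panel, spec, seed=13)
        retained = out.retained_per_wave()
        expected = 0.9**8
        se = np.sqrt(expected * (1 - expected) / 50000)
        assert abs(retained[-1] / 50000 - expected) < 3.5 * se
        assert out.is_monotone()
        assert np.all(np.diff(retained) <= 0)

    def test_severity_predicts_dropout(self):
        """Positive sum-score hazard coefficient: dropouts between waves 1-2
        were more symptomatic at wave 1 than continuers."""
        spec = default_ground_truth(seed=4, n_waves=3)
        panel = simulate_panel(spec, 20000, seed=4)
        out = apply_attrition(panel, spec, seed=4)
        from clpnet import sum_scores

        base = sum_scores(panel)[:, 0]
        present_w2 = out.observed[:, 1, :].all(axis=1)
        assert base[~present_w2].mean() > base[present_w2].mean()

    def test_requires_fully_observed_input(self, attrited_panel):
        spec = default_ground_truth(seed=11, n_waves=5)
        with pytest.raises(ValueError, match="fully observed"):
            apply_attrition(attrited_panel, spec, seed=1)
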