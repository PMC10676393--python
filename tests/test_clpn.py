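"""CLPN assembly, OR transform and expected-influence centrality."""

import numpy as np
import pytest

from clpnet import expected_influence, fit_clpn, simulate_panel, to_odds_ratio
from clpnet.synthetic import build_ground_truth
from clpnet.types import CESD8_ITEMS, CLPNetwork


def _toy_network(coef, items=("a", "b", "c"), cov_rows=()):
    coef = np.asarray(coef, dtype=float)
    preds = tuple(items) + tuple(f"cov{i}" for i in range(len(cov_rows)))
    return CLPNetwork(
        predictor_labels=preds,
        outcome_labels=tuple(items),
        coef=coef,
        intercepts=np.zeros(len(items)),
        penalties=np.zeros(len(items)),
        n=100,
        covariate_rows=tuple(cov_rows),
    )


def test_fit_shape_includes_covariates(small_panel):
    net = fit_clpn(small_panel, 1, seed=0)
    assert net.coef.shape == (10, 8)
    assert net.covariate_rows == (8, 9)
    assert net.predictor_labels[:8] == CESD8_ITEMS
    assert net.label == "t1_t2"
    no_cov = fit_clpn(small_panel, 1, covariates=False, seed=0)
    assert no_cov.coef.shape == (8, 8)


def test_fit_rejects_last_wave(small_panel):
    with pytest.raises(ValueError, match="successor"):
        fit_clpn(small_panel, small_panel.wave_labels[-1])


class TestOddsRatio:
    def test_scalar_mappings(self):
        net = _toy_network([[0.0, np.log(2), -np.log(2)], [0, 0, 0], [0, 0, 0]])
        orv = to_odds_ratio(net)
        assert orv.scale == "or"
        assert orv.coef[0] == pytest.approx([1.0, 2.0, 0.5])
        # original untouched
        assert net.scale == "log_odds"
        assert net.coef[0, 0] == 0.0

    def test_round_trip_duality(self, rng):
        coef = rng.normal(0, 0.5, (3, 3))
        net = _toy_network(coef)
        back = np.log(to_odds_ratio(net).coef)
        assert np.allclose(back, coef)

    def test_rejects_or_scale_input(self):
        net = _toy_network(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            to_odds_ratio(to_odds_ratio(net))


class TestExpectedInfluence:
    def test_empty_network(self):
        ei = expected_influence(_toy_network(np.zeros((3, 3))))
        assert np.all(ei.in_ei == 0) and np.all(ei.out_ei == 0)
        assert np.all(ei.in_ei_z == 0)

    def test_hand_summed_toy(self):
        # edges: a->b 0.5, a->c 0.3, b->a -0.2, autoregressive a->a 1.0
        coef = np.array([
            [1.0, 0.5, 0.3],
            [-0.2, 0.0, 0.0],
            [0.0, 0.0, 0.0],
        ])
        ei = expected_influence(_toy_network(coef))
        assert ei.out_ei == pytest.approx([0.8, -0.2, 0.0])
        assert ei.in_ei == pytest.approx([-0.2, 0.5, 0.3])

    def test_matches_brute_force_and_excludes_covariates(self, rng):
        k = 8
        coef = np.zeros((k + 2, k))
        mask = rng.random((k, k)) < 0.3
        coef[:k][mask] = rng.normal(0, 0.6, mask.sum())
        coef[k:] = rng.normal(0, 0.4, (2, k))  # covariate rows, must be ignored
        net = _toy_network(coef, items=tuple("abcdefgh"), cov_rows=(k, k + 1))
        ei = expected_influence(net)
        for j in range(k):
            in_expected = sum(coef[i, j] for i in range(k) if i != j)
            out_expected = sum(coef[j, i] for i in range(k) if i != j)
            assert ei.in_ei[j] == pytest.approx(in_expected)
            assert ei.out_ei[j] == pytest.approx(out_expected)
        # grand-sum identity and z standardization
        assert ei.in_ei.sum() == pytest.approx(ei.out_ei.sum())
        assert ei.in_ei_z.mean() == pytest.approx(0, abs=1e-12)
        assert ei.in_ei_z.std() == pytest.approx(1, abs=1e-12)

    def test_requires_log_odds_scale(self):
        net = to_odds_ratio(_toy_network(np.zeros((3, 3))))
        with pytest.raises(ValueError, match="log-odds"):
            expected_influence(net)


def test_single_edge_support_recovery():
    """A lone cross-lagged path of 1.0 log-odds is detected with the right
    sign at n = 10,000, and the coefficient is within shrinkage range."""
    spec = build_ground_truth({
        "n_waves": 2, "autoregressive": 1.0,
        "edges": [("effort", "get_going", 1.0)],
    })
    panel = simulate_panel(spec, 10000, seed=17)
    net = fit_clpn(panel, 1, seed=17)
    i, j = CESD8_ITEMS.index("effort"), CESD8_ITEMS.index("get_going")
    est = net.item_matrix()[i, j]
    assert est > 0.3
    # autoregressive paths survive on the diagonal
    assert np.all(np.diag(net.item_matrix()) > 0.3)
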