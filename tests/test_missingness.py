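"""MCAR testing, dropout modelling and chained-equations imputation."""

import numpy as np
import pandas as pd
import pytest

from clpnet import dropout_model, impute_chained, little_mcar_test, simulate_panel
from clpnet.missingness import panel_to_wide_matrix
from clpnet.synthetic import apply_attrition, build_ground_truth, default_ground_truth


class TestLittleMCAR:
    def test_complete_data_trivial(self, rng):
        y = rng.standard_normal((200, 4))
        res = little_mcar_test(y)
        assert res.d2 == pytest.approx(0.0, abs=1e-6)
        assert res.df == 0
        assert np.isnan(res.p_value)
        assert res.n_patterns == 1

    def test_type_one_error_under_mcar(self):
        """Nominal rejection near 5% under MCAR normal data (quick check;
        the full 500-replicate calibration runs in the acceptance suite)."""
        from clpnet.validation import mcar_rejection_rate

        res = mcar_rejection_rate(n_reps=100, n=1000, seed=1)
        # 99.9% binomial envelope around 0.05 at 100 replicates
        assert res["rejection_rate_pct"] <= 13.0

    def test_power_against_mar(self):
        """Missingness triggered by an observed variable is detected."""
        rng = np.random.default_rng(9)
        n = 2000
        y = rng.standard_normal((n, 4))
        y[:, 1] += 0.5 * y[:, 0]
        mask = (y[:, 0] > 0) & (rng.random(n) < 0.6)
        y[mask, 1] = np.nan
        res = little_mcar_test(y)
        assert res.p_value < 0.001
        assert res.df > 0

    def test_df_accounting(self):
        y = np.array([[1.0, 2.0, 0.5], [2.0, np.nan, 1.0], [0.0, 1.0, np.nan],
                      [1.5, 2.5, 0.0], [0.5, 1.5, 1.0], [2.5, 0.5, np.nan]])
        res = little_mcar_test(y)
        # patterns: complete (3 vars), miss-var2 (2), miss-var3 (2) -> df = 7 - 3
        assert res.df == 4
        assert res.n_patterns == 3


class TestDropoutModel:
    def test_recovers_severity_effect(self):
        spec = default_ground_truth(seed=6, n_waves=4)
        panel = apply_attrition(simulate_panel(spec, 10000, seed=6), spec, seed=6)
        table = dropout_model(panel)
        row = table[table.predictor == "baseline_sum_score"].iloc[0]
        assert row.coef > 0
        assert row.p_value < 0.05
        assert not row.separation

    def test_no_events_errors(self, small_panel):
        with pytest.raises(ValueError, match="no events"):
            dropout_model(small_panel)


class TestImputeChained:
    def test_complete_panel_unchanged(self, small_panel):
        out = impute_chained(small_panel, seed=0, n_iterations=2)
        assert np.array_equal(out.items, small_panel.items)
        assert out.observed.all()

    def test_observed_never_altered_and_binary(self, attrited_panel):
        out = impute_chained(attrited_panel, seed=3, n_iterations=3)
        assert out.observed.all()
        obs = attrited_panel.observed
        assert np.array_equal(out.items[obs], attrited_panel.items[obs])
        assert np.all(np.isin(out.items, (0, 1)))

    def test_seeded_reproducibility(self, attrited_panel):
        a = impute_chained(attrited_panel, seed=5, n_iterations=2)
        b = impute_chained(attrited_panel, seed=5, n_iterations=2)
        assert np.array_equal(a.items, b.items)

    def test_mcar_marginal_preserved(self):
        """20% MCAR on a known-prevalence panel: post-imputation endorsement
        within 2 points of the complete-data value (n = 10,000)."""
        spec = build_ground_truth({"endorsement": 0.3, "autoregressive": 1.0,
                                   "n_waves": 1})
        panel = simulate_panel(spec, 10000, seed=12)
        complete_rate = panel.items[:, 0, :].mean(axis=0)
        rng = np.random.default_rng(12)
        holey = panel.copy()
        holey.observed[rng.random(holey.observed.shape) < 0.2] = False
        holey.items[~holey.observed] = 0
        out = impute_chained(holey, seed=12, n_iterations=5)
        imputed_rate = out.items[:, 0, :].mean(axis=0)
        assert np.abs(imputed_rate - complete_rate).max() < 0.02

    def test_auxiliary_reduces_mar_bias(self):
        """MAR on an observed auxiliary: including the auxiliary in the
        chained equations shrinks the endorsement bias (paired design)."""
        rng = np.random.default_rng(30)
        n = 4000
        z = (rng.random(n) < 0.5).astype(float)
        p_x = 0.15 + 0.45 * z
        x = (rng.random(n) < p_x).astype(np.uint8)
        y = (rng.random(n) < 0.4).astype(np.uint8)
        items = np.stack([x, y], axis=1)[:, None, :]
        observed = np.ones_like(items, dtype=bool)
        miss = rng.random(n) < np.where(z == 1, 0.6, 0.05)
        observed[miss, 0, 0] = False
        from clpnet.types import PanelDataset

        panel = PanelDataset(
            subject_ids=np.arange(n), items=items, observed=observed,
            covariates=np.zeros((n, 0), dtype=np.uint8),
            item_labels=("x", "y"), wave_labels=(1,), covariate_labels=(),
        )
        panel.items[~panel.observed] = 0
        truth = x.mean()
        with_aux = impute_chained(panel, auxiliaries=pd.DataFrame({"z": z}),
                                  seed=1, n_iterations=5)
        without = impute_chained(panel, seed=1, n_iterations=5)
        bias_with = abs(with_aux.items[:, 0, 0].mean() - truth)
        bias_without = abs(without.items[:, 0, 0].mean() - truth)
        assert bias_with < bias_without

    def test_unobserved_variable_errors(self, small_panel):
        holey = small_panel.copy()
        holey.observed[:, 0, 0] = False
        holey.items[~holey.observed] = 0
        with pytest.raises(ValueError, match="no observed values"):
            impute_chained(holey)


def test_wide_matrix_layout(attrited_panel):
    mat, names = panel_to_wide_matrix(attrited_panel)
    assert mat.shape == (attrited_panel.n_subjects,
                         attrited_panel.n_waves * attrited_panel.n_items)
    assert names[0] == "w1_depressed"
    assert np.isnan(mat).sum() == (~attrited_panel.observed).sum()
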