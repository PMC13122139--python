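import numpy as np
import pandas as pd
import pytest
from itertools import permutations
from scipy.special import expit, logit

from dhdrisk import (
    breakdown_attributions,
    ceteris_paribus,
    partial_dependence,
    permutation_importance,
    shapley_attributions,
)
from dhdrisk.cohort_prep import CohortMatrix
from dhdrisk.risk_models import predict_risk
from tests.conftest import make_function_model, make_lr_model


def make_matrix(features: pd.DataFrame, outcome) -> CohortMatrix:
    n = len(features)
    return CohortMatrix(
        features=features,
        outcome=np.asarray(outcome, int),
        protected=pd.DataFrame(index=range(n)),
        patient_id=np.arange(n).astype(str),
        admission_date=np.full(n, np.datetime64("2015-01-01")),
    )


@pytest.fixture
def random_data():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(
        {
            "a": rng.integers(0, 2, 2000).astype(float),
            "b": rng.integers(0, 2, 2000).astype(float),
            "c": rng.normal(size=2000),
        }
    )
    return x


class TestPermutationImportance:
    def test_single_feature_model_loses_all_signal(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame({"a": rng.normal(size=3000)})
        y = (rng.random(3000) < expit(3.0 * x["a"])).astype(int)
        model = make_lr_model({"a": 3.0}, 0.0)
        data = make_matrix(x, y)
        imp = permutation_importance(model, data, n_repeats=10, seed=2)
        baseline = imp.attrs["baseline_auc"]
        assert imp.loc["a", "importance"] == pytest.approx(
            baseline - 0.5, abs=0.05
        )

    def test_ignored_feature_has_null_importance(self, random_data):
        y = (np.random.default_rng(3).random(2000) < 0.5).astype(int)
        model = make_lr_model({"a": 2.0, "b": 0.0, "c": 0.0}, 0.0)
        y = (np.random.default_rng(4).random(2000)
             < expit(2.0 * random_data["a"])).astype(int)
        imp = permutation_importance(
            model, make_matrix(random_data, y), n_repeats=10, seed=5
        )
        assert abs(imp.loc["b", "importance"]) < 0.005
        assert abs(imp.loc["c", "importance"]) < 0.005

    def test_reproducible_under_seed(self, random_data):
        y = (np.arange(2000) % 2).astype(int)
        model = make_lr_model({"a": 1.0, "b": -1.0, "c": 0.5}, 0.0)
        data = make_matrix(random_data, y)
        a = permutation_importance(model, data, n_repeats=3, seed=7)
        b = permutation_importance(model, data, n_repeats=3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_single_repeat(self, random_data):
        model = make_lr_model({"a": 1.0, "b": 1.0, "c": 1.0}, 0.0)
        with pytest.raises(ValueError):
            permutation_importance(
                model,
                make_matrix(random_data, np.arange(2000) % 2),
                n_repeats=1,
            )


class TestProfiles:
    def test_pdp_flat_for_ignored_feature(self, random_data):
        model = make_lr_model({"a": 1.5, "b": 0.0, "c": 0.0}, -0.5)
        data = make_matrix(random_data, np.arange(2000) % 2)
        prof = partial_dependence(model, data, "b", np.array([0.0, 1.0]))
        assert prof.predictions[0] == pytest.approx(prof.predictions[1], abs=1e-12)
        assert prof.grid.size == 2

    def test_pdp_equals_direct_row_average(self, random_data):
        model = make_lr_model({"a": 1.0, "b": -2.0, "c": 0.7}, 0.2)
        data = make_matrix(random_data, np.arange(2000) % 2)
        prof = partial_dependence(model, data, "b", np.array([0.0, 1.0]))
        for k, g in enumerate((0.0, 1.0)):
            x = random_data.copy()
            x["b"] = g
            assert prof.predictions[k] == pytest.approx(
                predict_risk(model, x).mean(), abs=1e-12
            )

    def test_pdp_of_flag_equals_mean_ceteris_paribus_endpoints(self, random_data):
        model = make_lr_model({"a": 0.8, "b": -1.1, "c": 0.3}, 0.0)
        data = make_matrix(random_data.head(50), np.arange(50) % 2)
        prof = partial_dependence(model, data, "a", np.array([0.0, 1.0]))
        cp_ends = np.array(
            [
                ceteris_paribus(
                    model, data.features.iloc[i], "a", np.array([0.0, 1.0])
                ).predictions
                for i in range(50)
            ]
        )
        np.testing.assert_allclose(prof.predictions, cp_ends.mean(axis=0))

    def test_ceteris_paribus_flag_flip_shifts_log_odds_by_coefficient(self):
        model = make_lr_model({"a": 1.3, "b": 0.4}, -0.7)
        inst = pd.Series({"a": 0.0, "b": 1.0})
        prof = ceteris_paribus(model, inst, "a", np.array([0.0, 1.0]))
        gap = logit(prof.predictions[1]) - logit(prof.predictions[0])
        assert gap == pytest.approx(1.3, abs=1e-9)

    def test_ceteris_paribus_endpoints_match_direct_predictions(self):
        model = make_lr_model({"a": 1.0, "b": -0.5}, 0.1)
        inst = pd.Series({"a": 0.0, "b": 2.0})
        prof = ceteris_paribus(model, inst, "a", np.array([0.0, 1.0]))
        for k, g in enumerate((0.0, 1.0)):
            x = pd.DataFrame([{"a": g, "b": 2.0}])
            assert prof.predictions[k] == pytest.approx(
                predict_risk(model, x)[0], abs=1e-12
            )

    def test_empty_data_rejected(self, random_data):
        model = make_lr_model({"a": 1.0, "b": 1.0, "c": 1.0}, 0.0)
        empty = make_matrix(random_data.iloc[:0], np.array([], int))
        with pytest.raises(ValueError):
            partial_dependence(model, empty, "a", np.array([0.0, 1.0]))


def _background(rng, names, n=30):
    return pd.DataFrame(
        {name: rng.integers(0, 2, n).astype(float) for name in names}
    )


class TestShapley:
    def test_additive_model_attributions_are_marginal_effects(self):
        # f(x) = 0.1 + 0.2 a + 0.3 b is additive on the prediction scale
        model = make_function_model(
            lambda x: 0.1 + 0.2 * x[:, 0] + 0.3 * x[:, 1], ["a", "b"]
        )
        rng = np.random.default_rng(0)
        bg = _background(rng, ["a", "b"])
        inst = pd.Series({"a": 1.0, "b": 0.0})
        row = shapley_attributions(model, inst, bg, mode="exact")
        assert row.contributions["a"] == pytest.approx(
            0.2 * (1.0 - bg["a"].mean()), abs=1e-12
        )
        assert row.contributions["b"] == pytest.approx(
            0.3 * (0.0 - bg["b"].mean()), abs=1e-12
        )

    def test_exact_matches_independent_permutation_enumeration(self, small_cohort):
        from dhdrisk import tune_and_fit

        cohort, _, _ = small_cohort
        sub = cohort.subset(np.arange(len(cohort)) < 2000)
        feats = ["age", "com_dementia", "hist_care_support"]
        small = make_matrix(sub.features[feats].copy(), sub.outcome)
        model = tune_and_fit(
            small, "GBT", grid={"max_depth": [2], "n_estimators": [20]}, seed=1
        )
        bg = small.features.head(25)
        inst = small.features.iloc[100]
        row = shapley_attributions(model, inst, bg, mode="exact")

        # independent oracle: average marginal contributions over all 3!
        # orders, with the value function recomputed from raw predictions
        def value(fixed):
            x = bg.copy()
            for f in fixed:
                x[f] = inst[f]
            return predict_risk(model, x).mean()

        phi = {f: 0.0 for f in feats}
        for order in permutations(feats):
            fixed = []
            prev = value(fixed)
            for f in order:
                fixed.append(f)
                cur = value(fixed)
                phi[f] += (cur - prev) / 6.0
                prev = cur
        for f in feats:
            assert row.contributions[f] == pytest.approx(phi[f], abs=1e-10)

    def test_local_accuracy_exact_and_sampled(self):
        rng = np.random.default_rng(2)
        names = list("abcde")
        model = make_function_model(
            lambda x: expit(x[:, 0] - 2 * x[:, 1] + x[:, 2] * x[:, 3]), names
        )
        bg = _background(rng, names)
        inst = pd.Series(dict(zip(names, [1.0, 0.0, 1.0, 1.0, 0.0])))
        exact = shapley_attributions(model, inst, bg, mode="exact")
        assert exact.total() == pytest.approx(exact.prediction, abs=1e-10)
        sampled = shapley_attributions(
            model, inst, bg, mode="sampled", n_samples=50, seed=3
        )
        assert sampled.total() == pytest.approx(sampled.prediction, abs=1e-10)

    def test_sampled_converges_to_exact(self):
        rng = np.random.default_rng(4)
        names = list("abcde")
        model = make_function_model(
            lambda x: expit(
                0.5 * x[:, 0] - x[:, 1] + 2 * x[:, 2] * x[:, 3] - 0.3 * x[:, 4]
            ),
            names,
        )
        bg = _background(rng, names, n=20)
        inst = pd.Series(dict(zip(names, [1.0, 1.0, 1.0, 0.0, 1.0])))
        exact = shapley_attributions(model, inst, bg, mode="exact")
        sampled = shapley_attributions(
            model, inst, bg, mode="sampled", n_samples=10_000, seed=5
        )
        for f in names:
            assert sampled.contributions[f] == pytest.approx(
                exact.contributions[f], abs=0.01
            )

    def test_symmetric_features_get_equal_attributions(self):
        names = ["a", "b"]
        model = make_function_model(lambda x: expit(x[:, 0] + x[:, 1]), names)
        bg = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0], "b": [0.0, 0.0, 1.0, 1.0]})
        inst = pd.Series({"a": 1.0, "b": 1.0})
        row = shapley_attributions(model, inst, bg, mode="exact")
        assert row.contributions["a"] == pytest.approx(
            row.contributions["b"], abs=1e-12
        )

    def test_exact_mode_feature_limit(self):
        names = [f"f{i}" for i in range(13)]
        model = make_function_model(lambda x: np.full(x.shape[0], 0.5), names)
        bg = pd.DataFrame(np.zeros((5, 13)), columns=names)
        with pytest.raises(ValueError, match="sampled"):
            shapley_attributions(
                model, pd.Series(dict.fromkeys(names, 0.0)), bg, mode="exact"
            )


class TestBreakdown:
    def test_additive_model_breakdown_is_order_invariant(self):
        model = make_function_model(
            lambda x: 0.2 + 0.1 * x[:, 0] + 0.25 * x[:, 1], ["a", "b"]
        )
        bg = _background(np.random.default_rng(6), ["a", "b"])
        inst = pd.Series({"a": 1.0, "b": 1.0})
        shap = shapley_attributions(model, inst, bg, mode="exact")
        for order in (["a", "b"], ["b", "a"]):
            bd = breakdown_attributions(model, inst, bg, order=order)
            for f in ("a", "b"):
                assert bd.contributions[f] == pytest.approx(
                    shap.contributions[f], abs=1e-12
                )

    def test_interaction_model_orders_differ_but_sums_agree(self):
        model = make_function_model(lambda x: 0.1 + 0.6 * x[:, 0] * x[:, 1], ["a", "b"])
        bg = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        inst = pd.Series({"a": 1.0, "b": 1.0})
        ab = breakdown_attributions(model, inst, bg, order=["a", "b"])
        ba = breakdown_attributions(model, inst, bg, order=["b", "a"])
        assert ab.contributions["a"] != pytest.approx(ba.contributions["a"])
        assert sum(ab.contributions.values()) == pytest.approx(
            sum(ba.contributions.values()), abs=1e-12
        )
        assert ab.total() == pytest.approx(ab.prediction, abs=1e-12)

    def test_auto_order_is_decreasing_single_fix_effect(self):
        model = make_function_model(
            lambda x: 0.3 + 0.05 * x[:, 0] + 0.4 * x[:, 1], ["weak", "strong"]
        )
        bg = pd.DataFrame({"weak": [0.0, 0.0], "strong": [0.0, 0.0]})
        inst = pd.Series({"weak": 1.0, "strong": 1.0})
        bd = breakdown_attributions(model, inst, bg, order="auto")
        assert list(bd.contributions) == ["strong", "weak"]

    def test_duplicate_order_rejected(self):
        model = make_function_model(lambda x: x[:, 0], ["a", "b"])
        bg = pd.DataFrame({"a": [0.0], "b": [0.0]})
        with pytest.raises(ValueError, match="duplicate"):
            breakdown_attributions(
                model, pd.Series({"a": 1.0, "b": 1.0}), bg, order=["a", "a"]
            )
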