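import numpy as np
import pandas as pd
import pytest

from dhdrisk import (
    SyntheticConfig,
    apply_exclusions,
    build_lookback_features,
    dichotomize_onmarg,
    generate_admissions,
    rebalance_training,
    split_by_patient,
    temporal_split,
)
from dhdrisk.cohort_prep import engineer_features
from tests.conftest import make_admission_row


class TestApplyExclusions:
    def test_hand_fixture_rule_by_rule_tally(self):
        rows = (
            [make_admission_row(patient_id=f"A{i}", age=64) for i in range(2)]
            + [make_admission_row(patient_id="B", from_ltc=1)]
            + [make_admission_row(patient_id="C", onmarg=(2, 3, np.nan, 1))]
            + [make_admission_row(patient_id=f"D{i}") for i in range(6)]
        )
        clean, tally = apply_exclusions(pd.DataFrame(rows))
        assert (
            tally.removed_age,
            tally.removed_ltc,
            tally.removed_missing,
        ) == (2, 1, 1)
        assert tally.retained == len(clean) == 6

    def test_all_valid_is_identity(self):
        df = pd.DataFrame([make_admission_row(patient_id=f"P{i}") for i in range(5)])
        clean, tally = apply_exclusions(df)
        assert tally.removed == 0 and tally.retained == 5
        pd.testing.assert_frame_equal(clean, df)

    def test_empty_input_zero_tally(self):
        df = pd.DataFrame([make_admission_row()]).iloc[:0]
        clean, tally = apply_exclusions(df)
        assert len(clean) == 0
        assert (tally.removed, tally.retained) == (0, 0)

    def test_double_violation_counted_under_first_rule(self):
        df = pd.DataFrame([make_admission_row(age=60, from_ltc=1)])
        _, tally = apply_exclusions(df)
        assert tally.removed_age == 1 and tally.removed_ltc == 0

    def test_tally_conservation(self, small_cohort):
        _, _, clean = small_cohort
        # re-run on a raw draw with contamination
        cfg = SyntheticConfig(n_patients=800, seed=17)
        df, _ = generate_admissions(cfg)
        _, tally = apply_exclusions(df)
        assert tally.removed + tally.retained == len(df)


class TestLookback:
    def _patient(self, events):
        """events: list of (date, flags) tuples for one patient."""
        return pd.DataFrame(
            [
                make_admission_row(
                    patient_id="P1", admission_date=d, flags=f
                )
                for d, f in events
            ]
        )

    def test_event_outside_window_ignored(self):
        df = self._patient(
            [("2010-01-01", ("fall",)), ("2012-03-15", ())]  # 803 days apart
        )
        feats = engineer_features(df, window_days=730)
        assert feats.loc[1, "hist_fall"] == 0

    def test_event_inside_window_counted(self):
        df = self._patient([("2012-01-01", ("fall",)), ("2012-04-10", ())])
        feats = engineer_features(df)
        assert feats.loc[1, "hist_fall"] == 1
        # strictly prior: the fall on the index row itself does not count
        assert feats.loc[0, "hist_fall"] == 0

    def test_union_of_flags_across_prior_admissions(self):
        df = self._patient(
            [
                ("2012-01-01", ("fall",)),
                ("2012-06-01", ("fracture",)),
                ("2012-12-01", ()),
            ]
        )
        feats = engineer_features(df)
        assert feats.loc[2, "hist_fall"] == 1
        assert feats.loc[2, "hist_fracture"] == 1

    def test_comorbidity_counts_index_admission(self):
        df = self._patient([("2012-01-01", ("dementia",))])
        feats = engineer_features(df)
        assert feats.loc[0, "com_dementia"] == 1

    def test_invariant_to_row_order(self):
        cfg = SyntheticConfig(
            n_patients=100, mean_admissions_per_patient=4.0, seed=23
        )
        df, _ = generate_admissions(cfg)
        feats = engineer_features(df)
        perm = np.random.default_rng(0).permutation(len(df))
        feats_perm = engineer_features(df.iloc[perm])
        np.testing.assert_array_equal(
            feats.to_numpy()[perm], feats_perm.to_numpy()
        )

    def test_rejects_nonpositive_window(self):
        df = self._patient([("2012-01-01", ())])
        with pytest.raises(ValueError, match="window"):
            engineer_features(df, window_days=0)

    def test_build_rejects_uncleaned_rows(self):
        df = pd.DataFrame([make_admission_row(age=60)])
        with pytest.raises(ValueError, match="under-65"):
            build_lookback_features(df)


@pytest.mark.parametrize(
    "quintile,expected", [(5, 1), (4, 0), (1, 0)]
)
def test_dichotomize_onmarg(quintile, expected):
    assert dichotomize_onmarg(quintile) == expected


def test_dichotomize_rejects_out_of_range():
    with pytest.raises(ValueError):
        dichotomize_onmarg(6)


class TestSplits:
    def test_patient_fraction_and_disjointness(self, small_cohort):
        cohort, _, _ = small_cohort
        train, test = split_by_patient(cohort, test_fraction=0.10, seed=1)
        n_total = len(np.unique(cohort.patient_id))
        n_test = len(np.unique(test.patient_id))
        assert abs(n_test - round(0.10 * n_total)) <= 1
        assert not set(train.patient_id) & set(test.patient_id)

    def test_all_admissions_of_a_patient_on_one_side(self, small_cohort):
        cohort, _, _ = small_cohort
        train, test = split_by_patient(cohort, seed=4)
        counts = pd.Series(cohort.patient_id).value_counts()
        multi = counts[counts >= 3].index[:20]
        train_p, test_p = set(train.patient_id), set(test.patient_id)
        for p in multi:
            assert (p in train_p) != (p in test_p)

    def test_split_determinism(self, small_cohort):
        cohort, _, _ = small_cohort
        a = split_by_patient(cohort, seed=9)[1]
        b = split_by_patient(cohort, seed=9)[1]
        np.testing.assert_array_equal(a.patient_id, b.patient_id)

    def test_rejects_bad_fraction(self, small_cohort):
        cohort, _, _ = small_cohort
        with pytest.raises(ValueError):
            split_by_patient(cohort, test_fraction=1.0)

    def test_temporal_split_uses_first_admission_year(self):
        rows = [
            make_admission_row(patient_id="A", admission_date="2010-05-01"),
            make_admission_row(patient_id="A", admission_date="2018-05-01"),
            make_admission_row(patient_id="B", admission_date="2015-02-01"),
        ]
        cohort = build_lookback_features(pd.DataFrame(rows))
        train, test = temporal_split(cohort, cutoff_year=2014)
        assert set(train.patient_id) == {"A"} and len(train) == 2
        assert set(test.patient_id) == {"B"}

    def test_temporal_split_all_pre_cutoff_gives_empty_test(self):
        rows = [
            make_admission_row(patient_id=p, admission_date="2008-01-01")
            for p in "ABC"
        ]
        cohort = build_lookback_features(pd.DataFrame(rows))
        _, test = temporal_split(cohort, cutoff_year=2014)
        assert len(test) == 0


class TestRebalance:
    def _cohort(self, n_neg=900, n_pos=100):
        rows = [
            make_admission_row(patient_id=f"P{i}", dhd=int(i < n_pos))
            for i in range(n_neg + n_pos)
        ]
        return build_lookback_features(pd.DataFrame(rows))

    def test_downsample_exact_balance(self):
        train = rebalance_training(self._cohort(), "downsample", seed=1)
        assert int(train.outcome.sum()) == 100
        assert len(train) == 200

    def test_none_is_identity(self):
        cohort = self._cohort()
        assert rebalance_training(cohort, "none") is cohort

    def test_downsample_determinism(self):
        a = rebalance_training(self._cohort(), "downsample", seed=3)
        b = rebalance_training(self._cohort(), "downsample", seed=3)
        np.testing.assert_array_equal(a.patient_id, b.patient_id)

    def test_class_weight_keeps_rows_and_attaches_weights(self):
        cohort = self._cohort()
        out = rebalance_training(cohort, "class_weight")
        assert len(out) == len(cohort)
        w = out.sample_weight
        assert w is not None
        # weighted class masses equalize
        assert w[out.outcome == 1].sum() == pytest.approx(
            w[out.outcome == 0].sum()
        )

    def test_single_class_rejected(self):
        cohort = self._cohort(n_neg=50, n_pos=0)
        with pytest.raises(ValueError):
            rebalance_training(cohort, "downsample")
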