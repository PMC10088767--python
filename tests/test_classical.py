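import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taskrel import (icc_agreement, icc_consistency, permutation_split_half,
                     spearman_brown)

from conftest import gaussian_stroop_dataset, make_trials


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 2 / 3)])
    def test_printed_formula_values(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    def test_undefined_at_minus_one(self):
        with pytest.raises(ValueError):
            spearman_brown(-1.0)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None)
    def test_strictly_increasing_and_maps_unit_interval(self, a, b):
        fa, fb = spearman_brown(a), spearman_brown(b)
        assert 0.0 <= fa <= 1.0
        if a < b:
            assert fa < fb


class TestPermutationSplitHalf:
    def test_noise_free_index_is_exactly_one(self):
        # zero within-subject variance, heterogeneous subjects
        rows = []
        for s, effect in enumerate([80.0, 100.0, 120.0, 140.0, 60.0]):
            for i in range(6):
                rows.append((f"s{s}", "stroop", "baseline", "test", i,
                             "congruent", 500.0, 1))
                rows.append((f"s{s}", "stroop", "baseline", "test", 10 + i,
                             "incongruent", 500.0 + effect, 1))
        res = permutation_split_half(make_trials(rows), "stroop_effect",
                                     "baseline", "test", n_perm=200, seed=5)
        assert res.mean_r == pytest.approx(1.0, abs=1e-12)
        assert res.ci == (pytest.approx(1.0), pytest.approx(1.0))

    def test_pure_noise_index_near_zero(self):
        ds = gaussian_stroop_dataset(n_subjects=300, n_trials=24, subject_sd=0.0,
                                     noise_sd=100.0, seed=21)
        res = permutation_split_half(ds, "stroop_effect", "baseline", "test",
                                     n_perm=500, seed=9)
        assert abs(res.mean_r) < 0.15

    def test_matches_closed_form_attenuation(self):
        # subject effect sd 50 ms, trial noise sd 100 ms, 48 trials/condition:
        # each half-based difference score has noise var 2 * 100^2 / 24, so the
        # half-half correlation is 2500 / (2500 + 833.3) = 0.75 and the
        # Spearman-Brown corrected value 2r/(1+r) = 6/7.
        ds = gaussian_stroop_dataset(n_subjects=200, n_trials=48, subject_sd=50.0,
                                     noise_sd=100.0, seed=33)
        res = permutation_split_half(ds, "stroop_effect", "baseline", "test",
                                     n_perm=300, seed=13)
        r_half = 2500.0 / (2500.0 + 2 * 100.0 ** 2 / 24)
        expected = 2 * r_half / (1 + r_half)
        assert res.mean_r == pytest.approx(expected, abs=0.05)

    def test_invariant_to_trial_order(self):
        ds = gaussian_stroop_dataset(n_subjects=60, n_trials=24, subject_sd=50.0,
                                     noise_sd=100.0, seed=40)
        shuffled = ds.copy()
        shuffled.trials = (shuffled.trials.sample(frac=1.0, random_state=1)
                           .reset_index(drop=True))
        a = permutation_split_half(ds, "stroop_effect", "baseline", "test",
                                   n_perm=600, seed=3)
        b = permutation_split_half(shuffled, "stroop_effect", "baseline", "test",
                                   n_perm=600, seed=4)
        assert a.mean_r == pytest.approx(b.mean_r, abs=0.03)

    def test_subject_with_too_few_trials_dropped(self):
        ds = gaussian_stroop_dataset(n_subjects=5, n_trials=8, subject_sd=50.0,
                                     noise_sd=30.0, seed=2)
        # subject s000 keeps a single congruent trial
        t = ds.trials
        drop = (t["subject"] == "s000") & (t["trial_type"] == "congruent") & (t["trial_index"] > 0)
        ds.trials = t[~drop].reset_index(drop=True)
        res = permutation_split_half(ds, "stroop_effect", "baseline", "test",
                                     n_perm=50, seed=8)
        assert res.dropped_subjects == ["s000"]
        assert res.n_subjects == 4

    def test_seed_is_required(self):
        ds = gaussian_stroop_dataset(n_subjects=5, n_trials=8, subject_sd=50.0,
                                     noise_sd=30.0, seed=2)
        with pytest.raises(ValueError, match="seed"):
            permutation_split_half(ds, "stroop_effect", "baseline", "test", n_perm=10)


class TestICC:
    def test_worked_consistency_example(self):
        scores = np.array([[1, 4], [2, 5], [3, 6]], dtype=float)
        assert icc_consistency(scores).value == pytest.approx(1.0)

    def test_worked_agreement_example_shrout_fleiss(self):
        # the same matrix is far from absolute agreement: the standard
        # two-way-random formula gives 2/11
        scores = np.array([[1, 4], [2, 5], [3, 6]], dtype=float)
        assert icc_agreement(scores).value == pytest.approx(2 / 11)

    def test_identical_occasions_give_one(self):
        scores = np.tile(np.array([[3.0], [7.0], [5.0], [9.0]]), (1, 2))
        assert icc_consistency(scores).value == pytest.approx(1.0)
        assert icc_agreement(scores).value == pytest.approx(1.0)

    def test_constant_shift_penalises_agreement_monotonically(self):
        base = np.array([1.0, 2.0, 3.0])
        values = []
        for c in (0.5, 1.0, 2.0, 4.0):
            scores = np.column_stack([base, base + c])
            assert icc_consistency(scores).value == pytest.approx(1.0)
            values.append(icc_agreement(scores).value)
        assert all(b < a for a, b in zip(values, values[1:]))
        assert all(v < 1.0 for v in values)

    def test_consistency_invariant_to_per_occasion_shift(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(10, 3))
        shifted = scores + np.array([0.0, 2.5, -1.0])
        assert icc_consistency(scores).value == pytest.approx(
            icc_consistency(shifted).value, rel=1e-10)

    def test_matches_pingouin_values_and_cis(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        for _ in range(10):
            n, k = rng.integers(5, 12), rng.integers(2, 4)
            scores = rng.normal(size=(n, k))
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": scores.ravel(),
            })
            table = pingouin.intraclass_corr(long, targets="subject",
                                             raters="rater", ratings="score")
            ref = table.set_index("Type")
            agree = "ICC2" if "ICC2" in ref.index else "ICC(A,1)"
            consist = "ICC3" if "ICC3" in ref.index else "ICC(C,1)"
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            mine2, mine3 = icc_agreement(scores), icc_consistency(scores)
            assert mine2.value == pytest.approx(ref.loc[agree, "ICC"], abs=1e-9)
            assert mine3.value == pytest.approx(ref.loc[consist, "ICC"], abs=1e-9)
            # pingouin rounds its reported interval to 2 decimals
            np.testing.assert_allclose(mine2.ci, ref.loc[agree, ci_col], atol=5.1e-3)
            np.testing.assert_allclose(mine3.ci, ref.loc[consist, ci_col], atol=5.1e-3)

    def test_missing_entry_rejected(self):
        scores = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 4.0]])
        with pytest.raises(ValueError, match="missing"):
            icc_consistency(scores)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(deadline=None, max_examples=60)
    def test_consistency_at_least_agreement_given_occasion_variance(self, seed):
        # systematic occasion differences penalise only absolute agreement;
        # the ordering needs non-negative subject and occasion variance
        # components (MSR >= MSE and MSC >= MSE), guaranteed here by large
        # added subject and occasion effects
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=(rng.integers(3, 9), rng.integers(2, 5)))
        scores = (scores + 10.0 * np.arange(scores.shape[1])
                  + 10.0 * np.arange(scores.shape[0])[:, None])
        a = icc_agreement(scores).value
        c = icc_consistency(scores).value
        assert c >= a - 1e-10
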