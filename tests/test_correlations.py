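import numpy as np
import pandas as pd
import pytest

from taskrel import (GroundTruth, between_task_correlations, compare_estimate_sets,
                     condition_means, difference_score, r_to_z,
                     reliability_correlation_similarity, simulate_study,
                     within_task_correlations)


def _est(records):
    return pd.DataFrame(records, columns=["subject", "task", "session", "value"])


def _battery_true_delta_estimates(seed=51, n=100, **kw):
    truth = GroundTruth(seed=seed, n_subjects=n, **kw)
    study = simulate_study(truth)
    est = study.true_deltas.rename(columns={"delta_test": "value"})
    return truth, est[["subject", "task", "session", "value"]]


class TestWithinTask:
    def test_duplicated_sessions_give_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=10)
        rows = [(f"s{i}", "stroop", ses, v)
                for ses in ("baseline", "proactive") for i, v in enumerate(vals)]
        out = within_task_correlations(_est(rows), screen=False)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(1)
        rows = [(f"s{i}", "stroop", ses, rng.normal())
                for ses in ("baseline", "proactive", "reactive") for i in range(200)]
        out = within_task_correlations(_est(rows), screen=False)
        assert np.abs(out["r"]).max() < 0.2

    def test_known_loading_recovered(self):
        # true deltas correlate rho * within_task_coupling across sessions
        truth, est = _battery_true_delta_estimates(within_task_coupling=0.6,
                                                   rho_delta=0.8)
        out = within_task_correlations(est, screen=False)
        expected = truth.rho_delta * truth.within_task_coupling
        assert out["r"].mean() == pytest.approx(expected, abs=0.1)

    def test_insufficient_pairs_skipped(self):
        rows = [("s1", "stroop", "baseline", 1.0), ("s1", "stroop", "proactive", 2.0)]
        out = within_task_correlations(_est(rows), screen=False)
        assert len(out) == 0


class TestBetweenTask:
    def test_identical_tasks_give_one(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=12)
        rows = [(f"s{i}", task, "baseline", v)
                for task in ("stroop", "axcpt") for i, v in enumerate(vals)]
        out = between_task_correlations(_est(rows), screen=False)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_uncoupled_tasks_near_zero_on_average(self):
        _, est = _battery_true_delta_estimates(cross_task_coupling=0.0)
        out = between_task_correlations(est, screen=False)
        assert len(out) == 6 * 3
        assert abs(out["r"].mean()) < 0.05
        assert np.abs(out["r"]).max() < 0.35

    def test_spearman_equals_pearson_on_rank_linear_data(self):
        x = np.arange(1.0, 16.0)
        rows = ([(f"s{i}", "stroop", "baseline", v) for i, v in enumerate(x)]
                + [(f"s{i}", "axcpt", "baseline", 2 * v + 1) for i, v in enumerate(x)])
        p = between_task_correlations(_est(rows), method="pearson", screen=False)
        s = between_task_correlations(_est(rows), method="spearman", screen=False)
        assert p["r"].iloc[0] == pytest.approx(s["r"].iloc[0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            between_task_correlations(_est([]), method="kendall")


class TestRToZ:
    def test_values(self):
        assert r_to_z(0.0) == 0.0
        # independent oracle: atanh(r) = 0.5 * log((1+r)/(1-r))
        assert r_to_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)
        assert r_to_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_antisymmetry(self):
        r = np.linspace(-0.95, 0.95, 21)
        np.testing.assert_allclose(r_to_z(-r), -r_to_z(r))

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.3])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            r_to_z(bad)


class TestPatternSimilarity:
    def _tables(self, rel_vals, within_vals):
        tasks = ["stroop", "axcpt", "cuedts", "sternberg"]
        rel_rows, within_rows = [], []
        i = 0
        for task in tasks:
            for ses in ("baseline", "proactive", "reactive"):
                rel_rows.append({"task": task, "session": ses, "r": rel_vals[i]})
                i += 1
        j = 0
        for task in tasks:
            for sa, sb in (("baseline", "proactive"), ("baseline", "reactive"),
                           ("proactive", "reactive")):
                within_rows.append({"task": task, "session_a": sa, "session_b": sb,
                                    "r": within_vals[j]})
                j += 1
        return pd.DataFrame(rel_rows), pd.DataFrame(within_rows)

    def test_identical_patterns_give_one(self):
        rng = np.random.default_rng(3)
        rel = rng.uniform(0.2, 0.8, 12)
        rel_df, within_df = self._tables(rel, rel)
        # within value k pairs sessions (a, b); construct within = mean of the
        # two sessions' reliabilities on the z scale for exact agreement
        within = []
        i = 0
        for t in range(4):
            sess = rel[3 * t: 3 * t + 3]
            for a, b in ((0, 1), (0, 2), (1, 2)):
                within.append(np.tanh(0.5 * (np.arctanh(sess[a]) + np.arctanh(sess[b]))))
        _, within_df = self._tables(rel, within)
        r, n = reliability_correlation_similarity(rel_df, within_df)
        assert n == 12
        assert r == pytest.approx(1.0)

    def test_permuted_pairing_near_zero_on_average(self):
        rng = np.random.default_rng(4)
        rel = rng.uniform(0.1, 0.9, 12)
        within = rng.uniform(0.1, 0.9, 12)
        rel_df, within_df = self._tables(rel, within)
        rs = []
        for _ in range(300):
            perm = within_df.copy()
            perm["r"] = rng.permutation(within["r"].values if hasattr(within, "values")
                                        else within)
            rs.append(reliability_correlation_similarity(rel_df, perm)[0])
        assert abs(np.mean(rs)) < 0.1

    def test_length_mismatch_rejected(self):
        rel_df, within_df = self._tables(np.full(12, 0.5), np.full(12, 0.4))
        with pytest.raises(ValueError):
            reliability_correlation_similarity(rel_df.iloc[:5], within_df)

    def test_trial_count_driven_reliability_orders_similarity(self):
        # tasks differ only in trials/cell (8 vs 96): sparser cells are less
        # reliable and show weaker within-task correlations, so the pattern
        # similarity across (task, session-pair) cells must be positive
        counts = {"stroop": 96, "axcpt": 48, "cuedts": 16, "sternberg": 8}
        from taskrel.schema import CONTRASTS
        trial_counts = {}
        for task, n in counts.items():
            c, i, _ = CONTRASTS[task]
            for ses in ("baseline", "proactive", "reactive"):
                trial_counts[(task, ses, c)] = n
                trial_counts[(task, ses, i)] = n
        truth = GroundTruth(seed=61, n_subjects=80, trial_counts=trial_counts)
        study = simulate_study(truth)
        summary = condition_means(study.dataset)
        diffs = pd.concat([difference_score(summary, t) for t in counts],
                          ignore_index=True)
        rel_rows, within_rows = [], []
        for task in counts:
            for ses in ("baseline", "proactive", "reactive"):
                w = diffs[(diffs["task"] == task) & (diffs["session"] == ses)]
                mat = w.pivot_table(index="subject", columns="phase", values="value")
                rel_rows.append({"task": task, "session": ses,
                                 "r": np.corrcoef(mat["test"], mat["retest"])[0, 1]})
        test_only = diffs[diffs["phase"] == "test"].rename(columns={"value": "value"})
        within_df = within_task_correlations(
            test_only[["subject", "task", "session", "value"]], screen=False)
        r, n = reliability_correlation_similarity(pd.DataFrame(rel_rows), within_df)
        assert n == 12
        assert r > 0


class TestCompareEstimateSets:
    def test_identical_sets_degenerate(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = compare_estimate_sets(a, a.copy())
        assert res.degenerate and res.pvalue == 1.0

    def test_uniform_positive_shift_gives_smallest_p(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 0.5, 8)
        res = compare_estimate_sets(a, a + 0.1, method="exact")
        assert res.pvalue == pytest.approx(2.0 / 2 ** 8)

    def test_needs_five_pairs(self):
        with pytest.raises(ValueError):
            compare_estimate_sets([1.0, 2.0], [2.0, 3.0])

    def test_continuity_corrected_approximation_reasonable(self):
        # at moderate p the corrected normal approximation tracks the exact
        # signed-rank distribution closely
        rng = np.random.default_rng(6)
        a = rng.normal(size=30)
        b = a + rng.normal(0.1, 0.5, size=30)
        approx = compare_estimate_sets(a, b, method="approx")
        exact = compare_estimate_sets(a, b, method="exact")
        assert 0.01 < exact.pvalue < 0.9
        assert approx.pvalue == pytest.approx(exact.pvalue, rel=0.15)
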