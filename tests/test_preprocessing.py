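import numpy as np
import pytest
from scipy import stats

from taskrel import (chi2_cutoff, error_rate_filter, mahalanobis_filter,
                     retention_filter, trim_rt)
from taskrel.preprocessing import error_rate_sweep

from conftest import make_trials


def _cell(subject, rts, accs=None, tt="congruent", start=0):
    accs = accs if accs is not None else [1] * len(rts)
    return [(subject, "stroop", "baseline", "test", start + i, tt, rt, a)
            for i, (rt, a) in enumerate(zip(rts, accs))]


class TestTrimRT:
    def test_uniform_cell_untouched(self):
        rng = np.random.default_rng(0)
        ds = make_trials(_cell("s1", rng.uniform(300, 500, 20)))
        out, report = trim_rt(ds)
        assert len(out) == 20
        assert report.per_task["n_removed"].sum() == 0

    def test_floor_rule_removes_fast_trial(self):
        ds = make_trials(_cell("s1", [150.0, 400, 410, 420, 430, 440]))
        out, report = trim_rt(ds)
        assert len(out) == 5
        assert 150.0 not in out.trials["rt_ms"].values
        assert report.per_cell["n_removed_fast"].sum() == 1
        assert report.per_cell["n_removed_slow"].sum() == 0

    def test_slow_rule_matches_bruteforce_oracle(self):
        rts = [400.0] * 19 + [5000.0]
        ds = make_trials(_cell("s1", rts))
        out, report = trim_rt(ds)
        # independent recomputation of the mean + 3 sd cutoff
        arr = np.array(rts)
        cutoff = arr.mean() + 3 * arr.std(ddof=1)
        expected_removed = [rt for rt in rts if rt > cutoff]
        assert expected_removed == [5000.0]
        assert len(out) == 19
        assert report.per_cell["n_removed_slow"].sum() == 1

    def test_incorrect_trials_untouched(self):
        rows = _cell("s1", [150.0, 400, 420], accs=[0, 1, 1])
        ds = make_trials(rows)
        out, _ = trim_rt(ds)
        assert len(out) == 3            # the 150 ms trial is an error trial: kept

    def test_small_cell_flagged_no_slow_trim(self):
        ds = make_trials(_cell("s1", [5000.0]))
        out, report = trim_rt(ds)
        assert len(out) == 1
        assert len(report.small_cells) == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        rows = []
        for s in range(4):
            rows += _cell(f"s{s}", rng.lognormal(6.2, 0.4, 30))
        ds = make_trials(rows)
        out, report = trim_rt(ds)
        removed = report.per_cell["n_removed_fast"].sum() + report.per_cell["n_removed_slow"].sum()
        assert len(ds) == len(out) + removed


class TestRetentionFilter:
    def test_no_trim_no_removal(self):
        ds = make_trials(_cell("s1", [400.0] * 8))
        out, report = retention_filter(ds, ds.copy())
        assert len(report.removed) == 0
        assert len(out) == 8

    def test_more_than_half_removed_drops_subject(self):
        before = make_trials(_cell("s1", [400.0] * 8) + _cell("s2", [400.0] * 8))
        after_rows = _cell("s1", [400.0] * 3) + _cell("s2", [400.0] * 8)
        after = make_trials(after_rows)
        out, report = retention_filter(before, after)     # 3/8 < 0.5
        assert list(report.removed["subject"]) == ["s1"]
        assert report.removed["reason"].iloc[0] == "over_half_trimmed"
        assert set(out.trials["subject"]) == {"s2"}

    def test_exactly_half_retained_passes(self):
        before = make_trials(_cell("s1", [400.0] * 8))
        after = make_trials(_cell("s1", [400.0] * 4))      # exactly half: keep
        out, report = retention_filter(before, after)
        assert len(report.removed) == 0
        assert len(out) == 4

    def test_removal_is_task_scoped(self):
        stroop = _cell("s1", [400.0] * 8)
        sternberg = [("s1", "sternberg", "baseline", "test", i, "NN", 500.0, 1)
                     for i in range(8)]
        before = make_trials(stroop + sternberg)
        after = make_trials(_cell("s1", [400.0] * 2) + sternberg)
        out, _ = retention_filter(before, after)
        assert set(out.trials["task"]) == {"sternberg"}    # other task survives


class TestErrorRateFilter:
    def test_all_correct_retained(self):
        ds = make_trials(_cell("s1", [400.0] * 10))
        out, report = error_rate_filter(ds)
        assert len(report.removed) == 0 and len(out) == 10

    def test_half_errors_removed(self):
        ds = make_trials(_cell("s1", [400.0] * 10, accs=[0] * 5 + [1] * 5)
                         + _cell("s2", [400.0] * 10))
        out, report = error_rate_filter(ds, cutoff=0.40)   # 0.5 > 0.4
        assert list(report.removed["subject"]) == ["s1"]
        assert set(out.trials["subject"]) == {"s2"}

    def test_planted_high_error_subject_exactly_removed(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(6):
            err = 0.45 if s == 2 else 0.05
            accs = (rng.random(40) >= err).astype(int)
            # make the planted subject deterministic: force 45% errors exactly
            if s == 2:
                accs = np.array([0] * 18 + [1] * 22)
            rows += _cell(f"s{s}", rng.lognormal(6.2, 0.3, 40), accs=accs)
        out, report = error_rate_filter(make_trials(rows), cutoff=0.40)
        assert list(report.removed["subject"]) == ["s2"]

    def test_sweep_monotone(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(8):
            accs = (rng.random(30) >= 0.1 + 0.05 * s).astype(int)
            rows += _cell(f"s{s}", rng.lognormal(6.2, 0.3, 30), accs=accs)
        sweep = error_rate_sweep(make_trials(rows))
        by_cutoff = sweep.groupby("cutoff")["n_removed"].sum()
        assert (by_cutoff.sort_index().diff().dropna() <= 0).all()


class TestChi2Cutoff:
    def test_printed_bivariate_outlier_cutoff(self):
        assert chi2_cutoff(0.001, 1) == pytest.approx(10.828, abs=5e-4)

    def test_median_of_chi2_1(self):
        # independent numeric quantile: median of Z^2 with Z standard normal
        z_med = stats.norm.ppf(0.75)                        # P(|Z| <= z) = 0.5
        assert chi2_cutoff(0.5, 1) == pytest.approx(z_med ** 2, rel=1e-10)

    def test_alpha_near_one_gives_zero(self):
        assert chi2_cutoff(1 - 1e-12, 1) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("alpha,df", [(0.0, 1), (1.0, 1), (0.5, 0), (0.5, 1.5)])
    def test_invalid_inputs(self, alpha, df):
        with pytest.raises(ValueError):
            chi2_cutoff(alpha, df)


class TestMahalanobisFilter:
    def test_centroid_kept(self):
        x = np.array([0.0, 1.0, -1.0, 0.5, -0.5])
        y = np.array([0.0, 1.0, -1.0, -0.5, 0.5])
        keep = mahalanobis_filter(x, y)
        assert keep[0]                                      # point at the mean

    def test_planted_outlier_excluded(self):
        rng = np.random.default_rng(12)
        x = np.append(rng.standard_normal(1000), 10.0)
        y = np.append(rng.standard_normal(1000), 10.0)
        keep = mahalanobis_filter(x, y)
        assert not keep[-1]
        # direct distance recomputation agrees with the mask everywhere
        xy = np.column_stack([x, y])
        cov = np.cov(xy, rowvar=False, ddof=1)
        dev = xy - xy.mean(axis=0)
        d2 = np.einsum("ni,ij,nj->n", dev, np.linalg.inv(cov), dev)
        np.testing.assert_array_equal(keep, d2 <= 10.828)

    def test_singular_covariance_raises(self):
        x = np.array([1.0, 1.0, 1.0, 2.0])
        y = np.array([3.0, 3.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="singular"):
            mahalanobis_filter(x, y)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            mahalanobis_filter([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])
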