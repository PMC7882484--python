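import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mothtaxis import AnalysisConfig
from mothtaxis.maneuvers import EXCLUDED, MATCH, MISMATCH
from mothtaxis.rewards import (
    GroupedRewards, analysis_report, binned_reward_stat, ecdf_and_histogram,
    join_records, ks_two_sample, report_from_json, report_to_json,
    rmse_windows, windowed_rmse_table,
)

from _oracles import binned_means_bruteforce, rmse_direct


def reward_frame(n, rng=None, hit_rate=None, cum_hits=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "t": np.arange(n) * 0.05,
        "S": rng.random(n),
        "dS": rng.normal(size=n),
        "EdS": rng.normal(size=n),
        "p_star": np.zeros(n),
        "hit": np.zeros(n),
        "cum_hits": cum_hits if cum_hits is not None else np.arange(n, dtype=float),
        "hit_rate": hit_rate if hit_rate is not None else rng.uniform(0, 10, n),
    })


def maneuver_frame(labels):
    n = len(labels)
    return pd.DataFrame({"t": np.arange(n) * 0.05, "tau_b": np.zeros(n),
                         "v": np.zeros(n), "omega": np.zeros(n),
                         "temporal": ["Surge"] * n, "kinematic": ["Surge"] * n,
                         "match": labels})


class TestJoinRecords:
    def test_all_excluded_gives_empty_groups(self):
        r = reward_frame(10)
        g = join_records(r, maneuver_frame([EXCLUDED] * 11))
        assert g.empty

    def test_group_sizes_match_label_counts(self):
        labels = [MATCH, MISMATCH] * 5 + [EXCLUDED]
        g = join_records(reward_frame(10), maneuver_frame(labels))
        assert len(g.groups[MATCH]) == 5
        assert len(g.groups[MISMATCH]) == 5

    def test_row_order_invariance(self):
        r = reward_frame(10)
        m = maneuver_frame([MATCH, MISMATCH] * 5 + [EXCLUDED])
        g1 = join_records(r, m)
        g2 = join_records(r.iloc[::-1].reset_index(drop=True),
                          m.iloc[::-1].reset_index(drop=True))
        for status in (MATCH, MISMATCH):
            pd.testing.assert_frame_equal(
                g1.groups[status].reset_index(drop=True),
                g2.groups[status].reset_index(drop=True))

    def test_time_base_mismatch_rejected(self):
        r = reward_frame(10)
        m = maneuver_frame([MATCH] * 11)
        m["t"] = m["t"] + 0.01
        with pytest.raises(ValueError):
            join_records(r, m)


class TestKolmogorovSmirnov:
    def test_identical_samples_d_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        d, p = ks_two_sample(a, a)
        assert d == 0.0

    def test_disjoint_supports_d_one(self):
        d, _ = ks_two_sample(np.zeros(3), np.ones(3))
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample(np.array([]), np.ones(3))

    def test_null_calibration(self):
        """Type-I error at alpha = 0.05 stays within 0.05 +/- 0.02 over 1000
        same-distribution replicates of n = 500."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(size=500)
            b = rng.normal(size=500)
            _, p = ks_two_sample(a, b)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


class TestEcdfHistogram:
    def test_single_value_step(self):
        out = ecdf_and_histogram(np.array([3.0]), bins=5)
        assert out["x"].tolist() == [3.0]
        assert out["F"].tolist() == [1.0]

    def test_ecdf_reaches_one_and_monotone(self, rng):
        out = ecdf_and_histogram(rng.normal(size=200), bins=20)
        assert out["F"][-1] == 1.0
        assert np.all(np.diff(out["F"]) >= 0)
        assert np.all(np.diff(out["x"]) >= 0)

    def test_histogram_mass_conserved(self, rng):
        s = rng.normal(size=333)
        out = ecdf_and_histogram(s, bins=13)
        assert out["hist_counts"].sum() == 333


class TestBinnedStat:
    def test_constant_values(self):
        out = binned_reward_stat(np.full(20, 7.0), np.linspace(0, 9.9, 20),
                                 [0.0, 5.0, 10.0])
        assert np.allclose(out["mean"], 7.0)

    def test_outside_counted(self):
        out = binned_reward_stat(np.ones(4), np.array([-1.0, 0.5, 1.5, 99.0]),
                                 [0.0, 1.0, 2.0])
        assert out.attrs["n_outside"] == 2
        assert out["n"].sum() == 2

    def test_matches_bruteforce_groupby(self, rng):
        values = rng.normal(size=300)
        cov = rng.uniform(-1.0, 11.0, size=300)
        edges = [0.0, 2.0, 5.0, 10.0]
        out = binned_reward_stat(values, cov, edges)
        expect = binned_means_bruteforce(values, cov, edges)
        for row, (mean, count) in zip(out.itertuples(), expect):
            assert row.n == count
            if count:
                assert row.mean == pytest.approx(mean, rel=1e-12)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            binned_reward_stat(np.ones(3), np.ones(3), [0.0, 2.0, 1.0])


class TestRmseWindows:
    def test_perfect_prediction_zero(self):
        x = np.sin(np.arange(41))
        eds = np.roll(x, -1)  # EdS_i == dS_{i+1}
        out = rmse_windows(x, eds, 20)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_constant_offset(self):
        ds = np.zeros(41)
        eds = np.full(41, -0.25)
        out = rmse_windows(ds, eds, 20)
        np.testing.assert_allclose(out, 0.25)

    def test_matches_direct_formula(self, rng):
        ds = rng.normal(size=105)
        eds = rng.normal(size=105)
        got = rmse_windows(ds, eds, 20)
        want = rmse_direct(list(ds), list(eds), 20)
        np.testing.assert_allclose(got, want, rtol=1e-12)
        assert len(got) == (105 - 1) // 20

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            rmse_windows(np.zeros(20), np.zeros(20), 20)

    def test_window_majority_status(self):
        r = reward_frame(41)
        labels = [MATCH] * 15 + [MISMATCH] * 5 + [MISMATCH] * 15 + [MATCH] * 5 + [EXCLUDED]
        out = windowed_rmse_table(r, maneuver_frame(labels),
                                  AnalysisConfig(rmse_window=20))
        assert out["match"].tolist() == [MATCH, MISMATCH]


class TestAnalysisReport:
    def grouped(self, a, b):
        fa = reward_frame(len(a))
        fa["dS"] = a
        fa["EdS"] = a
        fb = reward_frame(len(b))
        fb["dS"] = b
        fb["EdS"] = b
        return GroupedRewards({MATCH: fa, MISMATCH: fb})

    def test_same_distribution_usually_not_significant(self):
        rng = np.random.default_rng(7)
        rejected = 0
        for _ in range(20):
            g = self.grouped(rng.normal(size=300), rng.normal(size=300))
            rejected += analysis_report(g)["significant"]
        assert rejected <= 4  # p typically above alpha under the null

    def test_large_shift_detected(self):
        rng = np.random.default_rng(8)
        g = self.grouped(rng.normal(size=500), rng.normal(size=500) + 3.0)
        rep = analysis_report(g)
        assert rep["significant"]
        assert rep["ks"]["dS"]["p"] < 0.05
        assert rep["mean_dS_diff_sign"] == 1

    def test_report_round_trips_through_json(self):
        rng = np.random.default_rng(9)
        g = self.grouped(rng.normal(size=100), rng.normal(size=100))
        r = reward_frame(41)
        rmse = windowed_rmse_table(r, maneuver_frame([MATCH] * 41))
        rep = analysis_report(g, rmse)
        assert report_from_json(report_to_json(rep)) == rep
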