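"""Cluster-corrected permutation tests: trend statistic, clustering, nulls."""

import numpy as np
import pytest
from scipy import stats

from ssvepdyn.metrics import SuppressionTimeCourse
from ssvepdyn.cluster import (ClusterTestConfig, trend_t_series, find_clusters,
                              cluster_test_increase, cluster_test_groups)

GRID = np.round(np.arange(0.5, 5.51, 0.05), 10)


def course(values, pid="P0"):
    values = np.broadcast_to(values, GRID.shape).astype(float)
    return SuppressionTimeCourse(times=GRID.copy(), ratio_db=values.copy(),
                                 frequency=None, mask_type="pooled",
                                 participant_id=pid)


def noisy_courses(n, rng, trend=0.0, offset=0.0):
    out = []
    for i in range(n):
        vals = offset + trend * GRID + 0.3 * rng.standard_normal(GRID.size)
        out.append(course(vals, pid=f"P{i}"))
    return out


class TestTrendTSeries:
    def test_constant_courses_give_zero_t(self):
        centers, t = trend_t_series([course(1.0, f"P{i}") for i in range(5)], lag=1.0)
        np.testing.assert_array_equal(t, 0.0)
        # centers need both endpoints on the grid: [1.0, 5.0]
        assert centers[0] == pytest.approx(1.0)
        assert centers[-1] == pytest.approx(5.0)

    def test_unit_slope_zero_variance_hits_inf_sentinel(self):
        courses = [course(GRID, f"P{i}") for i in range(4)]
        _, t = trend_t_series(courses, lag=1.0)
        assert np.all(np.isposinf(t))

    def test_matches_textbook_paired_t(self):
        # per-participant lagged differences fixed by construction
        diffs = np.array([0.5, 0.3, 0.7, 0.4, 0.6, 0.5, 0.2, 0.8, 0.45, 0.55])
        courses = [course(np.where(GRID >= 3.0, d, 0.0), f"P{i}")
                   for i, d in enumerate(diffs)]
        centers, t = trend_t_series(courses, lag=1.0)
        # at center 2.5 the difference is course(3.0) - course(2.0) = d_p exactly
        idx = np.argmin(np.abs(centers - 2.5))
        expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(diffs.size))
        assert t[idx] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(8.8853, abs=1e-3)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="3 participants"):
            trend_t_series([course(1.0), course(1.0)], lag=1.0)

    def test_off_grid_lag_snaps_with_warning(self):
        courses = [course(1.0, f"P{i}") for i in range(4)]
        with pytest.warns(UserWarning, match="snapped"):
            trend_t_series(courses, lag=1.03)


class TestFindClusters:
    def threshold_alpha(self, value, df):
        # choose alpha so the cluster-forming threshold is exactly `value`
        return float(stats.t.sf(value, df))

    def test_single_run_summed(self):
        t = np.array([0.0, 3.0, 3.0, 3.0, 0.0])
        clusters = find_clusters(t, df=10, alpha_pointwise=self.threshold_alpha(2, 10))
        assert len(clusters) == 1
        assert clusters[0].summed_t == pytest.approx(9.0)
        assert (clusters[0].start_idx, clusters[0].end_idx) == (1, 3)

    def test_all_subthreshold_empty(self):
        t = np.array([0.5, 1.0, -2.0])
        assert find_clusters(t, df=10, alpha_pointwise=self.threshold_alpha(2, 10)) == []

    def test_adjacency_splits_clusters(self):
        t = np.array([3.0, 0.0, 3.0])
        clusters = find_clusters(t, df=10, alpha_pointwise=self.threshold_alpha(2, 10))
        assert [c.summed_t for c in clusters] == [pytest.approx(3.0)] * 2

    def test_two_sided_keeps_sign(self):
        t = np.array([-4.0, -4.0, 0.0, 4.0])
        clusters = find_clusters(t, df=10,
                                 alpha_pointwise=2 * self.threshold_alpha(2, 10),
                                 sidedness="two_sided")
        assert sorted(c.summed_t for c in clusters) == [pytest.approx(-8.0),
                                                        pytest.approx(4.0)]


class TestClusterTestIncrease:
    def test_same_seed_is_deterministic(self, rng):
        courses = noisy_courses(8, rng, trend=0.2)
        cfg = ClusterTestConfig(n_permutations=200, seed=9)
        a = cluster_test_increase(courses, cfg)
        b = cluster_test_increase(courses, cfg)
        np.testing.assert_array_equal(a.null_max, b.null_max)
        assert [c.significant for c in a.clusters] == [c.significant for c in b.clusters]

    def test_strong_trend_detected(self, rng):
        courses = noisy_courses(10, rng, trend=0.5)
        res = cluster_test_increase(courses, ClusterTestConfig(n_permutations=300,
                                                               seed=1))
        assert res.significant_clusters
        assert res.significant_timepoints.size > 0

    def test_invariant_to_common_offset(self, rng):
        courses = noisy_courses(8, rng, trend=0.3)
        shifted = [course(c.ratio_db + 7.5, c.participant_id) for c in courses]
        cfg = ClusterTestConfig(n_permutations=200, seed=3)
        a = cluster_test_increase(courses, cfg)
        b = cluster_test_increase(shifted, cfg)
        np.testing.assert_allclose(a.pointwise_t, b.pointwise_t, atol=1e-9)
        assert [c.significant for c in a.clusters] == [c.significant for c in b.clusters]

    def test_wrong_null_type_rejected(self, rng):
        courses = noisy_courses(4, rng)
        with pytest.raises(ValueError, match="sign_flip"):
            cluster_test_increase(courses, ClusterTestConfig(null_type="label_shuffle"))


class TestClusterTestGroups:
    def groups_config(self, n_perm=300, seed=2):
        return ClusterTestConfig(sidedness="two_sided", null_type="label_shuffle",
                                 n_permutations=n_perm, seed=seed)

    def test_identical_groups_find_nothing(self, rng):
        courses = noisy_courses(6, rng)
        copies = [course(c.ratio_db.copy(), c.participant_id) for c in courses]
        res = cluster_test_groups(courses, copies, self.groups_config())
        assert res.significant_clusters == []

    def test_constant_offset_detected_over_full_period(self, rng):
        group_a = noisy_courses(8, rng, offset=3.0)
        group_b = noisy_courses(8, rng, offset=0.0)
        res = cluster_test_groups(group_a, group_b, self.groups_config())
        sig = res.significant_clusters
        assert len(sig) == 1
        assert sig[0].start_s == pytest.approx(GRID[0])
        assert sig[0].end_s == pytest.approx(GRID[-1])

    def test_small_groups_rejected(self, rng):
        courses = noisy_courses(4, rng)
        with pytest.raises(ValueError, match="2 participants"):
            cluster_test_groups(courses[:1], courses[1:], self.groups_config())

    def test_offset_on_both_groups_is_invariant(self, rng):
        group_a = noisy_courses(6, rng, offset=1.0)
        group_b = noisy_courses(6, rng)
        cfg = self.groups_config()
        res0 = cluster_test_groups(group_a, group_b, cfg)
        res1 = cluster_test_groups(
            [course(c.ratio_db + 4.0, c.participant_id) for c in group_a],
            [course(c.ratio_db + 4.0, c.participant_id) for c in group_b], cfg)
        np.testing.assert_allclose(res0.pointwise_t, res1.pointwise_t, atol=1e-9)
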