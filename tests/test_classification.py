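"""Three-population classification, population summaries, Mann-Whitney U."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from saltatrack import AcquisitionMeta, MotionClass
from saltatrack.classification import (ClassifierThresholds, classify_all,
                                       classify_trajectory, mann_whitney_u,
                                       summarize_populations)
from saltatrack.trajectory_stats import TrajectoryStats, compute_stats


def mk_stats(d_total=5.0, alpha=1.0, v_max=50.0, straight=0.5, tid=0):
    return TrajectoryStats(trajectory_id=tid, n_frames=24, v=np.array([v_max]),
                           v_max=v_max, d_total_px=d_total, d_total_nm=d_total * 107,
                           msd=np.array([1.0, 2.0]), alpha=alpha,
                           straightness=straight, gap_steps=np.array([False]))


class TestRule:
    def test_static_trajectory_is_restricted(self):
        assert classify_trajectory(mk_stats(d_total=0.0, alpha=float("nan"), v_max=0.0)) \
            is MotionClass.P1_RESTRICTED

    def test_ballistic_trajectory_is_directed(self):
        assert classify_trajectory(mk_stats(d_total=20.0, alpha=2.0, v_max=400.0)) \
            is MotionClass.P3_DIRECTED

    def test_diffusive_midrange_is_brownian(self):
        assert classify_trajectory(mk_stats(d_total=7.0, alpha=1.0, v_max=70.0)) \
            is MotionClass.P2_BROWNIAN

    def test_velocity_burst_marks_directed_despite_small_net_displacement(self):
        # out-and-back saltatory run: large jump, small d_total
        assert classify_trajectory(mk_stats(d_total=4.0, alpha=1.1, v_max=600.0)) \
            is MotionClass.P3_DIRECTED

    def test_nan_alpha_falls_back_to_displacement(self):
        assert classify_trajectory(mk_stats(d_total=15.0, alpha=float("nan"), v_max=50.0)) \
            is MotionClass.P3_DIRECTED
        assert classify_trajectory(mk_stats(d_total=5.0, alpha=float("nan"), v_max=50.0)) \
            is MotionClass.P2_BROWNIAN

    def test_raising_t1_never_removes_from_p1(self):
        rng = np.random.default_rng(1)
        stats = [mk_stats(d_total=float(rng.uniform(0, 20)),
                          alpha=float(rng.uniform(0, 2)),
                          v_max=float(rng.uniform(0, 800)), tid=i)
                 for i in range(200)]
        lo = ClassifierThresholds(t1_px=2.0)
        hi = ClassifierThresholds(t1_px=5.0)
        for s in stats:
            if classify_trajectory(s, lo) is MotionClass.P1_RESTRICTED:
                assert classify_trajectory(s, hi) is MotionClass.P1_RESTRICTED

    def test_order_invariance(self):
        stats = [mk_stats(d_total=d, tid=i) for i, d in enumerate([1.0, 7.0, 30.0])]
        fwd = classify_all(stats)
        rev = classify_all(stats[::-1])[::-1]
        assert fwd == rev


class TestBenchmarkRecovery:
    def test_accuracy_fractions_medians_and_ordering(self, benchmark_300, meta):
        """On the 300-trajectory labelled benchmark at the observed mixture:
        accuracy >= 0.90, recovered fractions within 5 points of the
        generative mixture, and median displacement ordered P1 < P2 < P3
        with adjacent pairwise Mann-Whitney p < 0.01."""
        truth = benchmark_300
        stats = [compute_stats(t, meta) for t in truth.trajectories]
        classes = classify_all(stats)
        acc = np.mean([c is l for c, l in zip(classes, truth.labels)])
        assert acc >= 0.90, f"accuracy {acc:.3f}"
        summary = summarize_populations(classes, stats)
        mixture = {MotionClass.P1_RESTRICTED: 0.15, MotionClass.P2_BROWNIAN: 0.41,
                   MotionClass.P3_DIRECTED: 0.44}
        for c, want in mixture.items():
            got = summary.per_class[c].fraction
            assert abs(got - want) <= 0.05, f"{c}: {got:.3f} vs {want}"
        m1 = summary.per_class[MotionClass.P1_RESTRICTED].median_d_total_px
        m2 = summary.per_class[MotionClass.P2_BROWNIAN].median_d_total_px
        m3 = summary.per_class[MotionClass.P3_DIRECTED].median_d_total_px
        assert m1 < m2 < m3
        p12 = summary.pairwise_d_total[(MotionClass.P1_RESTRICTED, MotionClass.P2_BROWNIAN)][1]
        p23 = summary.pairwise_d_total[(MotionClass.P2_BROWNIAN, MotionClass.P3_DIRECTED)][1]
        assert p12 < 0.01 and p23 < 0.01


class TestSummaries:
    def test_small_summary_arithmetic(self):
        stats = [mk_stats(d_total=1.0, tid=0), mk_stats(d_total=5.0, tid=1),
                 mk_stats(d_total=10.0, tid=2), mk_stats(d_total=20.0, tid=3)]
        classes = [MotionClass.P1_RESTRICTED, MotionClass.P2_BROWNIAN,
                   MotionClass.P3_DIRECTED, MotionClass.P3_DIRECTED]
        s = summarize_populations(classes, stats)
        assert s.per_class[MotionClass.P1_RESTRICTED].fraction == 0.25
        assert s.per_class[MotionClass.P2_BROWNIAN].fraction == 0.25
        assert s.per_class[MotionClass.P3_DIRECTED].fraction == 0.5
        assert s.per_class[MotionClass.P3_DIRECTED].median_d_total_px == 15.0

    def test_single_class_leaves_others_null(self):
        stats = [mk_stats(d_total=1.0, tid=i) for i in range(3)]
        classes = [MotionClass.P1_RESTRICTED] * 3
        s = summarize_populations(classes, stats)
        assert s.per_class[MotionClass.P1_RESTRICTED].fraction == 1.0
        assert s.per_class[MotionClass.P2_BROWNIAN].count == 0
        assert s.per_class[MotionClass.P2_BROWNIAN].median_d_total_px is None
        assert s.pairwise_d_total == {}

    def test_fractions_sum_to_one(self, benchmark_300, meta):
        stats = [compute_stats(t, meta) for t in benchmark_300.trajectories]
        s = summarize_populations(classify_all(stats), stats)
        total = sum(cs.fraction for cs in s.per_class.values())
        assert total == pytest.approx(1.0, abs=1e-9)
        assert sum(cs.count for cs in s.per_class.values()) == s.n_total


def brute_force_mw_p(a, b):
    """Independent permutation oracle: enumerate every split of the pooled
    values into groups of the observed sizes and compare U statistics."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), na):
        us.append(ranks[list(comb)].sum() - na * (na + 1) / 2)
    us = np.array(us)
    eps = 1e-9
    return min(1.0, 2 * min((us <= u_obs + eps).mean(), (us >= u_obs - eps).mean()))


class TestMannWhitney:
    def test_identical_samples_give_p_1(self):
        u, p = mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    def test_fully_separated_123_456(self):
        """U = 0 for the lower sample; exact two-sided p = 2/20 = 0.1."""
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("na,nb", [(1, 1), (2, 3), (3, 3), (4, 4), (5, 5),
                                       (2, 8), (6, 6), (5, 7)])
    def test_exact_path_matches_brute_force_with_and_without_ties(self, na, nb):
        rng = np.random.default_rng(na * 100 + nb)
        for trial in range(5):
            # half the trials draw from a small integer set to force ties
            if trial % 2:
                a = rng.integers(0, 4, na).astype(float)
                b = rng.integers(0, 4, nb).astype(float)
            else:
                a = rng.normal(size=na)
                b = rng.normal(size=nb)
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_8_plus_8(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1.0, size=8)
            _, p_exact = mann_whitney_u(a, b, exact_max_n=16)
            _, p_norm = mann_whitney_u(a, b, exact_max_n=0)
            assert abs(p_exact - p_norm) <= 0.02

    def test_large_sample_path_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = rng.normal(0.4, 1.2, size=35)
        u, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
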