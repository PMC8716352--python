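"""Targeting-error metrics, group statistics and ANOVA tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import cbctnav as cn

from conftest import random_rigid

finite3 = st.lists(st.floats(-100, 100), min_size=3, max_size=3)


class TestTargetingErrors:
    def test_perfect_placement(self):
        m = cn.targeting_errors([0.0, 0, 0], [0.0, 0, 100], [0.0, 0, 100])
        assert (m.angular_deg, m.absolute_mm, m.longitudinal_mm) == (0.0, 0.0, 0.0)

    def test_worked_example_hand_trigonometry(self):
        # lateral miss of 2 mm at 100 mm depth
        m = cn.targeting_errors([0.0, 0, 0], [0.0, 0, 100], [2.0, 0, 100])
        assert m.angular_deg == pytest.approx(np.degrees(np.arctan(2 / 100)), abs=1e-9)
        assert m.angular_deg == pytest.approx(1.1458, abs=1e-4)
        assert m.absolute_mm == pytest.approx(2.0, abs=1e-12)
        assert m.longitudinal_mm == pytest.approx(np.hypot(2, 100) - 100, abs=1e-9)
        assert m.longitudinal_mm == pytest.approx(0.0200, abs=1e-4)

    def test_pure_depth_error(self):
        m = cn.targeting_errors([0.0, 0, 0], [0.0, 0, 100], [0.0, 0, 95])
        assert m.angular_deg == pytest.approx(0.0, abs=1e-9)
        assert m.absolute_mm == pytest.approx(5.0)
        assert m.longitudinal_mm == pytest.approx(5.0)

    def test_tip_at_entry_raises(self):
        with pytest.raises(ValueError, match="angle undefined"):
            cn.targeting_errors([0.0, 0, 0], [0.0, 0, 100], [0.0, 0, 0])

    def test_invariant_under_common_rigid_transform(self):
        rng = np.random.default_rng(0)
        for k in range(100):
            A, B, C = rng.uniform(-50, 50, (3, 3))
            if np.allclose(A, B) or np.allclose(A, C):
                continue
            m0 = cn.targeting_errors(A, B, C)
            T = random_rigid(k)
            m1 = cn.targeting_errors(T.apply(A), T.apply(B), T.apply(C))
            assert m1.angular_deg == pytest.approx(m0.angular_deg, abs=1e-9)
            assert m1.absolute_mm == pytest.approx(m0.absolute_mm, abs=1e-9)
            assert m1.longitudinal_mm == pytest.approx(m0.longitudinal_mm, abs=1e-9)

    def test_moving_tip_along_its_ray(self):
        A, B = np.zeros(3), np.array([0.0, 0, 100])
        C = np.array([3.0, 1.0, 90.0])
        m0 = cn.targeting_errors(A, B, C)
        u = (C - A) / np.linalg.norm(C - A)
        m1 = cn.targeting_errors(A, B, C + 7.0 * u)
        assert m1.angular_deg == pytest.approx(m0.angular_deg, abs=1e-9)
        assert abs(m1.longitudinal_mm - m0.longitudinal_mm) == pytest.approx(7.0,
                                                                             abs=1e-9)

    @given(A=finite3, B=finite3, C=finite3)
    def test_triangle_inequality_with_planned_depth_point(self, A, B, C):
        A, B, C = map(np.asarray, (A, B, C))
        if np.linalg.norm(B - A) < 1e-6 or np.linalg.norm(C - A) < 1e-6:
            return
        m = cn.targeting_errors(A, B, C)
        Cp = A + np.linalg.norm(B - A) * (C - A) / np.linalg.norm(C - A)
        assert m.absolute_mm <= m.longitudinal_mm + np.linalg.norm(Cp - B) + 1e-9


class TestSummarizeGroup:
    def test_constant_group(self):
        s = cn.summarize_group([2.0, 2.0, 2.0])
        assert (s.mean, s.std, s.min, s.max) == (2.0, 0.0, 2.0, 2.0)

    def test_hand_computed_sample_std(self):
        s = cn.summarize_group([1.0, 2.0, 3.0, 4.0])
        assert s.mean == pytest.approx(2.5)
        assert s.std == pytest.approx(1.2910, abs=1e-4)
        assert (s.min, s.max) == (1.0, 4.0)

    def test_single_value_group_flagged_degenerate(self):
        s = cn.summarize_group([7.0])
        assert s.std == 0.0 and s.degenerate


class TestOneWayAnova:
    def test_identical_groups(self):
        r = cn.one_way_anova([1.0, 2, 3], [1.0, 2, 3])
        assert r.f_stat == 0.0
        assert r.p_value == 1.0

    def test_hand_sums_of_squares(self):
        r = cn.one_way_anova([1.0, 2, 3], [4.0, 5, 6])
        assert r.f_stat == pytest.approx(13.5, abs=1e-12)
        assert (r.df_between, r.df_within) == (1, 4)

    def test_f_equals_t_squared(self):
        """Two-group F is the square of the pooled two-sample t statistic."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 1.3, rng.integers(3, 12))
            r = cn.one_way_anova(a, b)
            # independent t computed from its textbook definition
            na, nb = len(a), len(b)
            sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (
                na + nb - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            assert r.f_stat == pytest.approx(t**2, abs=1e-9)
            assert r.p_value == pytest.approx(
                float(stats.t.sf(abs(t), na + nb - 2) * 2), abs=1e-9)

    def test_zero_within_variance_unequal_means(self):
        r = cn.one_way_anova([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(r.f_stat) and r.p_value == 0.0

    def test_null_p_values_are_uniform(self):
        """KS test over 2000 simulated null datasets."""
        rng = np.random.default_rng(12345)
        pvals = [cn.one_way_anova(rng.normal(size=8), rng.normal(size=8)).p_value
                 for _ in range(2000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            cn.one_way_anova([1.0], [2.0, 3.0])


class TestStudySummary:
    def _zero_noise_outcomes(self):
        noise = cn.NeedleNoise(0.0, 0.0, 100.0, 0.0)
        return [
            cn.simulate_needle_outcome(
                cn.plan_trajectory(c - 100.0 * cn.direction_from_angles(cc, 0.0), c),
                noise, seed=0)
            for c, _ in cn.default_lesions()
            for cc in (0.0, 10.0)
        ]

    def test_zero_noise_study_all_zero_and_full_success(self):
        report = cn.study_summary(self._zero_noise_outcomes())
        assert report.n_total == 16
        for metric in ("angular_deg", "absolute_mm", "longitudinal_mm"):
            assert report.summaries["overall"][metric].mean == pytest.approx(
                0.0, abs=1e-5)
        assert report.technical_success_rate == 1.0

    def test_report_mirrors_study_table_shape(self):
        report = cn.study_summary(cn.simulate_study(seed=3))
        assert set(report.summaries) == {"overall", "in_plane", "out_of_plane"}
        for row in report.summaries.values():
            assert set(row) == {"angular_deg", "absolute_mm", "longitudinal_mm",
                                "iterations", "procedural_time_s"}
        assert set(report.anova_p) == {"angular_deg", "absolute_mm",
                                       "longitudinal_mm", "iterations",
                                       "procedural_time_s"}
        text = cn.format_report_table(report)
        assert "in_plane" in text and "technical success rate" in text

    def test_large_sample_mean_angular_deviation_matches_oracle(self):
        """Mean angular deviation at simulator defaults vs a direct
        Monte-Carlo of the same transverse-Gaussian construction."""
        rng = np.random.default_rng(77)
        plan = cn.plan_trajectory([0.0, -100, 0], [0.0, 0, 0])
        noise = cn.NeedleNoise(0.68, 1.55, 300.0, 0.0)
        sims = [cn.simulate_needle_outcome(plan, noise, rng) for _ in range(10000)]
        mean_ang = np.mean([
            cn.targeting_errors(o.entry_A, o.target_B, o.tip_C).angular_deg
            for o in sims])
        # independent oracle: angle of a 2-D Gaussian tilt vector
        orng = np.random.default_rng(1234)
        th = orng.normal(0, 0.68, size=(200000, 2))
        oracle = np.mean(np.degrees(np.arctan(np.hypot(
            np.tan(np.radians(th[:, 0])), np.tan(np.radians(th[:, 1]))))))
        assert mean_ang == pytest.approx(oracle, rel=0.05)
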