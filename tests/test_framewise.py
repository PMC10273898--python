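"""Frame-wise distance-to-centre statistics and category summaries."""

import numpy as np
import pytest
from scipy import stats

from gazediff.framewise import (
    AnalysisConfig,
    UndefinedCentreError,
    UndefinedStatisticError,
    VideoDifferenceSummary,
    category_anova,
    category_summary,
    distances_to_centre,
    frame_ttest,
    framewise_arrays,
    group_centre,
    summarise,
    video_framewise,
)
from gazediff.io_gaze import FrameGazeMatrix
from gazediff.questionnaire import GroupAssignment
from gazediff.simulate import SimConfig, generate_cohort

from conftest import analyse_cohort, small_sim_config


def summary(video_id, category, pct):
    return VideoDifferenceSummary(video_id, category, 100, pct, n_frames=100)


def make_groups(participants, n_low):
    labels = {p: ("low" if i < n_low else "high") for i, p in enumerate(participants)}
    return GroupAssignment(labels=labels, split_value=0.0)


class TestCentreAndDistances:
    def test_midpoint(self):
        np.testing.assert_allclose(group_centre([(0, 0), (10, 0)]), [5, 0])

    def test_single_point_identity(self):
        np.testing.assert_allclose(group_centre([(3.5, 7.0)]), [3.5, 7.0])

    def test_missing_positions_ignored(self):
        pos = [(0, 0), (np.nan, np.nan), (10, 10)]
        np.testing.assert_allclose(group_centre(pos), [5, 5])

    def test_empty_centre_undefined(self):
        with pytest.raises(UndefinedCentreError):
            group_centre(np.full((3, 2), np.nan))

    def test_three_four_five(self):
        np.testing.assert_allclose(distances_to_centre([(3, 4)], (0, 0)), [5.0])

    def test_point_at_centre(self):
        np.testing.assert_allclose(distances_to_centre([(2, 2)], (2, 2)), [0.0])

    def test_against_brute_force(self, rng):
        for _ in range(200):
            pts = rng.uniform(-100, 100, size=(rng.integers(1, 8), 2))
            c = group_centre(pts)
            expect_c = [sum(p[0] for p in pts) / len(pts), sum(p[1] for p in pts) / len(pts)]
            np.testing.assert_allclose(c, expect_c, atol=1e-12)
            d = distances_to_centre(pts, c)
            expect_d = [((p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2) ** 0.5 for p in pts]
            np.testing.assert_allclose(d, expect_d, atol=1e-12)


class TestFrameTTest:
    def test_identical_groups(self):
        r = frame_ttest([1, 2, 3], [1, 2, 3])
        assert r.t_stat == 0 and r.p_value == 1 and not r.significant

    def test_group_swap_flips_sign(self):
        a, b = [1.0, 2, 3], [4.0, 5, 7]
        r1, r2 = frame_ttest(a, b), frame_ttest(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_textbook_example(self):
        """Pooled-variance t for {1,2,3} vs {4,5,6}: t = -3/sqrt(2/3)."""
        r = frame_ttest([1, 2, 3], [4, 5, 6])
        expected_t = -3.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert r.t_stat == pytest.approx(expected_t, abs=1e-12)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(expected_t), 4), abs=1e-12)

    def test_zero_variance_conventions(self):
        same = frame_ttest([2, 2, 2], [2, 2, 2])
        assert (same.t_stat, same.p_value, same.significant) == (0.0, 1.0, False)
        assert same.zero_variance
        diff = frame_ttest([2, 2, 2], [3, 3, 3])
        assert diff.significant and diff.p_value == 0.0 and diff.zero_variance


class TestVideoFramewise:
    def test_zero_within_group_variance_never_significant(self):
        """Everyone glued to their group's point -> all distances 0 -> 0%."""
        pos = np.zeros((50, 6, 2))
        pos[:, 3:, :] = 100.0  # high group elsewhere, but zero dispersion
        m = FrameGazeMatrix("V1", 30, [f"P{i}" for i in range(6)], pos)
        groups = make_groups(m.participants, 3)
        frames, summ = video_framewise(m, groups, AnalysisConfig())
        assert summ.pct_significant == 0.0
        assert all(f.evaluable for f in frames)

    def test_planted_dispersion_frames_detected(self):
        """Doubled high-group dispersion on frames 100-199 concentrates hits there."""
        cfg = SimConfig(
            n_participants=50, group_sizes=(25, 25),
            categories={"V1": "FUN"}, signal_videos=("V1",),
            duration_s=10.0, signal_frame_fraction=1 / 3,
            dispersion_ratio=2.0, blink_rate=0.0, seed=42,
        )
        cohort = generate_cohort(cfg)
        lo, hi = cohort.truth.signal_frames["V1"]
        assert (lo, hi) == (100, 200)
        matrices, groups, _ = analyse_cohort(cohort)
        res = framewise_arrays(matrices["V1"], groups)
        sig = np.flatnonzero(res.significant)
        inside = ((sig >= lo) & (sig < hi)).mean()
        assert inside > 0.8
        assert res.significant[lo:hi].mean() > 0.5

    def test_translation_and_scale_invariance(self, small_null_cohort):
        """pct_significant is unchanged by rigid shifts and common rescaling."""
        matrices, groups, _ = analyse_cohort(small_null_cohort)
        m = matrices["FUN_1"]
        base = summarise(framewise_arrays(m, groups)).pct_significant
        shifted = FrameGazeMatrix(m.video_id, m.fps, m.participants, m.positions + 17.0)
        scaled = FrameGazeMatrix(m.video_id, m.fps, m.participants, m.positions * 2.5)
        assert summarise(framewise_arrays(shifted, groups)).pct_significant == base
        assert summarise(framewise_arrays(scaled, groups)).pct_significant == base

    def test_vectorised_tests_match_scalar_op(self, small_signal_cohort):
        """Per-frame vectorised t/p equal frame_ttest applied frame by frame."""
        matrices, groups, _ = analyse_cohort(small_signal_cohort)
        res = framewise_arrays(matrices["FUN_1"], groups)
        for f in range(0, res.n_frames, 17):
            dl = res.dist_low_own[f]
            dh = res.dist_high_own[f]
            r = frame_ttest(dl[~np.isnan(dl)], dh[~np.isnan(dh)])
            assert res.t_stat[f] == pytest.approx(r.t_stat, abs=1e-10)
            assert res.p_value[f] == pytest.approx(r.p_value, abs=1e-10)

    def test_sparse_frames_marked_non_evaluable(self):
        pos = np.full((10, 6, 2), np.nan)
        pos[:5] = np.arange(6 * 2).reshape(1, 6, 2) * 1.0  # only first 5 frames present
        rng = np.random.default_rng(0)
        pos[:5] += rng.normal(size=(5, 6, 2))
        m = FrameGazeMatrix("V1", 30, [f"P{i}" for i in range(6)], pos)
        groups = make_groups(m.participants, 3)
        res = framewise_arrays(m, groups)
        assert res.evaluable[:5].all() and not res.evaluable[5:].any()
        assert summarise(res).n_evaluable_frames == 5

    def test_absent_group_is_an_error(self):
        m = FrameGazeMatrix("V1", 30, ["P0", "P1"], np.zeros((5, 2, 2)))
        groups = GroupAssignment(labels={"P0": "low", "P1": "low"}, split_value=0)
        with pytest.raises(ValueError, match="absent"):
            framewise_arrays(m, groups)


class TestCategorySummary:
    def test_constant_category(self):
        out = category_summary([summary(f"V{i}", "FUN", 10.0) for i in range(4)])
        assert out["FUN"] == (10.0, 0.0)

    def test_hand_computed_sem(self):
        out = category_summary(
            [summary(f"V{i}", "FUN", p) for i, p in enumerate([4.0, 6.0, 8.0, 10.0])]
        )
        assert out["FUN"][0] == pytest.approx(7.0)
        assert out["FUN"][1] == pytest.approx(np.sqrt(20 / 3) / 2, abs=1e-12)

    def test_order_invariance(self):
        s = [summary(f"V{i}", "FUN", p) for i, p in enumerate([4.0, 6.0, 8.0, 10.0])]
        assert category_summary(s) == category_summary(s[::-1])

    def test_single_video_category_flagged(self):
        with pytest.warns(UserWarning, match="SEM undefined"):
            out = category_summary([summary("V1", "FUN", 5.0)])
        assert np.isnan(out["FUN"][1])


class TestCategoryAnova:
    def four_by_four(self, rng):
        return [
            summary(f"{c}_{i}", c, float(rng.uniform(0, 30)))
            for c in ("FUN", "SPORT", "PRODUCT", "CONTROL")
            for i in range(4)
        ]

    def test_df_structure(self, rng):
        a = category_anova(self.four_by_four(rng))
        assert (a.df_between, a.df_within) == (3, 12)

    def test_between_only_variance_gives_eta_one(self):
        s = [summary(f"{c}_{i}", c, p) for c, p in
             [("FUN", 10.0), ("SPORT", 20.0), ("PRODUCT", 5.0), ("CONTROL", 8.0)]
             for i in range(4)]
        a = category_anova(s)
        assert a.eta_squared == pytest.approx(1.0)
        assert np.isinf(a.f_stat) and a.p_value == 0.0

    def test_matches_scipy_and_brute_force(self, rng):
        """F and p against scipy.stats.f_oneway; eta^2 against explicit SS."""
        for _ in range(100):
            s = self.four_by_four(rng)
            a = category_anova(s)
            groups = {}
            for x in s:
                groups.setdefault(x.category, []).append(x.pct_significant)
            f, p = stats.f_oneway(*groups.values())
            assert a.f_stat == pytest.approx(f, abs=1e-10)
            assert a.p_value == pytest.approx(p, abs=1e-10)
            allv = [v for g in groups.values() for v in g]
            grand = sum(allv) / len(allv)
            ss_total = sum((v - grand) ** 2 for v in allv)
            ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups.values())
            assert a.eta_squared == pytest.approx(ss_between / ss_total, abs=1e-10)

    def test_zero_variance_signalled(self):
        s = [summary(f"{c}_{i}", c, 5.0) for c in ("FUN", "SPORT") for i in range(2)]
        with pytest.raises(UndefinedStatisticError):
            category_anova(s)


class TestDispersionMonotonicity:
    def test_pct_significant_increases_with_dispersion_ratio(self):
        """Mean signal-video pct over seeded cohorts is monotone in the ratio."""
        means = []
        for ratio in (1.0, 1.25, 1.5, 2.0):
            pcts = []
            for seed in range(10):
                cohort = generate_cohort(small_sim_config(
                    dispersion_ratio=ratio, blink_rate=0.0, seed=100 + seed))
                matrices, groups, _ = analyse_cohort(cohort)
                res = framewise_arrays(matrices["FUN_1"], groups)
                pcts.append(summarise(res).pct_significant)
            means.append(np.mean(pcts))
        assert means == sorted(means)
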