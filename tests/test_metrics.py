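"""Action-dynamics metrics and cohort statistics."""

import numpy as np
import pytest
from scipy import stats

from ogttmm import (
    ParticipantMetrics,
    action_profile,
    cohort_tests,
    compare_time_constants,
    metric1_delays,
    metric2_peak_gap,
    metric3_nadir_gap,
    peak_time,
)
from ogttmm.actions import ActionProfile


def profile(values, step=1.0, label="glucose"):
    values = np.asarray(values, dtype=float)
    return ActionProfile(grid=np.arange(values.size) * step, values=values, label=label)


def synth_metrics(pid, dg, dgly, gap, ngap, lG=-2.0, lg=0.0):
    return ParticipantMetrics(
        participant_id=pid, t_peak_insulin=84.0, t_peak_XG=84.0 + dg,
        t_peak_Xg=84.0 + dgly, delay_glucose=dg, delay_glycerol=dgly,
        peak_gap=gap, nadir_gap=ngap, log10_p2G=lG, log10_p2g=lg, t_nadir=180.0,
    )


class TestPeakTime:
    def test_simple_peak_and_earliest_tie(self):
        assert peak_time([0, 60, 75, 90], [1, 5, 5, 2]) == 60
        assert peak_time([0, 30, 75], [1, 2, 9]) != 30

    def test_boundary_peak_warns(self):
        with pytest.warns(UserWarning, match="final point"):
            assert peak_time([0, 10, 20], [0, 1, 2]) == 20

    def test_all_zero_profile_is_an_error(self):
        with pytest.raises(ValueError, match="no action"):
            peak_time([0, 10], [0.0, 0.0])


class TestMetrics:
    def test_delay_and_gap_arithmetic(self):
        XG = profile(np.concatenate([np.arange(151), np.arange(150)[::-1]]))      # peak at 150
        Xg = profile(np.concatenate([np.arange(85), np.arange(84)[::-1]]) / 2.0)  # peak at 84
        ins_t = np.array([0.0, 75.0, 150.0])
        ins_v = np.array([26.0, 300.0, 100.0])
        d = metric1_delays(ins_t, ins_v, XG, Xg)
        assert d[0] == pytest.approx(150 - 75)
        assert metric2_peak_gap(XG, Xg) == pytest.approx(150 - 84)

    def test_identical_profiles_give_zero_gap_and_zero_nadir_gap(self):
        v = np.concatenate([[0], np.arange(1, 100), np.arange(99)[::-1]])
        XG, Xg = profile(v), profile(v, label="glycerol")
        assert metric2_peak_gap(XG, Xg) == 0.0
        assert metric3_nadir_gap(XG, Xg, 120.0) == pytest.approx(0.0)

    def test_nadir_gap_extremes(self):
        up = np.concatenate([[0], np.linspace(0.1, 1.0, 180)])   # still at peak at t=180
        down = np.concatenate([[0], np.linspace(1.0, 0.0, 180)])  # decayed to 0 at t=180
        gap = metric3_nadir_gap(profile(up), profile(down, label="glycerol"), 180.0)
        assert gap == pytest.approx(1.0)

    def test_nadir_gap_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([[0], rng.uniform(0.1, 1, 100)])
        XG, Xg = profile(v), profile(v[::-1] * 0 + np.concatenate([[0], rng.uniform(0.1, 1, 100)]))
        g1 = metric3_nadir_gap(XG, Xg, 50.0)
        XG2 = profile(v * 7.3)
        assert metric3_nadir_gap(XG2, Xg, 50.0) == pytest.approx(g1)

    def test_log_time_constant_comparison(self):
        assert compare_time_constants(0.01, 1.0) == (pytest.approx(-2.0), pytest.approx(0.0))
        with pytest.raises(ValueError):
            compare_time_constants(0.0, 0.5)


class TestActionTimingProperties:
    def test_action_peak_lags_single_peaked_drive(self, sip_forcing):
        """For a single-peaked drive the action peak is at or after the drive peak."""
        for p2 in (0.01, 0.1, 0.5, 1.0):
            prof = action_profile(p2, p2, sip_forcing, 360.0)
            t_ins = sip_forcing.times[np.argmax(sip_forcing.values)]
            assert peak_time(prof.grid, prof.values) >= t_ins

    def test_peak_time_converges_to_insulin_peak_as_p2_grows(self, sip_forcing):
        t_ins = sip_forcing.times[np.argmax(sip_forcing.values)]
        lags = []
        for p2 in (0.01, 0.1, 0.5, 1.0):
            prof = action_profile(p2, p2, sip_forcing, 360.0)
            lags.append(peak_time(prof.grid, prof.values) - t_ins)
        assert all(a >= b for a, b in zip(lags, lags[1:]))  # monotone convergence
        assert lags[-1] <= 1.0  # within one grid step at p2 = 1

    def test_faster_time_constant_gives_smaller_delay(self, sip_forcing):
        slow = action_profile(0.006, 1e-6, sip_forcing, 360.0)
        fast = action_profile(0.6, 0.6, sip_forcing, 360.0, label="glycerol")
        assert metric2_peak_gap(slow, fast) > 0


class TestCohortTests:
    def test_degenerate_wilcoxon_flagged_as_p1(self):
        ms = [synth_metrics(f"P{i}", 30.0, 30.0, 0.0, 0.0) for i in range(5)]
        st_ = cohort_tests(ms)
        assert st_.wilcoxon_delays[1] == 1.0
        assert any("delay" in f for f in st_.flags)
        assert any("zero variance" in f for f in st_.flags)  # constant peak gap

    def test_needs_two_participants(self):
        with pytest.raises(ValueError):
            cohort_tests([synth_metrics("A", 1, 2, 3, 0.1)])

    def test_matches_scipy_on_nondegenerate_cohort(self):
        rng = np.random.default_rng(12)
        dg = rng.normal(80, 20, 30)
        dgly = rng.normal(8, 5, 30)
        gaps = rng.normal(67, 10, 30)
        ngaps = rng.normal(0.3, 0.1, 30)
        ms = [synth_metrics(f"P{i}", dg[i], dgly[i], gaps[i], ngaps[i],
                            lG=rng.normal(-2, 0.2), lg=rng.normal(-0.2, 0.2))
              for i in range(30)]
        st_ = cohort_tests(ms)
        ref_w = stats.wilcoxon(np.abs(dg), np.abs(dgly))
        assert st_.wilcoxon_delays[1] == pytest.approx(ref_w.pvalue)
        ref_t = stats.ttest_1samp(gaps, 0.0)
        assert st_.ttest_peak_gap[1] == pytest.approx(ref_t.pvalue)

    def test_ci_coverage_monte_carlo(self):
        """95% CI from the one-sample t machinery covers the true mean >= 90/100 times."""
        rng = np.random.default_rng(99)
        covered = 0
        for _ in range(100):
            gaps = rng.normal(67.0, 10.0, 66)
            ms = [synth_metrics(f"P{i}", 1, 0, gaps[i], 0.1 + 0.01 * i) for i in range(66)]
            st_ = cohort_tests(ms)
            _, _, mean, half = st_.ttest_peak_gap
            if abs(mean - 67.0) <= half:
                covered += 1
        assert covered >= 90
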