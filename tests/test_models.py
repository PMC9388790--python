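"""Forward simulation of both ODE models against closed-form oracles."""

import numpy as np
import pytest

from conftest import exact_action_piecewise_linear, exact_action_step, step_forcing
from ogttmm import (
    GlycerolParams,
    OMMParams,
    action_profile,
    insulin_sensitivity,
    lipolysis_rate,
    make_forcing,
    ra_meal,
    simulate_glycerol,
    simulate_omm,
)


class TestRaMeal:
    def test_node_identity_midpoint_and_null(self):
        p = OMMParams(SG=0.02, p2G=0.01, p3=1e-6,
                      ra_breakpoints=np.array([0.0, 10.0, 30.0]),
                      ra_heights=np.array([0.0, 2.0, 4.0]))
        assert ra_meal(p, 10.0) == 2.0
        assert ra_meal(p, 20.0) == pytest.approx(3.0)
        assert ra_meal(p, 100.0) == 4.0  # held beyond last knot
        null = OMMParams(SG=0.02, p2G=0.01, p3=1e-6)
        assert np.all(ra_meal(null, np.linspace(0, 360, 20)) == 0)


class TestSimulateOMM:
    def test_basal_fixed_point(self):
        """I = Ib and no meal appearance holds G = Gb, XG = 0."""
        p = OMMParams(SG=0.02, p2G=0.012, p3=1.2e-6)
        f = make_forcing([-20.0, 360.0], [26.0, 26.0], Ib=26.0)
        grid = np.arange(0.0, 361.0)
        G, XG = simulate_omm(p, f, Gb=90.0, grid=grid)
        assert np.max(np.abs(G - 90.0)) < 1e-8
        assert np.max(np.abs(XG.values)) < 1e-8

    def test_pure_accumulation_with_constant_ra(self):
        """SG = 0 and basal insulin: G grows linearly at Ra/V."""
        r, V = 2.9, 1.45
        p = OMMParams(SG=0.0, p2G=0.01, p3=1e-6, V=V,
                      ra_breakpoints=np.array([0.0, 1e-9, 360.0]),
                      ra_heights=np.array([0.0, r, r]))
        f = make_forcing([-20.0, 360.0], [26.0, 26.0], Ib=26.0)
        grid = np.arange(0.0, 181.0)
        G, _ = simulate_omm(p, f, Gb=90.0, grid=grid)
        assert np.max(np.abs(G - (90.0 + r / V * grid))) < 1e-5

    def test_step_insulin_action_matches_closed_form(self):
        """XG(t) = (p3 c / p2G)(1 - e^(-p2G t)) for a step of excess insulin c."""
        p = OMMParams(SG=0.02, p2G=0.015, p3=2e-6)
        c = 100.0
        f = step_forcing(Ib=26.0, c=c)
        grid = np.arange(0.0, 361.0)
        _, XG = simulate_omm(p, f, Gb=90.0, grid=grid)
        exact = exact_action_step(p.p2G, p.p3 * c, grid)
        assert np.max(np.abs(XG.values - exact)) <= 1e-6

    def test_solver_tolerance_convergence(self):
        from ogttmm import omm as omm_mod

        p = OMMParams(SG=0.02, p2G=0.01, p3=1.5e-6,
                      ra_heights=np.array([0, 2, 5, 4, 3, 2, 1, 0.5, 0.2, 0.0]))
        f = step_forcing(c=150.0)
        grid = np.arange(0.0, 361.0, 5.0)
        G1, _ = simulate_omm(p, f, Gb=90.0, grid=grid)
        orig = omm_mod.SOLVER_REL_TOL
        try:
            omm_mod.SOLVER_REL_TOL = orig / 10
            G2, _ = simulate_omm(p, f, Gb=90.0, grid=grid)
        finally:
            omm_mod.SOLVER_REL_TOL = orig
        assert np.max(np.abs(G1 - G2) / np.abs(G1)) < 1e-6


class TestInsulinSensitivity:
    def test_ratio_identity_and_linearity(self):
        assert insulin_sensitivity(OMMParams(SG=0.0, p2G=0.01, p3=0.01, V=1.0)) == pytest.approx(1.0)
        a = insulin_sensitivity(OMMParams(SG=0.0, p2G=0.01, p3=1e-6))
        b = insulin_sensitivity(OMMParams(SG=0.0, p2G=0.01, p3=2e-6))
        assert b == pytest.approx(2 * a)
        assert insulin_sensitivity(OMMParams(SG=0.0, p2G=0.01, p3=2e-6, V=1.45)) == pytest.approx(2.9e-4)

    def test_zero_time_constant_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            insulin_sensitivity(OMMParams(SG=0.02, p2G=0.0, p3=1e-6))


class TestLipolysisRate:
    def test_hill_endpoints_and_half_suppression(self):
        p = GlycerolParams(Sg=0.05, l0=2.0, l2=4.0, X2=50.0, p2g=0.5)
        assert lipolysis_rate(0.0, p) == pytest.approx(6.0)       # fasted maximum l0 + l2
        assert lipolysis_rate(50.0, p) == pytest.approx(4.0)      # l0 + l2/2 at Xg = X2
        assert lipolysis_rate(1e9, p) == pytest.approx(2.0, abs=1e-6)  # floor l0
        xs = np.linspace(0, 500, 50)
        assert np.all(np.diff(lipolysis_rate(xs, p)) < 0)         # strictly decreasing


class TestSimulateGlycerol:
    def test_basal_fixed_point(self):
        """g0 = (l0+l2)/Sg and basal insulin hold glycerol constant."""
        p = GlycerolParams(Sg=0.05, l0=2.0, l2=3.9, X2=50.0, p2g=0.5)
        f = make_forcing([-20.0, 360.0], [26.0, 26.0], Ib=26.0)
        grid = np.arange(0.0, 361.0)
        g, Xg = simulate_glycerol(p, f, g0=p.basal_steady_state, grid=grid)
        assert np.max(np.abs(g - p.basal_steady_state)) < 1e-8
        assert np.max(np.abs(Xg.values)) < 1e-8

    def test_step_insulin_action_matches_closed_form(self):
        """Xg(t) = c (1 - e^(-p2g t)): plateau equals the insulin excess itself."""
        p = GlycerolParams(Sg=0.05, l0=2.0, l2=4.0, X2=50.0, p2g=0.4)
        c = 120.0
        f = step_forcing(Ib=26.0, c=c)
        grid = np.arange(0.0, 181.0)
        _, Xg = simulate_glycerol(p, f, g0=118.0, grid=grid)
        exact = exact_action_step(p.p2g, p.p2g * c, grid)
        assert np.max(np.abs(Xg.values - exact)) <= 1e-6
        assert Xg.values[-1] == pytest.approx(c, rel=1e-5)

    def test_full_suppression_limit(self):
        """A large sustained insulin step drives glycerol to the floor l0/Sg."""
        p = GlycerolParams(Sg=0.06, l0=2.0, l2=4.0, X2=20.0, p2g=0.6)
        f = step_forcing(Ib=26.0, c=5000.0, t_end=2000.0)
        grid = np.arange(0.0, 2001.0)
        g, _ = simulate_glycerol(p, f, g0=100.0, grid=grid)
        assert g[-1] == pytest.approx(p.l0 / p.Sg, rel=1e-3)
        # trajectory never falls below the full-suppression steady state
        assert np.all(g >= p.l0 / p.Sg * (1 - 1e-6))

    def test_no_rebound_above_basal_from_steady_start(self):
        p = GlycerolParams(Sg=0.05, l0=2.0, l2=3.9, X2=40.0, p2g=0.5)
        g0 = p.basal_steady_state
        f = step_forcing(Ib=26.0, c=200.0)
        g, _ = simulate_glycerol(p, f, g0=g0, grid=np.arange(0.0, 361.0))
        assert np.all(g <= g0 + 1e-9)


class TestActionProfileAgainstPiecewiseOracle:
    @pytest.mark.parametrize("p2, gain", [(0.01, 2e-6), (0.1, 0.1), (0.5, 0.5)])
    def test_matches_integrating_factor_solution(self, p2, gain, sip_forcing):
        """Dense action profile equals the exact piecewise-linear-drive solution."""
        grid = np.arange(0.0, 361.0)
        prof = action_profile(p2, gain, sip_forcing, 360.0)
        # oracle: drive knots at insulin samples plus basal crossings (none here)
        knot_t = np.linspace(0.0, 360.0, 1441)
        knot_d = gain * sip_forcing.excess(knot_t)
        exact = exact_action_piecewise_linear(p2, knot_t, knot_d, grid)
        assert np.max(np.abs(prof.values - exact)) < 1e-6 * max(1.0, np.max(exact))

    def test_action_bounded_by_drive_supremum(self, sip_forcing):
        """Xg is a weighted average of past drive, so it never exceeds its sup."""
        prof = action_profile(0.7, 0.7, sip_forcing, 360.0)
        sup = np.max(sip_forcing.excess(np.linspace(0, 360, 2000))) / 0.7
        assert np.max(prof.values) <= sup * 0.7 + 1e-9
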