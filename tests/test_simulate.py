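"""Integrator checks against closed forms and qualitative invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

from pdl1dyn import (BaseParams, EpsilonParams, TreatmentArm, DoseEvent,
                     epsilon_qss_init, final_outcome, simulate,
                     CONSTANT_EPS, DYNAMIC_EPS)
from pdl1dyn.dosing import AVELUMAB


class TestClosedForms:
    def test_exponential_growth_without_killing(self, ep, arm_by_name):
        # η → 0 decouples V: V(t) = V(0)·e^{rt}
        bp = BaseParams(eta=1e-30)
        traj = simulate(bp, ep, arm_by_name["a"], t_end=25.0)
        expected = 100.0 * np.exp(bp.r * traj.times)
        np.testing.assert_allclose(traj.V, expected, rtol=1e-6)

    def test_single_bolus_decay_and_half_life(self, bp, ep):
        arm = TreatmentArm("av0", (DoseEvent(0.0, AVELUMAB, 200.0),))
        traj = simulate(bp, ep, arm, t_end=10.0, rtol=1e-12, atol=1e-14)
        expected = 200.0 * np.exp(-bp.d_A1 * traj.times)
        np.testing.assert_allclose(traj.A1, expected, rtol=1e-8)
        assert traj.volume_at(np.array([0.0]))[0] == 100.0
        a1_half = np.interp(1.86, traj.times, traj.A1)
        assert a1_half == pytest.approx(100.0, rel=1e-3)

    def test_interdose_drug_decay(self, bp, ep, arm_by_name):
        # between boluses A1 and A2 follow pure exponential clearance
        traj = simulate(bp, ep, arm_by_name["f"], t_end=25.0,
                        rtol=1e-12, atol=1e-14)
        for t0, t1 in [(0.0, 3.0), (3.0, 6.0), (6.0, 25.0)]:
            # grid values at dose days are post-jump; the left limit of the
            # segment end lives in pre_jump
            sel = (traj.times >= t0) & (traj.times < t1)
            t = traj.times[sel]
            a1_0 = traj.A1[sel][0]
            np.testing.assert_allclose(traj.A1[sel],
                                       a1_0 * np.exp(-bp.d_A1 * (t - t0)),
                                       rtol=1e-8)
            if t1 in traj.pre_jump:
                left = traj.pre_jump[t1][2]
                assert left == pytest.approx(
                    a1_0 * np.exp(-bp.d_A1 * (t1 - t0)), rel=1e-8)
        sel = traj.times >= 0
        np.testing.assert_allclose(traj.A2,
                                   10.0 * np.exp(-bp.d_A2 * traj.times),
                                   rtol=1e-8)

    def test_epsilon_linear_ode_vs_quadrature(self, arm_by_name):
        # with T ≈ 0 the ε equation is scalar linear in ε, driven by
        # V(t) = v0·e^{rt}; integrating-factor solution via quadrature
        bp = BaseParams(delta=1e-12)
        ep = EpsilonParams()
        traj = simulate(bp, ep, arm_by_name["a"], t_end=25.0, t0_cells=0.0)
        eps0 = epsilon_qss_init(100.0, ep)

        def prod(s):
            v = 100.0 * np.exp(bp.r * s)
            return ep.k_basal * v / (ep.K_V + v)

        for t in (5.0, 12.5, 25.0):
            integral = quad(lambda s: np.exp(ep.d_eps * s) * prod(s),
                            0.0, t, epsabs=1e-12, epsrel=1e-12)[0]
            exact = np.exp(-ep.d_eps * t) * (eps0 + integral)
            got = np.interp(t, traj.times, traj.eps)
            assert got == pytest.approx(exact, rel=1e-5)


class TestTrajectoryStructure:
    def test_dose_days_on_grid_with_jumps(self, bp, ep, arm_by_name):
        traj = simulate(bp, ep, arm_by_name["f"], t_end=25.0)
        assert np.all(np.diff(traj.times) > 0)
        for day in (0.0, 3.0, 6.0):
            assert day in traj.times
            assert day in traj.pre_jump
        # post-jump A1 at day 3 exceeds the recorded left limit by the dose
        i3 = np.searchsorted(traj.times, 3.0)
        assert traj.A1[i3] == pytest.approx(traj.pre_jump[3.0][2] + 200.0)

    def test_epsilon_initialized_before_day0_dose(self, bp, ep, arm_by_name):
        traj = simulate(bp, ep, arm_by_name["f"], t_end=5.0)
        # ε(0) is the drug-free quasi-steady state despite day-0 boluses
        assert traj.eps[0] == pytest.approx(epsilon_qss_init(100.0, ep))
        assert traj.pre_jump[0.0][2] == 0.0  # A1 left limit

    def test_observation_outside_window_rejected(self, bp, ep, arm_by_name):
        traj = simulate(bp, ep, arm_by_name["a"], t_end=10.0)
        with pytest.raises(ValueError):
            traj.volume_at(np.array([11.0]))

    def test_constant_mode_carries_fixed_eps_column(self, bp, arm_by_name):
        traj = simulate(bp, 12.5, arm_by_name["a"], t_end=5.0,
                        mode=CONSTANT_EPS)
        assert np.all(traj.eps == 12.5)


class TestRobustness:
    def test_nonnegative_states_random_draws(self, rng):
        ref = BaseParams()
        for _ in range(50):
            bp = BaseParams(
                r=ref.r * rng.uniform(0.3, 3),
                eta=ref.eta * rng.uniform(0.3, 3),
                delta=ref.delta * rng.uniform(0.3, 3),
                d_T=ref.d_T * rng.uniform(0.3, 3),
                c1=ref.c1 * rng.uniform(0.3, 3),
                c2=ref.c2 * rng.uniform(0.3, 3),
                K_TQ=ref.K_TQ * rng.uniform(0.3, 3),
            )
            ep = EpsilonParams(
                k_basal=30.5441 * rng.uniform(0.3, 3),
                K_V=50.0 * rng.uniform(0.3, 3),
                alpha_A1=38.2653 * rng.uniform(0.3, 3),
                alpha_A2=643.6397 * rng.uniform(0.3, 3),
                d_eps=0.4409 * rng.uniform(0.3, 3),
            )
            from pdl1dyn import standard_arms
            arm = standard_arms("EMT6")[int(rng.integers(0, 6))]
            traj = simulate(bp, ep, arm, t_end=25.0, grid_step=0.5)
            assert np.all(traj.states >= 0)

    def test_tolerance_halving_converged(self, bp, ep, arm_by_name):
        arm = arm_by_name["e"]
        v_ref = simulate(bp, ep, arm, rtol=1e-8, atol=1e-10).V[-1]
        v_tight = simulate(bp, ep, arm, rtol=5e-9, atol=5e-11).V[-1]
        assert abs(v_tight - v_ref) <= 1e-4 * max(abs(v_ref), 1.0)

    def test_eps_stays_at_qss_without_growth_or_drugs(self, ep, arm_by_name):
        # with negligible growth and killing the pre-treatment equilibrium
        # is an invariant state of the ε equation
        bp = BaseParams(r=1e-12, eta=1e-12)
        traj = simulate(bp, ep, arm_by_name["a"], t_end=25.0)
        eq = epsilon_qss_init(100.0, ep)
        np.testing.assert_allclose(traj.eps, eq, rtol=1e-6)


class TestFinalOutcome:
    def test_classification_and_boundary(self, bp, ep, arm_by_name):
        growing = simulate(bp, ep, arm_by_name["a"], t_end=25.0)
        assert final_outcome(growing)[0] == "progressing"
        cured = simulate(bp, ep, arm_by_name["f"], t_end=25.0)
        assert final_outcome(cured)[0] == "eliminated"
        # exactly at the threshold counts as progressing (strict inequality)
        outcome, v = final_outcome(growing,
                                   elimination_threshold=growing.V[-1])
        assert outcome == "progressing"
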