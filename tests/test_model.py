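"""Unit tests for the model equations and their algebraic limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdl1dyn import (BaseParams, EpsilonParams, activation_F, base_rhs,
                     blockade_fraction, complex_Q, decay_rate_from_half_life,
                     epsilon_qss_init, epsilon_rhs, SystemState)

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestBlockadeFraction:
    def test_limits(self, bp):
        assert blockade_fraction(0.0, bp) == 0.0
        half = bp.K_A1 / bp.c1
        assert blockade_fraction(half, bp) == pytest.approx(0.5)
        huge = 1e6 * bp.K_A1 / bp.c1
        assert blockade_fraction(huge, bp) == pytest.approx(1.0 - 1e-6, rel=1e-3)

    def test_monotone_and_bounded(self, bp):
        a1 = np.geomspace(1e-3, 1e9, 60)
        vals = np.array([blockade_fraction(a, bp) for a in a1])
        assert np.all(np.diff(vals) >= 0)
        assert np.all((vals >= 0) & (vals < 1))

    def test_negative_rejected(self, bp):
        with pytest.raises(ValueError):
            blockade_fraction(-1.0, bp)


class TestComplexQ:
    def test_zero_tcells_kills_complex(self, bp):
        assert complex_Q(50.0, 0.0, 3.0, 5.0, bp) == 0.0

    def test_direct_arithmetic(self):
        p = BaseParams(q0=1.0)
        # q0·t·(t + eps·v)·(1 − φ(0)) = 1·1·(1+6)·1
        assert complex_Q(3.0, 1.0, 0.0, 2.0, p) == pytest.approx(7.0)

    def test_blockade_limit(self, bp):
        big = 1e9 * bp.K_A1 / bp.c1
        q = complex_Q(10.0, 5.0, big, 3.0, bp)
        assert q == pytest.approx(0.0, abs=1e-6 * complex_Q(10, 5, 0, 3, bp))

    @given(v=positive, t=positive, eps=positive)
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_avelumab_and_eps(self, bp, v, t, eps):
        q_grid = [complex_Q(v, t, a1, eps, bp)
                  for a1 in (0.0, 1.0, 100.0, 1e4)]
        assert all(x >= y - 1e-12 for x, y in zip(q_grid, q_grid[1:]))
        e_grid = [complex_Q(v, t, 1.0, e, bp)
                  for e in (0.0, eps, 2 * eps)]
        assert all(x <= y + 1e-12 for x, y in zip(e_grid, e_grid[1:]))


class TestActivationF:
    def test_basal_only(self, bp):
        # no drug, no T-cells: only basal production remains
        assert activation_F(5.0, 0.0, 0.0, 0.0, 1.0, bp) == pytest.approx(
            bp.delta)

    def test_suppression_limit(self, bp):
        # enormous complex drives F to zero
        big_eps = 1e12
        f = activation_F(1e3, 10.0, 0.0, 0.0, big_eps, bp)
        assert f < 1e-3 * bp.delta

    def test_saturating_stimulation(self, bp):
        t = 4.0
        big_a2 = 1e9 * bp.K_A2 / bp.c2
        f = activation_F(0.0, t, 0.0, big_a2, 0.0, BaseParams(q0=1e-12))
        assert f == pytest.approx(bp.delta + bp.lambda_T * t, rel=1e-4)

    @given(v=positive, t=positive, a2=positive, eps=positive)
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_unsuppressed_rate(self, bp, v, t, a2, eps):
        f = activation_F(v, t, 0.0, a2, eps, bp)
        assert f <= bp.delta + bp.lambda_T * t + 1e-9


class TestBaseRhs:
    def test_origin_leaves_only_basal_production(self, bp):
        dv, dt, da1, da2 = base_rhs(SystemState(0, 0, 0, 0), bp, eps=0.0)
        assert (dv, da1, da2) == (0.0, 0.0, 0.0)
        assert dt == pytest.approx(bp.delta)

    def test_pure_drug_decay(self, bp):
        _, _, da1, da2 = base_rhs(SystemState(0, 0, 50.0, 7.0), bp, eps=0.0)
        assert da1 == pytest.approx(-bp.d_A1 * 50.0)
        assert da2 == pytest.approx(-bp.d_A2 * 7.0)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            SystemState(float("nan"), 0, 0, 0)
        with pytest.raises(ValueError):
            SystemState(-5.0, 0, 0, 0)


class TestEpsilonOde:
    def test_decay_only_without_tumor_or_drugs(self, bp, ep):
        d = epsilon_rhs(10.0, 0.0, 0.0, 0.0, ep, bp)
        assert d == pytest.approx(-ep.d_eps * 10.0)

    def test_production_at_reference_volume(self, bp):
        # k_basal·V/(K_V+V) at V=100 with the fitted constants: 30.5441·(2/3)
        ep = EpsilonParams()
        d = epsilon_rhs(0.0, 100.0, 0.0, 0.0, ep, bp)
        assert d == pytest.approx(20.363, abs=5e-4)

    def test_qss_closed_form(self, bp):
        ep = EpsilonParams()
        assert epsilon_qss_init(0.0, ep) == 0.0
        assert epsilon_qss_init(100.0, ep) == pytest.approx(46.185, abs=1e-3)
        # saturation limit k_basal/d_eps
        assert epsilon_qss_init(1e12, ep) == pytest.approx(69.277, abs=5e-4)

    def test_qss_is_root_of_rhs(self, bp, rng):
        for _ in range(100):
            ep = EpsilonParams(
                k_basal=rng.uniform(0.1, 100),
                K_V=rng.uniform(1, 500),
                alpha_A1=rng.uniform(0.1, 100),
                alpha_A2=rng.uniform(0.1, 1000),
                d_eps=rng.uniform(0.01, 5),
            )
            v0 = rng.uniform(0.1, 5000)
            eq = epsilon_qss_init(v0, ep)
            assert abs(epsilon_rhs(eq, v0, 0.0, 0.0, ep, bp)) < 1e-10 * max(
                1.0, ep.k_basal)

    def test_restoring_sign_around_qss(self, bp, ep):
        eq = epsilon_qss_init(100.0, ep)
        assert epsilon_rhs(eq * 1.1, 100.0, 0, 0, ep, bp) < 0
        assert epsilon_rhs(eq * 0.9, 100.0, 0, 0, ep, bp) > 0


class TestHalfLifeConversion:
    @pytest.mark.parametrize("t_half, rate, tol", [
        (1.86, 0.3726, 5e-4),       # Avelumab, murine serum half-life
        (9.5, 0.0730, 5e-4),        # NHS-muIL12
        (math.log(2.0), 1.0, 1e-12),
    ])
    def test_known_conversions(self, t_half, rate, tol):
        assert decay_rate_from_half_life(t_half) == pytest.approx(rate, abs=tol)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            decay_rate_from_half_life(bad)


class TestParamValidation:
    def test_positive_invariant(self):
        with pytest.raises(ValueError):
            BaseParams(r=-0.1)
        with pytest.raises(ValueError):
            EpsilonParams(d_eps=0.0)

    def test_clearance_matches_half_life(self, bp):
        assert bp.d_A1 == pytest.approx(math.log(2) / 1.86, rel=1e-3)
        assert bp.d_A2 == pytest.approx(math.log(2) / 9.5, rel=1e-3)
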