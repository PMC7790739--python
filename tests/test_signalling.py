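"""Tests of the Wnt/Hippo signalling ODE network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryptdyn.signalling import (ALL_SPECIES, SPECIES, HippoInput,
                                 SignallingParams, SignallingState,
                                 _rhs_vector, integrate_signalling,
                                 signalling_rhs, steady_state,
                                 wnt_modulated_rates)


@pytest.fixture(scope="module")
def params():
    return SignallingParams()


def _state(params, **overrides):
    base = dict(X=1.0, D=5.0, A=10.0, C_A=10.0, C_C=20.0, C_T=8.0,
                C_U=1.0, C_H=2.0, Y=3.0)
    base.update(overrides)
    base["T"] = params.T_total - base["C_T"]
    return SignallingState(**base)


class TestWntModulatedRates:
    def test_boundaries_return_off_and_on_values(self, params):
        assert wnt_modulated_rates(params, 0.0) == (
            params.dX_off, params.dDX_off, params.dD_off)
        assert wnt_modulated_rates(params, 1.0) == (
            params.dX_on, params.dDX_on, params.dD_on)

    def test_midpoint_is_arithmetic_mean(self, params):
        # linear interpolation evaluated independently
        expected = tuple(0.5 * (a + b) for a, b in
                         [(params.dX_off, params.dX_on),
                          (params.dDX_off, params.dDX_on),
                          (params.dD_off, params.dD_on)])
        assert wnt_modulated_rates(params, 0.5) == pytest.approx(expected)

    @pytest.mark.parametrize("W", [-0.1, 1.1, 2.0])
    def test_rejects_out_of_range(self, params, W):
        with pytest.raises(ValueError):
            wnt_modulated_rates(params, W)


class TestRhs:
    def test_hippo_flux_mass_conserving(self, params):
        """Binding/unbinding moves beta-catenin between C_C and C_H only."""
        s = _state(params)
        on = signalling_rhs(s, params, 0.7, HippoInput(p_hat_H=5000.0))
        off = signalling_rhs(s, params, 0.7, HippoInput(p_hat_H=0.0))
        # switching binding on changes dC_C and dC_H by equal and
        # opposite amounts (the flux-matching identity)
        assert on["C_C"] - off["C_C"] == pytest.approx(
            -(on["C_H"] - off["C_H"]), rel=1e-12)
        # and touches no other species' derivative
        for sp in ALL_SPECIES:
            if sp not in ("C_C", "C_H"):
                assert on[sp] == pytest.approx(off[sp], rel=1e-12)

    def test_hippo_off_leaves_no_complex_inflow(self, params):
        s = _state(params, C_H=4.0)
        d = signalling_rhs(s, params, 1.0, HippoInput(0.0))
        # pure decay of the existing complex, no binding inflow
        assert d["C_H"] == pytest.approx(
            -(params.k_off + params.d_CH) * 4.0)

    def test_transcription_molecules_conserved(self, params):
        d = signalling_rhs(_state(params), params, 0.5, HippoInput(100.0))
        assert d["T"] + d["C_T"] == pytest.approx(0.0, abs=1e-12)

    def test_rejects_negative_state(self, params):
        s = _state(params, C_C=-1.0)
        with pytest.raises(ValueError):
            signalling_rhs(s, params, 0.5, HippoInput(0.0))

    def test_steady_state_has_zero_rhs(self, params):
        ss = steady_state(params, 1.0, 0.0)
        d = signalling_rhs(ss, params, 1.0, HippoInput(0.0))
        assert np.linalg.norm([d[s] for s in SPECIES]) < 1e-8


class TestSteadyState:
    def test_monotone_decreasing_in_hippo_rate(self, params):
        cts = [steady_state(params, 1.0, ph).C_T
               for ph in (0.0, 5e3, 1.3e4, 2.6e4, 5e4)]
        assert all(a >= b - 1e-9 for a, b in zip(cts, cts[1:]))

    def test_monotone_increasing_in_wnt(self, params):
        for ph in (0.0, 2.6e4):
            cts = [steady_state(params, w, ph).C_T
                   for w in (0.0, 0.25, 0.5, 0.75, 1.0)]
            assert all(b >= a - 1e-9 for a, b in zip(cts, cts[1:]))

    def test_wnt_on_raises_transcriptional_pool(self, params):
        assert (steady_state(params, 1.0).C_T
                > 3.0 * steady_state(params, 0.0).C_T)


class TestIntegration:
    def test_zero_length_span_returns_initial_state(self, params):
        s0 = _state(params)
        t, states = integrate_signalling(s0, params, 1.0, 0.0, (0.0, 0.0))
        assert len(states) == 1 and states[0] == s0

    def test_matches_fixed_step_rk4_oracle(self, params):
        """Adaptive integration agrees with brute-force RK4 at dt=1e-4 h."""
        s0 = _state(params)
        t, states = integrate_signalling(s0, params, 0.8, 1e4, (0.0, 10.0),
                                         rtol=1e-8, atol=1e-11)
        y = s0.to_vector()
        dt = 1e-4
        for _ in range(100_000):
            k1 = _rhs_vector(y, params, 0.8, 1e4)
            k2 = _rhs_vector(y + 0.5 * dt * k1, params, 0.8, 1e4)
            k3 = _rhs_vector(y + 0.5 * dt * k2, params, 0.8, 1e4)
            k4 = _rhs_vector(y + dt * k3, params, 0.8, 1e4)
            y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        np.testing.assert_allclose(states[-1].to_vector(), y, atol=1e-5)

    def test_long_integration_converges_to_steady_state(self, params):
        s0 = _state(params)
        _, states = integrate_signalling(s0, params, 1.0, 0.0, (0.0, 500.0))
        expected = steady_state(params, 1.0, 0.0)
        np.testing.assert_allclose(states[-1].to_vector(),
                                   expected.to_vector(), rtol=1e-4,
                                   atol=1e-6)

    def test_tolerance_refinement_converges(self, params):
        s0 = _state(params)
        terminal = {}
        for tol in (1e-6, 5e-7):
            _, states = integrate_signalling(s0, params, 0.5, 2.6e4,
                                             (0.0, 20.0), rtol=tol,
                                             atol=tol * 1e-3)
            terminal[tol] = states[-1].C_T
        assert abs(terminal[1e-6] - terminal[5e-7]) < 10 * 1e-6 * 50.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 2.6e4),
           st.integers(0, 2**31 - 1))
    def test_non_negativity_preserved(self, W, p_hat, seed):
        params = SignallingParams()
        rng = np.random.default_rng(seed)
        y0 = rng.uniform(0.0, 40.0, 9)
        y0[5] = min(y0[5], params.T_total)  # C_T cannot exceed total TCF
        s0 = SignallingState.from_vector(y0, params.T_total)
        _, states = integrate_signalling(s0, params, W, p_hat, (0.0, 5.0))
        for s in states:
            assert np.all(s.to_vector() >= 0.0)
            assert s.T >= -1e-9
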