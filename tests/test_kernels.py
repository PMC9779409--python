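"""Closed-form kernels: exactness, limiting cases and singular handling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radonchamber import oracle
from radonchamber.kernels import (
    ChainState,
    SystemParameters,
    bateman,
    concentrations_at,
    constant_parent,
    singular_guard,
    steady_state,
)

from conftest import random_scenario


def relerr(a, b, floor=1e-12):
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), floor))


class TestConcentrationsAt:
    def test_time_zero_returns_initial_state(self, thoron):
        params = SystemParameters(V=5.0, E1=2.0, Q_D=0.01, F=0.5)
        state0 = ChainState(np.arange(1.0, 7.0))
        assert np.array_equal(concentrations_at(thoron, params, state0, 0.0), state0.values)

    def test_gas_constant_when_seeded_at_steady_state(self, radon):
        """Inflow exactly compensates decay when C_o1 = S1/lambda_1, whatever
        the device does."""
        params = SystemParameters(V=20.0, E1=1.0, Q_D=0.05, F=0.7)
        c1 = params.S1 / radon.gas.decay_constant
        state0 = ChainState.gas_only(radon, c1)
        for t in (60.0, 3600.0, 30 * 86400.0):
            out = concentrations_at(radon, params, state0, t)
            assert out[0] == pytest.approx(c1, rel=1e-12)

    def test_gas_trajectory_independent_of_removal_rate(self, thoron):
        state0 = ChainState.gas_only(thoron, 500.0)
        t = np.linspace(0.0, 3 * 3600.0, 50)
        base = concentrations_at(
            thoron, SystemParameters(V=2.0, E1=0.3), state0, t)[:, 0]
        filtered = concentrations_at(
            thoron, SystemParameters(V=2.0, E1=0.3, Q_D=0.05, F=1.0), state0, t)[:, 0]
        np.testing.assert_allclose(filtered, base, rtol=1e-14)

    @pytest.mark.parametrize("gas", ["Rn-222", "Rn-220"])
    def test_matches_stiff_oracle_on_random_scenarios(self, gas, radon, thoron):
        chain = radon if gas == "Rn-222" else thoron
        rng = np.random.default_rng(7)
        for _ in range(10):
            params, state0, t = random_scenario(rng, chain)
            if singular_guard(chain, params).must_fallback:
                continue
            closed = concentrations_at(chain, params, state0, t)
            ref = oracle.integrate(chain, params, state0, np.array([t]), engine="radau")[0]
            assert relerr(closed, ref) < 1e-8

    def test_pure_decay_matches_oracle(self, radon):
        """No source, no filtration: plain chain decay of an initial gas load."""
        params = SystemParameters(V=1.0)
        state0 = ChainState.gas_only(radon, 100.0)
        for t in (60.0, 3600.0, 86400.0):
            closed = concentrations_at(radon, params, state0, t)
            ref = oracle.integrate(radon, params, state0, np.array([t]), engine="radau")[0]
            assert relerr(closed, ref) < 1e-8

    def test_long_time_limit_is_source_over_lambda(self, radon):
        """With no filtration every radon-chain member approaches S1/lambda_1."""
        params = SystemParameters(V=20.0, E1=1.0)
        out = concentrations_at(radon, params, ChainState.zeros(radon), 200 * 86400.0)
        c_inf = params.S1 / radon.gas.decay_constant
        assert c_inf == pytest.approx(2.38e4, rel=0.01)
        np.testing.assert_allclose(out, c_inf, rtol=1e-6)

    def test_negative_time_rejected(self, radon):
        with pytest.raises(ValueError, match="time"):
            concentrations_at(radon, SystemParameters(V=1.0), ChainState.zeros(radon), -1.0)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            SystemParameters(V=math.nan, E1=1.0)
        with pytest.raises(ValueError):
            SystemParameters(V=1.0, E1=math.inf)
        with pytest.raises(ValueError):
            SystemParameters(V=1.0, F=1.5)

    def test_vectorized_grid_matches_scalar_calls(self, thoron):
        params = SystemParameters(V=3.0, E1=0.5, Q_D=0.001, F=0.9)
        state0 = ChainState(np.full(6, 10.0))
        grid = np.array([10.0, 100.0, 5000.0])
        block = concentrations_at(thoron, params, state0, grid)
        for k, t in enumerate(grid):
            np.testing.assert_array_equal(
                block[k], concentrations_at(thoron, params, state0, t))


class TestAlgebraicProperties:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(1e-3, 1e3), seed=st.integers(0, 2**16))
    def test_linearity_in_initial_state_and_inflow(self, thoron, alpha, seed):
        rng = np.random.default_rng(seed)
        params, state0, t = random_scenario(rng, thoron)
        scaled = SystemParameters(V=params.V, E1=alpha * params.E1, Q_D=params.Q_D, F=params.F)
        a = concentrations_at(thoron, scaled, ChainState(alpha * state0.values), t)
        b = alpha * concentrations_at(thoron, params, state0, t)
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-300)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_superposition_of_initial_state_and_source(self, radon, seed):
        rng = np.random.default_rng(seed)
        params, state0, t = random_scenario(rng, radon)
        no_source = SystemParameters(V=params.V, E1=0.0, Q_D=params.Q_D, F=params.F)
        full = concentrations_at(radon, params, state0, t)
        decay_only = concentrations_at(radon, no_source, state0, t)
        source_only = concentrations_at(radon, params, ChainState.zeros(radon), t)
        np.testing.assert_allclose(full, decay_only + source_only, rtol=1e-10, atol=1e-300)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_non_negative_outputs(self, thoron, seed):
        rng = np.random.default_rng(seed)
        params, state0, t = random_scenario(rng, thoron)
        assert np.all(concentrations_at(thoron, params, state0, t) >= 0.0)


class TestBateman:
    def test_single_parent_halves_per_half_life(self, radon):
        state0 = ChainState.gas_only(radon, 1000.0)
        out = bateman(radon, state0, radon.gas.half_life)
        assert out[0] == pytest.approx(500.0, rel=1e-12)

    def test_time_zero(self, thoron):
        state0 = ChainState(np.linspace(1, 6, 6))
        assert np.array_equal(bateman(thoron, state0, 0.0), state0.values)

    def test_reduces_concentrations_at_bit_identically(self, thoron):
        """bateman is concentrations_at at S1 = 0, R_D = 0, to the last bit."""
        rng = np.random.default_rng(3)
        state0 = ChainState(rng.uniform(0, 100, 6))
        grid = np.array([1.0, 60.0, 3600.0, 86400.0])
        via_params = concentrations_at(
            thoron, SystemParameters(V=1.0), state0, grid)
        np.testing.assert_array_equal(bateman(thoron, state0, grid), via_params)

    def test_transient_equilibrium_after_ingrowth(self, radon):
        """Four hours after a pure radon injection the progeny track the gas."""
        state0 = ChainState.gas_only(radon, 1000.0)
        out = bateman(radon, state0, 4 * 3600.0)
        np.testing.assert_allclose(out[1:], out[0], rtol=0.01)


class TestConstantParent:
    def test_time_zero(self, thoron):
        state0 = ChainState(np.ones(6))
        assert np.array_equal(constant_parent(thoron, state0, 0.0), state0.values)

    def test_gas_never_decays(self, thoron):
        state0 = ChainState.gas_only(thoron, 1000.0)
        out = constant_parent(thoron, state0, np.array([60.0, 3600.0, 300 * 3600.0]))
        np.testing.assert_array_equal(out[:, 0], 1000.0)

    def test_thoron_reaches_true_equilibrium(self, thoron):
        """With the gas held constant even the thoron chain equilibrates:
        Pb-212 and Bi-212 reach the gas concentration."""
        state0 = ChainState.gas_only(thoron, 1000.0)
        out = constant_parent(thoron, state0, 300 * 3600.0)
        for name in ("Pb-212", "Bi-212"):
            assert out[thoron.index(name)] == pytest.approx(1000.0, rel=1e-3)
        # the branch members split the feed by their branch fractions
        assert out[thoron.index("Po-212")] == pytest.approx(638.0, rel=1e-3)
        assert out[thoron.index("Tl-208")] == pytest.approx(362.0, rel=1e-3)

    def test_radon_progeny_equilibrate_within_a_day(self, radon):
        state0 = ChainState.gas_only(radon, 1000.0)
        out = constant_parent(radon, state0, 24 * 3600.0)
        np.testing.assert_allclose(out, 1000.0, rtol=1e-4)

    def test_matches_oracle_with_zero_gas_decay(self, thoron):
        """Independent check: integrate the cascade with lambda_1 forced to 0."""
        params = SystemParameters(V=1.0)
        A = oracle.rate_matrix(thoron, params)
        A[0, 0] = 0.0
        state0 = ChainState.gas_only(thoron, 1000.0)
        t = np.array([600.0, 7200.0])
        from scipy.integrate import solve_ivp

        sol = solve_ivp(lambda _, y: A @ y, (0, t[-1]), state0.values, method="Radau",
                        t_eval=t, jac=lambda _, y: A, rtol=1e-10, atol=1e-8)
        np.testing.assert_allclose(constant_parent(thoron, state0, t), sol.y.T,
                                   rtol=1e-7, atol=1e-9)


class TestSteadyState:
    def test_secular_equilibrium_without_filtration(self, radon):
        params = SystemParameters(V=20.0, E1=1.0)
        ss = steady_state(radon, params)
        np.testing.assert_allclose(ss, params.S1 / radon.gas.decay_constant, rtol=1e-12)

    def test_pb214_ratio_under_device(self, radon):
        """10 L/min at full efficiency in 20 m^3 gives R_D ~ 8.33e-6 s^-1 and
        depresses Pb-214 to ~97.9% of the gas."""
        params = SystemParameters.with_device(V=20.0, E1=1.0, flow_L_per_min=10.0, F=1.0)
        assert params.R_D == pytest.approx(8.333e-6, rel=1e-3)
        ss = steady_state(radon, params)
        expected = np.prod([
            n.decay_constant / (n.decay_constant + params.R_D)
            for n in radon.members[1:3]
        ])
        assert ss[radon.index("Pb-214")] / ss[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.979, abs=0.001)

    def test_is_long_time_limit_of_closed_form(self, radon):
        params = SystemParameters.with_device(V=5.0, E1=0.4, flow_L_per_min=25.0, F=0.8)
        ss = steady_state(radon, params)
        out = concentrations_at(radon, params, ChainState.zeros(radon), 200 * 86400.0)
        np.testing.assert_allclose(out, ss, rtol=1e-6)

    def test_zero_inflow_returns_zero_state(self, thoron):
        assert np.array_equal(steady_state(thoron, SystemParameters(V=1.0)), np.zeros(6))


class TestSingularGuard:
    def test_radon_never_singular(self, radon):
        for q in (0.0, 0.01, 0.2489, 10.0):
            report = singular_guard(radon, SystemParameters(V=20.0, Q_D=q, F=1.0))
            assert report.flagged == ()

    def test_thoron_flags_pb212_denominator_at_critical_flow(self, thoron):
        lam1 = thoron.gas.decay_constant
        lam3 = thoron.members[thoron.index("Pb-212")].decay_constant
        params = SystemParameters(V=20.0, Q_D=20.0 * (lam1 - lam3), F=1.0)
        flagged = singular_guard(thoron, params).flagged
        assert any({a, b} == {"Rn-220", "Pb-212"} for a, b, _ in flagged)

    def test_thoron_unfiltered_not_singular(self, thoron):
        assert singular_guard(thoron, SystemParameters(V=20.0)).flagged == ()

    def test_fallback_at_exact_singularity_matches_oracle(self, thoron):
        lam1 = thoron.gas.decay_constant
        lam3 = thoron.members[thoron.index("Pb-212")].decay_constant
        params = SystemParameters(V=20.0, E1=1.0, Q_D=20.0 * (lam1 - lam3), F=1.0)
        state0 = ChainState.zeros(thoron)
        closed = concentrations_at(thoron, params, state0, 7200.0)
        ref = oracle.integrate(thoron, params, state0, np.array([7200.0]), engine="radau")[0]
        assert relerr(closed, ref) < 1e-8

    def test_singular_limit_continuity(self, thoron):
        """Approaching the critical removal rate from either side converges to
        the regular ODE value at the singular point."""
        lam1 = thoron.gas.decay_constant
        lam3 = thoron.members[thoron.index("Pb-212")].decay_constant
        state0 = ChainState.gas_only(thoron, 1000.0)
        t = 7200.0
        at_singular = oracle.integrate(
            thoron, SystemParameters(V=1.0, E1=0.1, Q_D=lam1 - lam3, F=1.0),
            state0, np.array([t]))[0]
        errs = []
        for delta in (1e-3 * lam1, 1e-5 * lam1, 1e-7 * lam1):
            params = SystemParameters(V=1.0, E1=0.1, Q_D=lam1 - lam3 + delta, F=1.0)
            out = concentrations_at(thoron, params, state0, t)
            errs.append(relerr(out, at_singular))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-6
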