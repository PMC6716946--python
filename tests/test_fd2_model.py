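"""Unit and property tests for the FD2 release simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from fd2pool.fd2 import (
    FD2ConfigError,
    FD2Params,
    ModelState,
    evolve,
    facilitation,
    fire,
    init_state,
    ppr,
    recovery_rate,
    sample_counts,
    simulate_train,
)


def two_pulse_oracle(params: FD2Params, isi: float) -> float:
    """Independent closed-form paired-pulse ratio for two stimuli.

    Walks the two-pulse protocol by hand and integrates the recovery rate
    over the decaying calcium sensor with adaptive quadrature, so it shares
    no code path with the simulator's analytic rate integral.
    """
    f1, d1 = params.F_base, 1.0
    # post-pulse state
    ca_f, ca_d, d = params.delta_F, params.delta_D, d1 * (1.0 - f1)
    # facilitation at the second pulse
    ca_f2 = ca_f * math.exp(-isi / params.tau_F)
    f2 = params.F_base + (1.0 - params.F_base) * ca_f2 / (ca_f2 + params.K_F)

    def k_of_t(t):
        c = ca_d * math.exp(-t / params.tau_D)
        return params.k_0 + (params.k_max - params.k_0) * c / (c + params.K_D)

    integral, _ = quad(k_of_t, 0.0, isi, epsabs=1e-12, epsrel=1e-12)
    d2 = 1.0 - (1.0 - d) * math.exp(-integral)
    return (f2 * d2) / (f1 * d1)


class TestStateAndRates:
    def test_initial_state_is_rested(self, default_params):
        state = init_state(default_params)
        assert (state.CaX_F, state.CaX_D, state.D, state.t) == (0.0, 0.0, 1.0, 0.0)
        assert facilitation(state.CaX_F, default_params) == default_params.F_base

    def test_empty_pool_has_zero_rrp(self):
        assert FD2Params(N_T=7, P_occ=0.0).rrp == 0.0

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"tau_F": -0.1}, "tau_F"),
            ({"F_base": 1.5}, "F_base"),
            ({"P_occ": -0.2}, "P_occ"),
            ({"N_T": 0}, "N_T"),
            ({"k_max": 0.1}, "k_max"),  # below k_0
        ],
    )
    def test_invalid_parameters_name_the_field(self, kwargs, field):
        with pytest.raises(FD2ConfigError, match=field.split("_")[0]):
            FD2Params(**kwargs)

    @pytest.mark.parametrize(
        "ca, f_base, k_f, expected",
        [
            (0.0, 0.4, 2.0, 0.4),  # zero residual calcium -> baseline
            (3.03265, 0.4, 2.0, 0.4 + 0.6 * 3.03265 / 5.03265),
            (1e9, 0.4, 2.0, pytest.approx(1.0, abs=1e-8)),  # saturation
        ],
    )
    def test_facilitation_values(self, ca, f_base, k_f, expected):
        params = FD2Params(F_base=f_base, K_F=k_f)
        assert facilitation(ca, params) == pytest.approx(expected, rel=1e-12)

    def test_facilitation_rejects_negative_calcium(self, default_params):
        with pytest.raises(ValueError):
            facilitation(-0.1, default_params)

    @pytest.mark.parametrize(
        "ca, expected",
        [
            (0.0, 0.7),  # baseline recovery rate
            (2.0, 0.7 + (20.0 - 0.7) / 2.0),  # half-saturation at K_D
            (1e12, pytest.approx(20.0, abs=1e-6)),
        ],
    )
    def test_recovery_rate_values(self, ca, expected, default_params):
        assert recovery_rate(ca, default_params) == pytest.approx(expected, rel=1e-9)

    @given(ca=st.floats(0.0, 1e3), ca2=st.floats(0.0, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_facilitation_and_recovery_are_monotone(self, ca, ca2):
        params = FD2Params(F_base=0.3)
        lo, hi = sorted((ca, ca2))
        assert facilitation(lo, params) <= facilitation(hi, params)
        assert recovery_rate(lo, params) <= recovery_rate(hi, params)


class TestEvolve:
    def test_zero_dt_is_identity(self, default_params):
        state = ModelState(CaX_F=1.0, CaX_D=0.5, D=0.7, t=2.0)
        assert evolve(state, 0.0, default_params) == state

    def test_calcium_decays_exponentially(self, default_params):
        state = ModelState(CaX_F=5.0, CaX_D=0.0, D=1.0)
        out = evolve(state, 0.05, default_params)
        assert out.CaX_F == pytest.approx(5.0 * math.exp(-0.5), rel=1e-12)
        assert out.t == pytest.approx(0.05)

    def test_recovery_toward_one_with_low_calcium(self, default_params):
        # near-zero CaX_D keeps the rate pinned between k_0 and k(0.001)
        out = evolve(ModelState(CaX_D=0.001, D=0.6), 0.05, default_params)
        assert out.D == pytest.approx(0.6138, abs=5e-4)

    def test_negative_dt_rejected(self, default_params):
        with pytest.raises(ValueError):
            evolve(init_state(default_params), -1e-3, default_params)


class TestFire:
    def test_first_pulse_release_high_occupancy(self):
        # seven sites, five occupied, 90% success -> 4.5 vesicles on average
        params = FD2Params(N_T=7, P_occ=5 / 7, F_base=0.90)
        _, rec = fire(init_state(params), params)
        assert rec.V_released == pytest.approx(4.5, abs=1e-12)
        assert rec.P_succ == pytest.approx(0.90)

    def test_empty_pool_releases_nothing(self):
        params = FD2Params(P_occ=0.0, F_base=0.95)
        _, rec = fire(init_state(params), params)
        assert rec.V_released == 0.0

    def test_single_site_bounded_by_one(self, rng):
        for _ in range(20):
            params = FD2Params(
                N_T=1, P_occ=rng.random(), F_base=rng.random()
            )
            _, rec = fire(init_state(params), params)
            assert rec.V_released <= 1.0

    def test_release_bookkeeping_identity(self, default_params):
        _, rec = fire(init_state(default_params), default_params)
        assert rec.V_released == pytest.approx(
            default_params.N_T * default_params.P_occ * rec.F * rec.D, rel=1e-12
        )


class TestSimulateTrain:
    def test_single_stimulus_has_no_history(self, default_params):
        traj = simulate_train([0.0], default_params)
        assert len(traj.pulses) == 1
        assert traj.pulses[0].F == default_params.F_base
        assert traj.pulses[0].D == 1.0

    def test_low_success_two_pulse_facilitates(self):
        # low-occupancy, low-success operating point: sub-unitary release
        # with paired-pulse facilitation approaching 1.2
        params = FD2Params(N_T=7, P_occ=0.30, F_base=0.40)
        traj = simulate_train([0.0, 0.05], params)
        assert traj.pulses[0].V_released == pytest.approx(0.84, abs=1e-12)
        assert traj.pulses[0].V_released < 1.0
        assert ppr(traj) == pytest.approx(1.168, abs=2e-3)
        assert round(ppr(traj), 1) == 1.2

    def test_high_success_two_pulse_depresses(self):
        params = FD2Params(N_T=7, P_occ=5 / 7, F_base=0.90)
        assert ppr(simulate_train([0.0, 0.05], params)) < 1.0

    def test_non_monotone_times_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate_train([0.0, 0.05, 0.04], default_params)

    @pytest.mark.parametrize("f_base", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("isi", [0.010, 0.025, 0.050, 0.100, 0.500])
    def test_matches_quadrature_two_pulse_oracle(self, f_base, isi):
        params = FD2Params(N_T=7, P_occ=0.5, F_base=f_base)
        simulated = ppr(simulate_train([0.0, isi], params))
        assert simulated == pytest.approx(two_pulse_oracle(params, isi), abs=1e-6)

    def test_ppr_recovers_to_unity_at_long_intervals(self):
        params = FD2Params(N_T=7, P_occ=0.5, F_base=0.9)
        assert ppr(simulate_train([0.0, 60.0], params)) == pytest.approx(1.0, abs=0.01)

    def test_static_dynamics_give_unit_ppr(self):
        # increments off and a huge recovery rate freeze the state
        params = FD2Params(
            delta_F=0.0, delta_D=0.0, k_0=1e6, k_max=1e6, F_base=0.5, P_occ=0.4
        )
        assert ppr(simulate_train([0.0, 0.05], params)) == pytest.approx(1.0, abs=1e-9)


class TestInvariants:
    def test_occupancy_is_a_pure_scale_factor(self, rng):
        """All within-train amplitude ratios are independent of P_occ."""
        times = np.cumsum(rng.uniform(0.005, 0.2, size=10))
        for _ in range(10):
            f_base = rng.uniform(0.05, 0.95)
            base = None
            for p_occ in (0.1, 0.35, 0.9):
                params = FD2Params(N_T=7, P_occ=p_occ, F_base=f_base)
                v = simulate_train(times, params).v_released()
                ratios = v / v[0]
                if base is None:
                    base = ratios
                else:
                    assert np.max(np.abs(ratios - base)) <= 1e-12

    def test_state_conservation_along_long_train(self, rng):
        for _ in range(5):
            params = FD2Params(
                N_T=int(rng.integers(1, 11)),
                P_occ=rng.random(),
                F_base=rng.uniform(0.05, 0.95),
            )
            times = np.arange(50) / rng.uniform(5, 100)
            state = init_state(params)
            prev_t = 0.0
            for t in times:
                state = evolve(state, t - prev_t, params)
                state, rec = fire(state, params)
                prev_t = t
                assert 0.0 <= state.D <= 1.0
                assert state.CaX_F >= 0 and state.CaX_D >= 0
                assert 0.0 <= rec.V_released <= params.N_T * params.P_occ + 1e-12


class TestSampleCounts:
    def test_degenerate_probabilities(self):
        params0 = FD2Params(N_T=7, P_occ=0.0, F_base=0.9)
        traj = simulate_train([0.0, 0.05], params0)
        assert np.all(sample_counts(traj, params0, seed=1) == 0)
        # saturated: full occupancy, certain success, frozen dynamics
        params1 = FD2Params(
            N_T=7, P_occ=1.0, F_base=1.0, delta_F=0.0, delta_D=0.0, k_0=1e7, k_max=1e7
        )
        traj = simulate_train([0.0, 0.05], params1)
        assert np.all(sample_counts(traj, params1, seed=1) == 7)

    def test_binomial_moments(self):
        params = FD2Params(N_T=7, P_occ=5 / 7, F_base=0.90)
        traj = simulate_train([0.0], params)
        reps = 100_000
        rng = np.random.default_rng(7)
        draws = np.array([sample_counts(traj, params, rng)[0] for _ in range(reps)])
        p = params.P_occ * 0.90
        mean, var = params.N_T * p, params.N_T * p * (1 - p)
        assert draws.mean() == pytest.approx(mean, abs=3 * math.sqrt(var / reps))
        assert draws.var() == pytest.approx(var, rel=0.05)

    def test_seed_reproducibility(self, default_params):
        traj = simulate_train([0.0, 0.05, 0.1], default_params)
        a = sample_counts(traj, default_params, seed=42)
        b = sample_counts(traj, default_params, seed=42)
        assert np.array_equal(a, b)
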