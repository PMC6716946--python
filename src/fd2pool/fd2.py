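"""Event-driven simulator of the FD2 short-term plasticity model.

The model describes an active zone with ``N_T`` vesicle docking sites, each
occupied with probability ``P_occ`` (set upstream by kinase/synapsin state
and static within a train). A presynaptic action potential releases each
docked, release-ready vesicle with probability ``P_succ = F * D`` where

* ``F`` is a calcium-driven facilitation probability that relaxes to a
  baseline ``F_base`` and saturates toward 1 as the facilitation sensor
  ``CaX_F`` accumulates, and
* ``D`` is the fraction of sites whose release machinery has recovered from
  the refractory state entered after release; recovery is accelerated by a
  second calcium sensor ``CaX_D``.

Both sensors jump by a fixed increment at each stimulus and decay
exponentially between stimuli. The expected number of vesicles released per
active zone and stimulus is ``V_released = N_T * P_occ * F * D``; the
resting readily-releasable pool is ``RRP = N_T * P_occ``.

Between stimuli the refractory-recovery ODE

    dD/dt = (1 - D) * k(CaX_D(t)),
    k(c)  = k_0 + (k_max - k_0) * c / (c + K_D)

is integrated exactly: with ``CaX_D(t) = c0 * exp(-t/tau_D)`` the rate
integral has the closed form
``k_0*dt + (k_max-k_0)*tau_D*log[(c0+K_D)/(c0*exp(-dt/tau_D)+K_D)]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "FD2Params",
    "ModelState",
    "PulseRecord",
    "ReleaseTrajectory",
    "init_state",
    "facilitation",
    "recovery_rate",
    "evolve",
    "fire",
    "simulate_train",
    "ppr",
    "sample_counts",
]


class FD2ConfigError(ValueError):
    """Raised when an FD2 parameter set violates its invariants."""


@dataclass(frozen=True)
class FD2Params:
    """Constants of the FD2 model.

    Defaults are the published dynamics constants; ``F_base``, ``N_T`` and
    ``P_occ`` are condition-dependent and must be chosen per scenario.

    Parameters
    ----------
    delta_F, delta_D : float
        Increment of the facilitation / recovery calcium sensor per stimulus
        (dimensionless concentration units).
    tau_F, tau_D : float
        Exponential decay time constants of the two sensors, in seconds.
    K_F, K_D : float
        Half-saturation constants (affinities) of the sensors.
    k_0, k_max : float
        Baseline and maximal recovery rate from the refractory state, s^-1.
    F_base : float
        Facilitation probability at zero residual calcium, in [0, 1].
    N_T : int
        Docking sites per active zone (typically 1-10).
    P_occ : float
        Probability that a docking site holds a release-competent vesicle.
    """

    delta_F: float = 5.0
    delta_D: float = 0.001
    tau_F: float = 0.1
    tau_D: float = 0.05
    K_F: float = 2.0
    K_D: float = 2.0
    k_0: float = 0.7
    k_max: float = 20.0
    F_base: float = 0.4
    N_T: int = 7
    P_occ: float = 1.0

    def __post_init__(self) -> None:
        positive = ("tau_F", "tau_D", "K_F", "K_D", "k_0", "k_max")
        for name in positive:
            if not getattr(self, name) > 0:
                raise FD2ConfigError(f"{name} must be strictly positive")
        if self.delta_F < 0 or self.delta_D < 0:
            raise FD2ConfigError("sensor increments delta_F/delta_D must be nonnegative")
        if not 0.0 <= self.F_base <= 1.0:
            raise FD2ConfigError("F_base must lie in [0, 1]")
        if not 0.0 <= self.P_occ <= 1.0:
            raise FD2ConfigError("P_occ must lie in [0, 1]")
        if not (isinstance(self.N_T, (int, np.integer)) and self.N_T >= 1):
            raise FD2ConfigError("N_T must be a positive integer")
        if self.k_max < self.k_0:
            raise FD2ConfigError("k_max must be >= k_0")

    @property
    def rrp(self) -> float:
        """Resting readily-releasable pool, ``N_T * P_occ`` vesicles."""
        return self.N_T * self.P_occ


@dataclass(frozen=True)
class ModelState:
    """Continuous state of one active zone between stimuli."""

    CaX_F: float = 0.0
    CaX_D: float = 0.0
    D: float = 1.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.CaX_F < 0 or self.CaX_D < 0:
            raise ValueError("calcium-sensor concentrations cannot be negative")
        if not 0.0 <= self.D <= 1.0:
            raise ValueError("D must lie in [0, 1]")


@dataclass(frozen=True)
class PulseRecord:
    """Per-stimulus release bookkeeping, evaluated at the pre-pulse state."""

    stim_index: int
    t: float
    F: float
    D: float
    P_succ: float
    RRP: float
    V_released: float


@dataclass(frozen=True)
class ReleaseTrajectory:
    """Outcome of a deterministic FD2 train simulation."""

    stimulus_times: tuple
    pulses: tuple
    params: FD2Params

    def v_released(self) -> np.ndarray:
        return np.array([p.V_released for p in self.pulses])

    def to_frame(self):
        """Trajectory as a pandas DataFrame (one row per stimulus)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "stim_index": [p.stim_index for p in self.pulses],
                "time_s": [p.t for p in self.pulses],
                "F": [p.F for p in self.pulses],
                "D": [p.D for p in self.pulses],
                "P_succ": [p.P_succ for p in self.pulses],
                "V_released": [p.V_released for p in self.pulses],
            }
        )


def init_state(params: FD2Params) -> ModelState:
    """Resting state: no residual calcium, fully recovered pool."""
    if not isinstance(params, FD2Params):
        raise FD2ConfigError("params must be an FD2Params instance")
    return ModelState(CaX_F=0.0, CaX_D=0.0, D=1.0, t=0.0)


def facilitation(CaX_F: float, params: FD2Params) -> float:
    """Facilitation probability at residual calcium ``CaX_F``.

    Saturable form ``F_base + (1 - F_base) * CaX_F / (CaX_F + K_F)``: equals
    ``F_base`` at zero calcium and approaches 1 as the sensor saturates.
    """
    if CaX_F < 0:
        raise ValueError("CaX_F must be nonnegative")
    return params.F_base + (1.0 - params.F_base) * CaX_F / (CaX_F + params.K_F)


def recovery_rate(CaX_D: float, params: FD2Params) -> float:
    """Refractory-recovery rate ``k_0 + (k_max - k_0) * c/(c + K_D)``, s^-1."""
    if CaX_D < 0:
        raise ValueError("CaX_D must be nonnegative")
    return params.k_0 + (params.k_max - params.k_0) * CaX_D / (CaX_D + params.K_D)


def _rate_integral(CaX_D: float, dt: float, params: FD2Params) -> float:
    # exact integral of k(CaX_D * exp(-t/tau_D)) over [0, dt]
    decayed = CaX_D * math.exp(-dt / params.tau_D)
    return params.k_0 * dt + (params.k_max - params.k_0) * params.tau_D * math.log(
        (CaX_D + params.K_D) / (decayed + params.K_D)
    )


def evolve(state: ModelState, dt: float, params: FD2Params) -> ModelState:
    """Advance the state ``dt`` seconds with no stimulus.

    Calcium sensors decay exponentially; ``D`` relaxes toward 1 under the
    time-varying recovery rate (closed-form integral, see module docstring).
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if dt == 0:
        return state
    ca_f = state.CaX_F * math.exp(-dt / params.tau_F)
    ca_d = state.CaX_D * math.exp(-dt / params.tau_D)
    d_new = 1.0 - (1.0 - state.D) * math.exp(-_rate_integral(state.CaX_D, dt, params))
    return ModelState(CaX_F=ca_f, CaX_D=ca_d, D=min(d_new, 1.0), t=state.t + dt)


def fire(state: ModelState, params: FD2Params, stim_index: int = 1):
    """Deliver one stimulus; return ``(post_state, PulseRecord)``.

    Release is evaluated at the pre-pulse state; the released fraction of
    ready sites then becomes refractory (``D <- D * (1 - F)``) and both
    calcium sensors are incremented.
    """
    f = facilitation(state.CaX_F, params)
    p_succ = f * state.D
    record = PulseRecord(
        stim_index=stim_index,
        t=state.t,
        F=f,
        D=state.D,
        P_succ=p_succ,
        RRP=params.rrp,
        V_released=params.rrp * p_succ,
    )
    post = ModelState(
        CaX_F=state.CaX_F + params.delta_F,
        CaX_D=state.CaX_D + params.delta_D,
        D=state.D * (1.0 - f),
        t=state.t,
    )
    return post, record


def simulate_train(stimulus_times: Sequence[float], params: FD2Params) -> ReleaseTrajectory:
    """Simulate a stimulus train from rest.

    Parameters
    ----------
    stimulus_times : sequence of float
        Strictly increasing stimulus times in seconds (first may be 0).
    """
    times = np.asarray(stimulus_times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("at least one stimulus time is required")
    if np.any(np.diff(times) <= 0):
        raise ValueError("stimulus times must be strictly increasing")
    state = init_state(params)
    if times[0] > 0:
        state = evolve(state, float(times[0]), params)
    pulses = []
    for i, t in enumerate(times):
        if i > 0:
            state = evolve(state, float(t - times[i - 1]), params)
        state, rec = fire(state, params, stim_index=i + 1)
        pulses.append(rec)
    return ReleaseTrajectory(tuple(times.tolist()), tuple(pulses), params)


def regular_train(n_stim: int, freq_hz: float, start: float = 0.0) -> np.ndarray:
    """Stimulus times for ``n_stim`` pulses at ``freq_hz``, seconds."""
    if n_stim < 1 or freq_hz <= 0:
        raise ValueError("need n_stim >= 1 and freq_hz > 0")
    return start + np.arange(n_stim) / freq_hz


def ppr(trajectory: ReleaseTrajectory) -> float:
    """Paired-pulse ratio ``V_released[2] / V_released[1]``."""
    if len(trajectory.pulses) < 2:
        raise ValueError("paired-pulse ratio needs at least two pulses")
    v1 = trajectory.pulses[0].V_released
    if v1 == 0:
        raise ZeroDivisionError("first-pulse release is zero; PPR undefined")
    return trajectory.pulses[1].V_released / v1


def sample_counts(
    trajectory: ReleaseTrajectory, params: FD2Params, seed: int | np.random.Generator
) -> np.ndarray:
    """Stochastic released-vesicle counts for each pulse of a trajectory.

    Each pulse draws ``Binomial(N_T, P_occ * F * D)`` — a single-stage draw
    whose mean matches the deterministic ``V_released``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([params.P_occ * rec.P_succ for rec in trajectory.pulses])
    return rng.binomial(params.N_T, p)
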