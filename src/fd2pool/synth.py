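"""Synthetic electrophysiology generators.

Everything downstream (pool estimators, quantal statistics, event
detection) is exercised on data from this module: depletion-model EPSC
trains, noisy per-sweep amplitude tables, Poisson asynchronous quantal
events, and continuous current traces assembled from a unit EPSC kernel.

The kernel is the alpha-like waveform ``(t/tau_E) * exp(1 - t/tau_E)``,
normalised to peak 1 at ``t = tau_E`` (default 1.5 ms, typical of a fast
AMPA-receptor EPSC). Amplitudes are peak scalings of this kernel, in pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuantalParams",
    "DepletionParams",
    "SweepSet",
    "EventList",
    "epsc_kernel",
    "depletion_train_expected",
    "noisy_sweeps",
    "async_events",
    "render_trace",
]


@dataclass(frozen=True)
class QuantalParams:
    """Quantal response parameters.

    q : quantal (single-vesicle) peak amplitude, pA. Default 55 pA, a
        typical asynchronous-EPSC mean at a large cerebellar synapse.
    tau_E : EPSC weighted decay time constant, ms.
    amp_cv : coefficient of variation of the quantal amplitude.
    noise_sd : additive Gaussian baseline noise SD, pA.
    """

    q: float = 55.0
    tau_E: float = 1.5
    amp_cv: float = 0.3
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.q <= 0 or self.tau_E <= 0:
            raise ValueError("q and tau_E must be positive")
        if self.amp_cv < 0 or self.noise_sd < 0:
            raise ValueError("amp_cv and noise_sd must be nonnegative")


@dataclass(frozen=True)
class DepletionParams:
    """Vesicle-depletion train model: pool N0, per-vesicle release
    probability p_r, and R vesicles replenished per interstimulus interval."""

    N0: float = 100.0
    p_r: float = 0.8
    R: float = 0.0
    n_stim: int = 25
    freq: float = 50.0

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if not 0.0 < self.p_r <= 1.0:
            raise ValueError("p_r must lie in (0, 1]")
        if self.R < 0 or self.n_stim < 1 or self.freq <= 0:
            raise ValueError("need R >= 0, n_stim >= 1, freq > 0")


@dataclass
class SweepSet:
    """Tidy per-sweep, per-stimulus EPSC amplitude table.

    ``data`` has columns ``sweep_id, stim_index, amplitude`` with
    ``stim_index`` contiguous from 1. All estimators consume either this
    object or its per-stimulus sweep average.
    """

    data: pd.DataFrame
    freq: float
    units: str = "pA"
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"sweep_id", "stim_index", "amplitude"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"SweepSet table needs columns {sorted(required)}")
        if not np.all(np.isfinite(self.data["amplitude"])):
            raise ValueError("amplitudes must be finite")
        idx = np.sort(self.data["stim_index"].unique())
        if idx[0] != 1 or np.any(np.diff(idx) != 1):
            raise ValueError("stim_index must be contiguous from 1")

    def mean_amplitudes(self) -> np.ndarray:
        """Arithmetic mean amplitude across sweeps, per stimulus."""
        return (
            self.data.groupby("stim_index")["amplitude"].mean().sort_index().to_numpy()
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, freq: float, units: str = "pA") -> "SweepSet":
        return cls(pd.read_csv(path), freq=freq, units=units)


@dataclass
class EventList:
    """Sorted quantal event times (ms) and peak amplitudes within a window."""

    times: np.ndarray
    amplitudes: np.ndarray
    window: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must align")
        if self.times.size and (
            np.any(np.diff(self.times) < 0)
            or self.times.min() < 0
            or self.times.max() > self.window
        ):
            raise ValueError("event times must be sorted and inside the window")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "amplitude": self.amplitudes})


def epsc_kernel(t, tau_E: float = 1.5):
    """Unit EPSC waveform ``(t/tau_E) * exp(1 - t/tau_E)``.

    Zero at ``t = 0``, unique peak of exactly 1 at ``t = tau_E``, decaying
    to zero for large ``t``. ``t`` in ms (scalar or array, nonnegative).
    """
    if tau_E <= 0:
        raise ValueError("tau_E must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = (t / tau_E) * np.exp(1.0 - t / tau_E)
    return float(out) if out.ndim == 0 else out


def depletion_train_expected(d: DepletionParams, q: QuantalParams) -> np.ndarray:
    """Expected EPSC amplitudes ``A_k = q * p_r * N_k`` of a depletion train.

    Pool recursion ``N_{k+1} = N_k*(1 - p_r) + R``. With no replenishment
    the train is geometric; with R > 0 it settles at the steady amplitude
    ``q * R`` (pool fixed point ``R / p_r``).
    """
    amps = np.empty(d.n_stim)
    pool = float(d.N0)
    for k in range(d.n_stim):
        amps[k] = q.q * d.p_r * pool
        pool = max(pool * (1.0 - d.p_r) + d.R, 0.0)
    return amps


def noisy_sweeps(
    d: DepletionParams,
    q: QuantalParams,
    n_sweeps: int,
    seed: int | np.random.Generator,
) -> SweepSet:
    """Stochastic sweep table for the depletion train.

    Per sweep, the integer pool starts at round(N0); each stimulus releases
    ``Binomial(N_k, p_r)`` vesicles, each contributing a lognormal quantal
    amplitude with mean ``q`` and CV ``amp_cv``; Gaussian baseline noise of
    SD ``noise_sd`` is added to every amplitude. Seed-reproducible.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    sigma = np.sqrt(np.log1p(q.amp_cv**2))
    mu = np.log(q.q) - 0.5 * sigma**2
    rows = []
    n0 = int(round(d.N0))
    for sweep in range(n_sweeps):
        pool = n0
        for k in range(1, d.n_stim + 1):
            count = rng.binomial(pool, d.p_r) if pool > 0 else 0
            if q.amp_cv > 0 and count > 0:
                quanta = rng.lognormal(mu, sigma, size=count).sum()
            else:
                quanta = count * q.q
            amp = quanta + rng.normal(0.0, q.noise_sd) if q.noise_sd > 0 else quanta
            rows.append((sweep, k, amp))
            pool = max(pool - count + int(round(d.R)), 0)
    frame = pd.DataFrame(rows, columns=["sweep_id", "stim_index", "amplitude"])
    return SweepSet(frame, freq=d.freq, seed=seed_val)


def async_events(
    rate: float,
    window: float,
    q: QuantalParams,
    seed: int | np.random.Generator,
) -> EventList:
    """Homogeneous Poisson quantal events over ``[0, window]`` ms.

    Event rate in Hz; amplitudes lognormal with mean ``q.q`` and CV
    ``q.amp_cv``. A statistical surrogate for strontium-evoked asynchronous
    EPSC records.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(rate * window / 1000.0)
    times = np.sort(rng.random(n) * window)
    if q.amp_cv > 0:
        sigma = np.sqrt(np.log1p(q.amp_cv**2))
        mu = np.log(q.q) - 0.5 * sigma**2
        amps = rng.lognormal(mu, sigma, size=n)
    else:
        amps = np.full(n, q.q)
    return EventList(times=times, amplitudes=amps, window=window)


def render_trace(
    events: EventList,
    q: QuantalParams,
    duration: float,
    dt: float = 0.02,
    seed: int | np.random.Generator | None = None,
):
    """Continuous current trace from a quantal event list.

    Linear superposition ``sum_i a_i * kernel(t - t_i)`` sampled every
    ``dt`` ms (default 0.02 ms, i.e. 50 kHz), plus Gaussian noise of SD
    ``q.noise_sd`` when a seed is given and ``noise_sd > 0``. Returns
    ``(times_ms, current)`` arrays.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(events) and events.times.max() > duration:
        raise ValueError("events fall outside the rendered window")
    t = np.arange(0.0, duration, dt)
    trace = np.zeros_like(t)
    # kernel support truncated at 20*tau_E (amplitude < 5e-7 of peak there)
    support = int(np.ceil(20.0 * q.tau_E / dt))
    for ti, ai in zip(events.times, events.amplitudes):
        i0 = int(np.ceil(ti / dt))
        if i0 >= t.size:
            continue
        offset = t[i0] - ti
        seg = ai * epsc_kernel(offset + np.arange(min(support, t.size - i0)) * dt, q.tau_E)
        trace[i0 : i0 + seg.size] += seg
    if seed is not None and q.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, q.noise_sd, size=trace.size)
    return t, trace
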