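"""Quantal and population statistics for synaptic recordings.

Covers the supporting analyses around the release model: percent
inhibition by an antagonist, coefficient-of-variation comparisons,
variance–mean (multiple-probability compound binomial) analysis,
potency-based univesicular/multivesicular classification, threshold event
detection on current traces, Kolmogorov–Smirnov distribution comparison,
and four-parameter logistic dose–response fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats as sps
from scipy.optimize import curve_fit

from .synth import EventList, epsc_kernel

__all__ = [
    "SynapseClassification",
    "VarianceMeanFit",
    "EventStats",
    "DoseResponseFit",
    "percent_inhibition",
    "cv_percent_of_control",
    "variance_mean_fit",
    "classify_release_mode",
    "detect_events",
    "event_stats",
    "ks_compare",
    "dose_response_fit",
]

# Potency-ratio bands for release-mode classification: synapses whose
# late/early potency ratio sits in [0.8, 1.2] are univesicular (UVR),
# > 1.3 multivesicular (MVR); the gap (1.2, 1.3] and anything < 0.8 are
# left unclassified.
UVR_BAND = (0.8, 1.2)
MVR_MIN = 1.3


@dataclass(frozen=True)
class SynapseClassification:
    ppr_potency: float
    p_success: float
    mode: str  # "UVR" | "MVR" | "unclassified"
    reason: str | None = None


@dataclass(frozen=True)
class VarianceMeanFit:
    """Parabola fit sigma^2 = q*mu - mu^2/N through the origin."""

    q_est: float
    n_est: float
    coef_linear: float
    coef_quadratic: float
    failure: str | None = None


@dataclass(frozen=True)
class EventStats:
    frequency: float  # Hz
    mean_amplitude: float
    intervals: np.ndarray  # inter-event intervals, ms
    amplitudes: np.ndarray


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    log10_ec50: float
    hill_slope: float
    residual_rms: float
    failure: str | None = None

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log10_ec50


def percent_inhibition(pre_mean: float, post_mean: float) -> float:
    """Percent block of a response: ``100 * (1 - post/pre)``."""
    if pre_mean <= 0:
        raise ValueError("pre_mean must be positive")
    return 100.0 * (1.0 - post_mean / pre_mean)


def cv_percent_of_control(base_amps, treat_amps) -> float:
    """CV of treated sweeps as a percentage of the control CV.

    CV = sd/mean per condition (sample SD). 100% under any uniform scaling
    of the amplitudes — the signature of a purely postsynaptic change —
    whereas a change in release probability moves the CV.
    """
    base = np.asarray(base_amps, dtype=float)
    treat = np.asarray(treat_amps, dtype=float)
    if base.size < 2 or treat.size < 2:
        raise ValueError("need >= 2 sweeps per condition")
    cvs = []
    for arr in (base, treat):
        m = arr.mean()
        if m == 0:
            raise ValueError("zero-mean condition: CV undefined")
        cvs.append(arr.std(ddof=1) / m)
    return 100.0 * cvs[1] / cvs[0]


def variance_mean_fit(condition_stats: Sequence[tuple]) -> VarianceMeanFit:
    """Binomial variance–mean analysis across release-probability conditions.

    For binomial release with N sites of quantal size q, the amplitude
    variance is a parabola in the mean: ``sigma^2 = q*mu - mu^2/N``. A
    least-squares fit through the origin returns ``q_est`` (linear
    coefficient) and ``n_est = -1/quadratic``. Data whose variance exceeds
    the fitted ``q*mu`` envelope or yields nonpositive (q, N) are flagged
    as non-binomial.
    """
    pts = np.asarray(condition_stats, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (mean, variance) conditions")
    mu, var = pts[:, 0], pts[:, 1]
    if np.unique(mu).size < 2:
        raise ValueError("condition means must be distinct")
    design = np.column_stack([mu, mu**2])
    coef, *_ = np.linalg.lstsq(design, var, rcond=None)
    q_est = float(coef[0])
    n_est = float(-1.0 / coef[1]) if coef[1] != 0 else float("inf")
    failure = None
    predicted = design @ coef
    if q_est <= 0 or n_est <= 0:
        failure = "non-binomial variance-mean relation (nonpositive q or N)"
    elif np.any(var > q_est * mu * (1.0 + 1e-9)) or np.any(
        np.abs(var - predicted) > 0.5 * np.maximum(predicted, 1e-300)
    ):
        failure = "supra-binomial or off-parabola variance in at least one condition"
    return VarianceMeanFit(q_est, n_est, float(coef[0]), float(coef[1]), failure)


def classify_release_mode(
    successes: Sequence[Sequence[float]],
    n_trials: int,
    early: tuple = (0, 1),
    late: tuple = (2, 3, 4),
) -> SynapseClassification:
    """Classify a synapse as UVR or MVR from a five-stimulus train protocol.

    ``successes[k]`` holds the amplitudes of successful responses to
    stimulus ``k`` (failures omitted); ``n_trials`` is the number of sweeps.
    Potency is the mean successful amplitude per stimulus; the classifier
    ratio is mean potency of the late stimuli over mean potency of the
    early stimuli (unweighted across stimuli). UVR synapses keep a flat
    potency (ratio 0.8–1.2); MVR synapses grow (> 1.3).
    """
    if len(successes) != 5:
        raise ValueError("protocol expects five stimuli per sweep")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    potencies = [float(np.mean(s)) if len(s) else np.nan for s in successes]
    n_succ = sum(len(s) for s in successes)
    p_success = n_succ / (5 * n_trials)
    early_p = [potencies[i] for i in early if np.isfinite(potencies[i])]
    late_p = [potencies[i] for i in late if np.isfinite(potencies[i])]
    if not early_p or not late_p:
        return SynapseClassification(
            float("nan"), p_success, "unclassified",
            reason="no successes in early or late stimulus group",
        )
    ratio = float(np.mean(late_p) / np.mean(early_p))
    if UVR_BAND[0] <= ratio <= UVR_BAND[1]:
        mode, reason = "UVR", None
    elif ratio > MVR_MIN:
        mode, reason = "MVR", None
    else:
        mode, reason = "unclassified", "potency ratio outside UVR/MVR bands"
    return SynapseClassification(ratio, p_success, mode, reason)


def detect_events(
    trace: np.ndarray,
    dt: float,
    threshold: float,
    refractory: float = 3.0,
    smooth_ms: float = 0.3,
    amp_smooth_ms: float = 0.5,
    baseline_ms: float = 2.0,
    tau_e_ms: float | None = None,
) -> EventList:
    """Threshold event detection on a sampled current trace.

    The trace (inward currents positive) is boxcar-smoothed over
    ``smooth_ms``; local maxima whose height *and* prominence exceed
    ``threshold``, separated by at least ``refractory`` ms, are events
    (the prominence requirement stops noise ripples riding on the decay
    tail of a large event from registering as extra events). Each
    amplitude is measured against the median of the ``baseline_ms`` window
    preceding the event: by default as the peak of an
    ``amp_smooth_ms``-wide second smoothing of the trace, or, when the
    EPSC time constant ``tau_e_ms`` is supplied, as the least-squares
    scale of the unit EPSC waveform over the event (much lower variance
    on noisy traces). ``dt`` is the sample interval in ms.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    trace = np.asarray(trace, dtype=float)

    def boxcar(arr, width_ms):
        width = max(int(round(width_ms / dt)), 1)
        if width <= 1:
            return arr
        return np.convolve(arr, np.ones(width) / width, mode="same")

    smooth = boxcar(trace, smooth_ms)
    distance = max(int(round(refractory / dt)), 1)
    peaks, _ = signal.find_peaks(
        smooth, height=threshold, prominence=threshold, distance=distance
    )
    times = peaks * dt
    amp_trace = boxcar(trace, amp_smooth_ms)
    n_base = max(int(round(baseline_ms / dt)), 1)
    if tau_e_ms is not None:
        template = epsc_kernel(np.arange(int(round(6 * tau_e_ms / dt))) * dt, tau_e_ms)
    amps = np.empty(peaks.size)
    for j, p in enumerate(peaks):
        lo = max(p - 2 * n_base, 0)
        hi = max(p - n_base, lo + 1)
        baseline = np.median(amp_trace[lo:hi]) if hi > lo else 0.0
        if tau_e_ms is not None:
            # align the template by maximizing correlation over small shifts
            nominal = p - int(round(tau_e_ms / dt))
            r = max(int(round(0.4 * tau_e_ms / dt)), 1)
            best, best_score = nominal, -np.inf
            for onset in range(max(nominal - r, 0), nominal + r + 1):
                seg = trace[onset : onset + template.size] - baseline
                score = template[: seg.size] @ seg
                if score > best_score:
                    best, best_score = onset, score
            seg = trace[best : best + template.size] - baseline
            w = template[: seg.size]
            amps[j] = float(w @ seg / (w @ w))
        else:
            amps[j] = amp_trace[p] - baseline
    window = trace.size * dt
    return EventList(times=times, amplitudes=amps, window=window)


def event_stats(events: EventList) -> EventStats:
    """Frequency (Hz), mean amplitude and raw distributions of an event list."""
    freq = len(events) / (events.window / 1000.0) if events.window > 0 else 0.0
    mean_amp = float(events.amplitudes.mean()) if len(events) else float("nan")
    return EventStats(
        frequency=freq,
        mean_amplitude=mean_amp,
        intervals=np.diff(events.times),
        amplitudes=events.amplitudes.copy(),
    )


def ks_compare(sample_a, sample_b):
    """Two-sample Kolmogorov–Smirnov comparison; returns ``(D, p)``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp" if min(a.size, b.size) > 100 else "auto")
    return float(res.statistic), float(res.pvalue)


def dose_response_fit(x, y) -> DoseResponseFit:
    """Four-parameter logistic fit on a log10 concentration axis.

    ``y = bottom + (top - bottom) / (1 + 10^(slope*(log10(EC50) - log10(x))))``.
    Used e.g. for percent inhibition versus extracellular calcium, where
    the fitted floor is the calcium-insensitive component.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or x.size != y.size:
        raise ValueError("need >= 4 matched (x, y) points")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.allclose(y, y[0]):
        return DoseResponseFit(
            float(y[0]), float(y[0]), float("nan"), float("nan"), 0.0,
            failure="flat response: midpoint unidentifiable",
        )
    lx = np.log10(x)

    def model(logc, bottom, top, logec50, slope):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logec50 - logc)))

    try:
        popt, _ = curve_fit(
            model, lx, y,
            p0=[y.min(), y.max(), float(np.median(lx)), 1.0],
            maxfev=20000,
        )
    except RuntimeError as exc:
        return DoseResponseFit(*([float("nan")] * 5), failure=str(exc))
    resid = y - model(lx, *popt)
    bottom, top, logec50, slope = popt
    if bottom > top:  # (bottom, top, slope) <-> (top, bottom, -slope) are one curve
        bottom, top, slope = top, bottom, -slope
    return DoseResponseFit(
        float(bottom), float(top), float(logec50), float(slope),
        float(np.sqrt(np.mean(resid**2))),
    )
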