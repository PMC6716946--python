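"""Readily-releasable-pool (RRP) and release-probability (Pr) estimators.

Two train-based pool estimates with different replenishment assumptions:

* ``cumulative_train_estimate`` — plot the cumulative EPSC amplitude versus
  stimulus number, fit a line to the final (steady-state) points and take
  its y-intercept as the pool (assumes constant replenishment throughout
  the train).
* ``eq_estimate`` — the Elmqvist–Quastel construction: plot each amplitude
  against the cumulative amplitude released *before* it and take the
  x-intercept of the line through the first points (assumes replenishment
  negligible early in the train).

Both return the pool in the amplitude units supplied (the product of
vesicle count and quantal size) and define ``Pr`` as the first amplitude
divided by the pool. Also here: the depletion-model Pr from paired-pulse
depression, and single-exponential fits for train decay and recovery from
depression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PoolEstimate",
    "RecoveryFit",
    "TrainDecayFit",
    "EstimationError",
    "cumulative_train_estimate",
    "eq_estimate",
    "pr_from_ppd",
    "fit_recovery",
    "fit_train_decay",
]


class EstimationError(ValueError):
    """Raised when an estimator cannot produce a meaningful value."""


@dataclass(frozen=True)
class PoolEstimate:
    """Pool-size estimate with the fit diagnostics that produced it.

    ``rrp`` carries the units of the input amplitudes; ``pr`` is the first
    amplitude divided by ``rrp``. ``failure`` is None for a valid fit, else
    a short reason (the estimate fields may then be NaN).
    """

    rrp: float
    pr: float
    method: str
    fit_slope: float
    fit_intercept: float
    n_points_used: int
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.failure is None


@dataclass(frozen=True)
class RecoveryFit:
    """Recovery-from-depression fit ``r(dt) = 1 - (1 - floor) * exp(-dt/tau)``."""

    tau: float
    floor: float
    residual_rms: float
    failure: str | None = None


@dataclass(frozen=True)
class TrainDecayFit:
    """Train-amplitude decay fit ``A(t) = plateau + (initial - plateau)*exp(-t/tau)``."""

    tau: float
    plateau: float
    initial: float
    residual_rms: float
    failure: str | None = None


def _as_amplitudes(amplitudes) -> np.ndarray:
    a = np.asarray(amplitudes, dtype=float)
    if a.ndim != 1:
        raise ValueError("amplitudes must be one-dimensional")
    if np.any(~np.isfinite(a)) or np.any(a < 0):
        raise ValueError("amplitudes must be finite and nonnegative")
    return a


def cumulative_train_estimate(amplitudes, n_last: int = 5) -> PoolEstimate:
    """Pool estimate from the y-intercept of the cumulative-amplitude plot.

    An ordinary least-squares line is fit to the last ``n_last`` cumulative
    points against stimulus number (1-based); its y-intercept estimates the
    pool and ``pr = amplitudes[0] / rrp``. The fitted slope estimates the
    steady replenishment per stimulus.
    """
    a = _as_amplitudes(amplitudes)
    if n_last < 2:
        raise ValueError("n_last must be >= 2")
    if a.size <= n_last:
        raise ValueError("need more stimuli than n_last")
    cum = np.cumsum(a)
    x = np.arange(1, a.size + 1, dtype=float)[-n_last:]
    y = cum[-n_last:]
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        return PoolEstimate(
            rrp=float("nan"), pr=float("nan"), method="train",
            fit_slope=float(slope), fit_intercept=float(intercept),
            n_points_used=n_last,
            failure="nonpositive y-intercept (replenishment-dominated train)",
        )
    return PoolEstimate(
        rrp=float(intercept), pr=float(a[0] / intercept), method="train",
        fit_slope=float(slope), fit_intercept=float(intercept),
        n_points_used=n_last,
    )


def eq_estimate(amplitudes, n_first: int = 2) -> PoolEstimate:
    """Elmqvist–Quastel pool estimate from amplitude vs prior cumulative release.

    For stimulus ``k`` the point is ``(C_{k-1}, A_k)`` with ``C_0 = 0``; a
    line through the first ``n_first`` points is extrapolated to its
    x-intercept, the pool. Exact when depression is pure depletion: then
    ``A_k = p_r * (pool - C_{k-1})`` is linear with x-intercept ``pool`` and
    slope ``-p_r``.
    """
    a = _as_amplitudes(amplitudes)
    if n_first < 2:
        raise ValueError("n_first must be >= 2")
    if a.size < n_first:
        raise ValueError(f"need at least {n_first} amplitudes")
    prior_cum = np.concatenate([[0.0], np.cumsum(a)[:-1]])
    x = prior_cum[:n_first]
    y = a[:n_first]
    if y[1] >= y[0]:
        return PoolEstimate(
            rrp=float("nan"), pr=float("nan"), method="eq",
            fit_slope=float("nan"), fit_intercept=float("nan"),
            n_points_used=n_first, failure="non-depressing train",
        )
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0 or not np.isfinite(slope):
        return PoolEstimate(
            rrp=float("nan"), pr=float("nan"), method="eq",
            fit_slope=float(slope), fit_intercept=float(intercept),
            n_points_used=n_first, failure="degenerate slope",
        )
    rrp = -intercept / slope
    return PoolEstimate(
        rrp=float(rrp), pr=float(a[0] / rrp), method="eq",
        fit_slope=float(slope), fit_intercept=float(intercept),
        n_points_used=n_first,
    )


def pr_from_ppd(ppr: float, recovered_fraction: float = 0.0) -> float:
    """Depletion-model release probability from paired-pulse depression.

    At a short interval the second response reports the pool left by the
    first plus any recovery: ``A2/A1 = 1 - Pr*(1 - r)``, so
    ``Pr = (1 - PPR) / (1 - r)``, clamped to [0, 1]. ``r`` defaults to 0
    (no recovery), appropriate for intervals of ~10 ms.
    """
    if not 0.0 <= recovered_fraction < 1.0:
        raise ValueError("recovered_fraction must lie in [0, 1)")
    if ppr < 0:
        raise ValueError("ppr must be nonnegative")
    if ppr > 1:
        raise EstimationError(
            "paired-pulse facilitation (PPR > 1): depletion model not applicable"
        )
    return float(np.clip((1.0 - ppr) / (1.0 - recovered_fraction), 0.0, 1.0))


def fit_recovery(intervals, ratios) -> RecoveryFit:
    """Fit recovery from depression: ``r(dt) = 1 - (1 - floor)*exp(-dt/tau)``.

    ``intervals`` are positive increasing waiting times; ``ratios`` the
    recovered amplitude fractions at each. Units of ``tau`` follow the
    intervals.
    """
    t = np.asarray(intervals, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.size < 3 or t.size != r.size:
        raise ValueError("need >= 3 matched (interval, ratio) points")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("intervals must be positive and increasing")
    if np.allclose(r, r[0]):
        return RecoveryFit(float("nan"), float("nan"), 0.0, failure="flat recovery curve")

    def model(dt, tau, floor):
        return 1.0 - (1.0 - floor) * np.exp(-dt / tau)

    try:
        popt, _ = curve_fit(
            model, t, r, p0=[np.median(t), max(min(r.min(), 0.9), 0.0)],
            bounds=([1e-9, 0.0], [np.inf, 1.0]), maxfev=10000,
        )
    except RuntimeError as exc:
        return RecoveryFit(float("nan"), float("nan"), float("nan"), failure=str(exc))
    resid = r - model(t, *popt)
    return RecoveryFit(float(popt[0]), float(popt[1]), float(np.sqrt(np.mean(resid**2))))


def fit_train_decay(amplitudes, freq: float) -> TrainDecayFit:
    """Single-exponential fit of train depression versus time.

    ``A(t_k) = plateau + (initial - plateau)*exp(-t_k/tau)`` with
    ``t_k = (k-1)/freq``; ``tau`` returned in ms. For a pure depletion
    train with per-stimulus survival ``(1-p_r)`` the decay constant is
    ``dt / (-ln(1-p_r))``.
    """
    a = _as_amplitudes(amplitudes)
    if a.size < 5:
        raise ValueError("need >= 5 stimuli to fit a train decay")
    if freq <= 0:
        raise ValueError("freq must be positive")
    t_ms = np.arange(a.size) / freq * 1000.0
    if np.allclose(a, a[0]):
        return TrainDecayFit(
            float("nan"), float(a[0]), float(a[0]), 0.0,
            failure="constant train: decay constant unidentifiable",
        )

    def model(t, tau, plateau, initial):
        return plateau + (initial - plateau) * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model, t_ms, a,
            p0=[t_ms[1] if t_ms.size > 1 else 1.0, a[-1], a[0]],
            bounds=([1e-9, 0.0, 0.0], [np.inf, np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        return TrainDecayFit(float("nan"), float("nan"), float("nan"), float("nan"), failure=str(exc))
    resid = a - model(t_ms, *popt)
    return TrainDecayFit(
        float(popt[0]), float(popt[1]), float(popt[2]),
        float(np.sqrt(np.mean(resid**2))),
    )
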