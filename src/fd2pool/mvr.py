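"""Analytic geometry of multivesicular release probability.

When neither the site-occupancy probability ``x = P_occ`` nor the
vesicle-success probability ``y = P_succ`` is known, treat both as uniform
on the unit square. The number of vesicles released by an active zone with
``v`` docking sites is ``V = v * x * y`` (a hyperbolic paraboloid over the
square), and the probability that more than ``z`` vesicles are released is
the area fraction of the region ``v*x*y > z``:

    P(V > z) = 1 + (z/v) * (ln(z/v) - 1),   0 < z/v <= 1,

with the continuity limits ``P = 1`` at ``z = 0`` and ``P = 0`` for
``z >= v``. A Monte-Carlo estimator over the same square serves as a
brute-force cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExceedanceQuery",
    "prob_exceeding",
    "mc_exceedance",
    "released_surface",
    "exceedance_vs_sites",
]


@dataclass(frozen=True)
class ExceedanceQuery:
    """Threshold ``z`` (vesicles) against ``v`` docking sites."""

    z: float
    v: float

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("site count v must be positive")
        if self.z < 0:
            raise ValueError("threshold z must be nonnegative")

    @property
    def ratio(self) -> float:
        return self.z / self.v


def prob_exceeding(q: ExceedanceQuery | None = None, *, z: float | None = None, v: float | None = None) -> float:
    """Probability that a ``v``-site active zone releases more than ``z`` vesicles.

    Closed form under uniform (P_occ, P_succ); accepts either an
    :class:`ExceedanceQuery` or keyword ``z=,... v=``.
    """
    if q is None:
        q = ExceedanceQuery(z=float(z), v=float(v))
    r = q.ratio
    if r == 0:
        return 1.0
    if r >= 1:
        return 0.0
    return 1.0 + r * (np.log(r) - 1.0)


def mc_exceedance(z: float, v: float, reps: int, seed: int | np.random.Generator):
    """Monte-Carlo estimate of ``P(v*x*y > z)`` with x, y ~ U(0,1).

    Returns ``(estimate, standard_error)``; the standard error is the
    binomial ``sqrt(p*(1-p)/reps)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if v <= 0 or z < 0:
        raise ValueError("need v > 0 and z >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.random(reps)
    y = rng.random(reps)
    p = float(np.mean(v * x * y > z))
    se = float(np.sqrt(p * (1.0 - p) / reps))
    return p, se


def released_surface(N_T: int, grid_resolution: int = 51) -> pd.DataFrame:
    """Mean released vesicles ``V = N_T * P_occ * P_succ`` over the unit square.

    Returns a long-format frame with columns ``p_occ, p_succ, V``; the
    surface is bilinear (a hyperbolic paraboloid), so any cross-section at
    fixed occupancy or success probability is a straight line.
    """
    if N_T < 1 or grid_resolution < 2:
        raise ValueError("need N_T >= 1 and grid_resolution >= 2")
    axis = np.linspace(0.0, 1.0, grid_resolution)
    occ, succ = np.meshgrid(axis, axis, indexing="ij")
    return pd.DataFrame(
        {
            "p_occ": occ.ravel(),
            "p_succ": succ.ravel(),
            "V": (N_T * occ * succ).ravel(),
        }
    )


def exceedance_vs_sites(z: float, v_range) -> pd.DataFrame:
    """Tabulate ``prob_exceeding`` across site counts for one threshold.

    Columns ``v, z, probability``; probability grows logarithmically with
    the number of sites and is 0 wherever ``v <= z``.
    """
    v_range = np.asarray(v_range, dtype=float)
    if np.any(v_range <= 0):
        raise ValueError("site counts must be positive")
    probs = [prob_exceeding(ExceedanceQuery(z=z, v=float(v))) for v in v_range]
    return pd.DataFrame({"v": v_range, "z": z, "probability": probs})
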