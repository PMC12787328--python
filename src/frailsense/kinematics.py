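"""UWB trajectory kinematics.

Turns raw indoor-positioning streams into the mobility measures used
for frailty scoring: per-step Euclidean distances, cumulative distance
traveled, a per-participant ordinary-least-squares fit of distance on
elapsed time (which absorbs positioning noise and the zigzag wander of
unsteady gait), the implied 15-ft walk time, and zone-occupancy task
durations.

All distances are metric. Planar (x, y) distance is the default since
walks happen on a single floor; 3-D distance is available via ``mode``.
Only elapsed time (t - t0) enters any formula, so absolute clock
offsets are irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidFitError
from .models import FIFTEEN_FEET_M, Trajectory, ZoneMap


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of cumulative distance (m) on elapsed time (s).

    ``b`` is the slope — the participant's effective path speed — and
    ``c`` the intercept. A fit is usable for walk-time estimation only
    if ``b > 0``.
    """

    b: float
    c: float
    r_squared: float
    n: int

    @property
    def valid(self) -> bool:
        return self.b > 0


@dataclass(frozen=True)
class TaskDuration:
    """One contiguous stay inside a named zone."""

    zone: str
    entry_s: float
    exit_s: float

    @property
    def duration_s(self) -> float:
        return self.exit_s - self.entry_s


def step_distances(trajectory: Trajectory, mode: str = "planar") -> np.ndarray:
    """Euclidean distance between consecutive samples.

    Parameters
    ----------
    mode:
        ``"planar"`` uses (x, y) only; ``"3d"`` includes z.
    """
    if len(trajectory) < 2:
        raise InsufficientDataError("need >= 2 samples for step distances")
    if mode not in ("planar", "3d"):
        raise ValueError(f"unknown mode {mode!r}")
    dx = np.diff(trajectory.x)
    dy = np.diff(trajectory.y)
    sq = dx * dx + dy * dy
    if mode == "3d":
        dz = np.diff(trajectory.z)
        sq = sq + dz * dz
    return np.sqrt(sq)


def cumulative_distance(trajectory: Trajectory, mode: str = "planar") -> np.ndarray:
    """Cumulative path length at each sample, starting at 0."""
    steps = step_distances(trajectory, mode=mode)
    out = np.empty(len(trajectory))
    out[0] = 0.0
    np.cumsum(steps, out=out[1:])
    return out


def displacement_from_start(trajectory: Trajectory, mode: str = "planar") -> np.ndarray:
    """Euclidean distance of each sample from the first sample."""
    if len(trajectory) < 2:
        raise InsufficientDataError("need >= 2 samples for displacements")
    dx = trajectory.x - trajectory.x[0]
    dy = trajectory.y - trajectory.y[0]
    sq = dx * dx + dy * dy
    if mode == "3d":
        dz = trajectory.z - trajectory.z[0]
        sq = sq + dz * dz
    elif mode != "planar":
        raise ValueError(f"unknown mode {mode!r}")
    return np.sqrt(sq)


def fit_distance_time(
    trajectory: Trajectory, mode: str = "planar", distance: str = "displacement"
) -> RegressionFit:
    """OLS of distance on elapsed time (d = b*t + c).

    ``distance`` selects the dependent variable: ``"displacement"``
    (default) regresses distance from the start point, which is robust
    to per-sample positioning noise (zero-mean errors leave the slope
    unbiased); ``"cumulative"`` regresses summed step distances, which
    is exact for noiseless data but inflates the slope when white
    positional noise dominates the per-step motion.

    Requires >= 3 samples and a positive elapsed-time span. The fit
    is returned even when the slope is non-positive; callers that need
    a walk time must check :attr:`RegressionFit.valid`.
    """
    if len(trajectory) < 3:
        raise InsufficientDataError("need >= 3 samples for a distance-time fit")
    t = trajectory.t - trajectory.t[0]
    if t[-1] <= 0:
        raise InvalidFitError("degenerate time span")
    if distance == "displacement":
        d = displacement_from_start(trajectory, mode=mode)
    elif distance == "cumulative":
        d = cumulative_distance(trajectory, mode=mode)
    else:
        raise ValueError(f"unknown distance kind {distance!r}")
    res = stats.linregress(t, d)
    r2 = float(res.rvalue) ** 2
    return RegressionFit(b=float(res.slope), c=float(res.intercept),
                         r_squared=min(r2, 1.0), n=len(trajectory))


def estimate_walk_time(fit: RegressionFit, distance: float = FIFTEEN_FEET_M) -> float:
    """Time (s) to cover ``distance`` implied by the fitted line.

    Solves d = b*t + c for t at the target distance: t = (d - c) / b.
    Raises :class:`InvalidFitError` for non-positive slope or a
    non-positive implied time (intercept at or beyond the target
    distance — no walk detected).
    """
    if not fit.valid:
        raise InvalidFitError(f"non-positive slope b={fit.b}")
    t = (distance - fit.c) / fit.b
    if t <= 0:
        raise InvalidFitError(
            f"implied walk time {t:.3g} s <= 0 (intercept {fit.c:.3g} m "
            f">= target distance {distance} m)"
        )
    return t


def zone_durations(
    trajectory: Trajectory, zonemap: ZoneMap, min_dwell: float = 2.0
) -> list[TaskDuration]:
    """Contiguous in-zone stays, with short blips suppressed.

    A stay is the span from the first to the last sample of a maximal
    run of consecutive samples inside one zone; runs shorter than
    ``min_dwell`` seconds are discarded (hysteresis against boundary
    chatter). Zones are evaluated independently, so overlapping zones
    each record their own stays.
    """
    if len(zonemap) == 0:
        raise InsufficientDataError("zone map is empty")
    out: list[TaskDuration] = []
    t = trajectory.t
    for zone in zonemap:
        inside = zone.contains(trajectory.x, trajectory.y)
        if not inside.any():
            continue
        # boundaries of runs of True
        padded = np.concatenate([[False], inside, [False]])
        diff = np.diff(padded.astype(int))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1) - 1
        for s, e in zip(starts, ends):
            dur = t[e] - t[s]
            if dur >= min_dwell:
                out.append(TaskDuration(zone=zone.name, entry_s=float(t[s]),
                                        exit_s=float(t[e])))
    out.sort(key=lambda td: td.entry_s)
    return out


def zone_total_durations(
    trajectory: Trajectory, zonemap: ZoneMap, min_dwell: float = 2.0
) -> dict[str, float]:
    """Total dwell time per zone (s), summed over stays."""
    totals = {z.name: 0.0 for z in zonemap}
    for td in zone_durations(trajectory, zonemap, min_dwell=min_dwell):
        totals[td.zone] += td.duration_s
    return totals
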