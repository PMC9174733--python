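"""Cleaning, filtering and smoothing of raw positional streams, plus the
static-sensor validation statistics (CEP and DIST).

The canonical processing order is: exclusion windows -> out-of-pen filter ->
moving-average smoothing; smoothed data feed directly into the behaviour
metrics. The two filters commute (both are pure row deletions), which is
property-tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import PenGeometry
from .synthetic import StaticTestData
from .trajectory import SECONDS_PER_DAY, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionWindow",
    "remove_out_of_pen",
    "apply_exclusion_windows",
    "moving_average_smooth",
    "compute_cep",
    "compute_dist_accuracy",
    "segment_into_units",
    "TrajectoryUnit",
]


@dataclass(frozen=True)
class ExclusionWindow:
    """Time window whose samples are discarded (e.g. human proximity,
    power cut). ``start``/``end`` are epoch seconds; inclusive bounds."""

    start: float
    end: float
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("exclusion window requires start < end")


def remove_out_of_pen(traj: Trajectory, pen: PenGeometry) -> Trajectory:
    """Drop fixes outside the pen boundary (boundary-inclusive keep)."""
    inside = pen.contains_points(traj.x, traj.y)
    n_removed = int((~inside).sum())
    out = traj.subset(inside)
    out.meta["n_out_of_pen_removed"] = n_removed
    if len(out) == 0 and len(traj) > 0:
        warnings.warn(f"all {len(traj)} fixes of {traj.individual_id!r} "
                      "fall outside the pen", stacklevel=2)
    if n_removed:
        logger.debug("%s: removed %d out-of-pen fixes", traj.individual_id, n_removed)
    return out


def apply_exclusion_windows(traj: Trajectory,
                            windows: list[ExclusionWindow]) -> Trajectory:
    """Drop fixes whose timestamp falls in any window (union semantics)."""
    if not windows:
        out = traj.subset(np.ones(len(traj), dtype=bool))
        out.meta["exclusion_removed_fraction"] = 0.0
        return out
    excluded = np.zeros(len(traj), dtype=bool)
    for w in windows:
        excluded |= (traj.t >= w.start) & (traj.t <= w.end)
    out = traj.subset(~excluded)
    out.meta["exclusion_removed_fraction"] = (
        float(excluded.mean()) if len(traj) else 0.0)
    return out


def moving_average_smooth(traj: Trajectory, window_s: float = 10.0) -> Trajectory:
    """Centred moving-average smoothing over a time window.

    Each coordinate is replaced by the mean of all samples within
    ``window_s / 2`` seconds on either side; timestamps are unchanged.
    Windows are truncated at the stream edges and never bridge gaps longer
    than ``window_s`` (the stream is split into contiguous segments first,
    so a power cut cannot be averaged across).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = len(traj)
    if n <= 1:
        return traj.subset(np.ones(n, dtype=bool))

    x_s = np.empty(n)
    y_s = np.empty(n)
    gaps = np.flatnonzero(np.diff(traj.t) > window_s)
    starts = np.concatenate([[0], gaps + 1])
    stops = np.concatenate([gaps + 1, [n]])
    half = window_s / 2.0
    for a, b in zip(starts, stops):
        t = traj.t[a:b]
        cx = np.concatenate([[0.0], np.cumsum(traj.x[a:b])])
        cy = np.concatenate([[0.0], np.cumsum(traj.y[a:b])])
        lo = np.searchsorted(t, t - half, side="left")
        hi = np.searchsorted(t, t + half, side="right")
        cnt = hi - lo
        x_s[a:b] = (cx[hi] - cx[lo]) / cnt
        y_s[a:b] = (cy[hi] - cy[lo]) / cnt
    out = Trajectory(traj.individual_id, traj.t.copy(), x_s, y_s,
                     traj.nominal_hz, dict(traj.meta))
    out.meta["smoothed_window_s"] = window_s
    return out


def _per_position_cep(fixes: np.ndarray) -> float:
    centre = fixes.mean(axis=0)
    d = np.hypot(*(fixes - centre).T)
    return float(np.percentile(d, 50))  # linear-interpolation median


def compute_cep(data: StaticTestData) -> dict:
    """Circular error probability per static position.

    CEP is the radius of the circle, centred at the mean fix, containing
    50% of the fixes — the median distance to the mean, with the
    linear-interpolation percentile convention.
    """
    for f in data.fixes:
        if len(f) < 2:
            raise ValueError("CEP requires at least 2 fixes per position")
    per_pos = {pid: _per_position_cep(f)
               for pid, f in zip(data.position_ids, data.fixes)}
    vals = np.array(list(per_pos.values()))
    return {"per_position": per_pos, "mean": float(vals.mean()),
            "range": (float(vals.min()), float(vals.max()))}


def compute_dist_accuracy(data: StaticTestData,
                          truth: np.ndarray | None = None) -> dict:
    """Mean Euclidean distance between fixes and the ground-truth position
    (the accuracy measure complementing CEP's precision)."""
    truth = data.truth if truth is None else np.asarray(truth, float)
    if truth.shape[0] != len(data.fixes):
        raise ValueError("ground-truth rows must match the number of positions")
    per_pos = {}
    for pid, f, p in zip(data.position_ids, data.fixes, truth):
        per_pos[pid] = float(np.hypot(*(f - p).T).mean())
    vals = np.array(list(per_pos.values()))
    return {"per_position": per_pos, "mean": float(vals.mean()),
            "range": (float(vals.min()), float(vals.max()))}


@dataclass
class TrajectoryUnit:
    """One observational time unit: consecutive calendar days of one
    individual's stream, with per-day sub-streams retained for the daily
    utilization distributions behind site fidelity."""

    individual_id: str
    unit_index: int
    days: list[Trajectory]          # one (possibly empty) sub-stream per day
    coverage_fraction: float        # observed samples / expected at nominal_hz

    @property
    def pooled(self) -> Trajectory:
        parts = [d for d in self.days if len(d)]
        if not parts:
            return Trajectory(self.individual_id, np.array([]), np.array([]),
                              np.array([]), self.days[0].nominal_hz
                              if self.days else 1.0)
        return Trajectory(self.individual_id,
                          np.concatenate([d.t for d in parts]),
                          np.concatenate([d.x for d in parts]),
                          np.concatenate([d.y for d in parts]),
                          parts[0].nominal_hz)


def segment_into_units(traj: Trajectory, unit_days: int = 4,
                       drop_first_day: bool = False) -> list[TrajectoryUnit]:
    """Split a stream into consecutive ``unit_days``-day observational units.

    Days are calendar days (local-midnight boundaries). The first calendar
    day can be dropped (habituation to the new pen); a trailing partial
    unit is discarded. Per-day sub-streams are retained.
    """
    if unit_days < 1:
        raise ValueError("unit_days must be >= 1")
    if len(traj) == 0:
        return []
    day_idx = traj.day_index()
    first, last = day_idx.min(), day_idx.max()
    if drop_first_day:
        first += 1
    span = last - first + 1
    n_units = span // unit_days
    units: list[TrajectoryUnit] = []
    for u in range(n_units):
        day0 = first + u * unit_days
        days = []
        n_samples = 0
        for d in range(day0, day0 + unit_days):
            sub = traj.subset(day_idx == d)
            days.append(sub)
            n_samples += len(sub)
        expected = unit_days * SECONDS_PER_DAY * traj.nominal_hz
        units.append(TrajectoryUnit(traj.individual_id, u, days,
                                    coverage_fraction=n_samples / expected))
    return units
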