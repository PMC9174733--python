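"""Movement and space-use behaviours per individual per observational unit.

Five behaviours are computed over four-day observational time units:

* total distance travelled (m),
* core area (m^2): area of the smallest region holding 50% of the
  utilization distribution (UD),
* total area (m^2): same at 95%,
* site fidelity: similarity of the individual's daily UDs within a unit,
  derived from the mean pairwise Hellinger distance,
* time in the feeder area (min).

The UD is a gridded kernel density over the pen: fixes are binned onto a
regular grid (default 0.1 m cells) and convolved with a Gaussian kernel,
then truncated to the pen plus a small buffer and renormalized to unit
mass. Isopleth areas count whole cells, taking cells in decreasing density
order until the requested cumulative mass is reached.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter

from .geometry import PenGeometry
from .preprocess import TrajectoryUnit, segment_into_units
from .trajectory import SECONDS_PER_DAY, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "UtilizationDistribution",
    "total_distance",
    "estimate_ud",
    "area_at_isopleth",
    "hellinger_distance",
    "site_fidelity",
    "feeder_time",
    "MetricsConfig",
    "build_behaviour_table",
    "BEHAVIOURS",
]

BEHAVIOURS = ("distance_m", "core_area_m2", "total_area_m2",
              "site_fidelity", "feeder_time_min")


@dataclass
class UtilizationDistribution:
    """Gridded space-use probability mass.

    ``mass[i, j]`` is the probability mass of the cell whose lower-left
    corner is ``grid_origin + (i, j) * cell_size`` (x index first).
    """

    grid_origin: tuple[float, float]
    cell_size: float
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass < 0):
            raise ValueError("UD mass must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("UD mass must sum to 1 within 1e-9")

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def same_grid(self, other: "UtilizationDistribution") -> bool:
        return (np.allclose(self.grid_origin, other.grid_origin)
                and np.isclose(self.cell_size, other.cell_size)
                and self.mass.shape == other.mass.shape)


def total_distance(traj: Trajectory, gap_threshold_s: float = 10.0) -> float:
    """Sum of Euclidean step lengths; steps spanning gaps longer than
    ``gap_threshold_s`` are excluded (no teleporting across power cuts)."""
    if len(traj) < 2:
        logger.warning("total_distance: fewer than 2 samples for %s",
                       traj.individual_id)
        return 0.0
    dt = np.diff(traj.t)
    step = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return float(step[dt <= gap_threshold_s].sum())


def reference_bandwidth(xy: np.ndarray) -> float:
    """Ad-hoc bivariate-normal reference bandwidth ("href"):
    0.5 * (sd_x + sd_y) * n^(-1/6)."""
    n = len(xy)
    sd = xy.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    return float(0.5 * sd.sum() * n ** (-1 / 6))


def estimate_ud(points: np.ndarray, pen: PenGeometry,
                cell_size: float = 0.1,
                bandwidth_rule: str | float = "href",
                buffer_m: float = 0.5,
                min_points: int = 10) -> UtilizationDistribution:
    """Kernel utilization distribution on a regular grid over the pen.

    ``bandwidth_rule`` is either the string ``"href"`` (reference rule) or
    an explicit bandwidth in metres. The grid covers the pen bounds plus
    ``buffer_m``; after smoothing, mass outside the buffered pen is removed
    and the rest renormalized to 1.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < min_points:
        raise ValueError(f"UD estimation needs at least {min_points} points, "
                         f"got {len(points)}")
    if bandwidth_rule == "href":
        h = reference_bandwidth(points)
    else:
        h = float(bandwidth_rule)
    if h < 0:
        raise ValueError("bandwidth must be non-negative")

    xmin, ymin, xmax, ymax = pen.bounds()
    x0, y0 = xmin - buffer_m, ymin - buffer_m
    nx = int(np.ceil((xmax - xmin + 2 * buffer_m) / cell_size))
    ny = int(np.ceil((ymax - ymin + 2 * buffer_m) / cell_size))
    hist, _, _ = np.histogram2d(
        points[:, 0], points[:, 1], bins=[nx, ny],
        range=[[x0, x0 + nx * cell_size], [y0, y0 + ny * cell_size]])
    if h > 0:
        hist = gaussian_filter(hist, sigma=h / cell_size, mode="constant")
    # truncate to the buffered pen and renormalize
    cx = x0 + (np.arange(nx) + 0.5) * cell_size
    cy = y0 + (np.arange(ny) + 0.5) * cell_size
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    inside = shapely.intersects_xy(pen.boundary.buffer(buffer_m),
                                   gx.ravel(), gy.ravel()).reshape(nx, ny)
    hist = np.where(inside, hist, 0.0)
    total = hist.sum()
    if total <= 0:
        raise ValueError("all UD mass fell outside the buffered pen")
    mass = hist / total
    mass = mass / mass.sum()  # exact renormalization against rounding
    return UtilizationDistribution((x0, y0), cell_size, mass)


def area_at_isopleth(ud: UtilizationDistribution, level: float) -> float:
    """Area (m^2) of the smallest set of whole cells holding ``level`` of
    the UD mass: cells are taken in decreasing density order until the
    cumulative mass first reaches the level."""
    if not 0 < level < 1:
        raise ValueError("isopleth level must be in (0, 1)")
    flat = np.sort(ud.mass.ravel())[::-1]
    csum = np.cumsum(flat)
    n_cells = int(np.searchsorted(csum, level - 1e-12) + 1)
    return n_cells * ud.cell_area


def hellinger_distance(ud1: UtilizationDistribution,
                       ud2: UtilizationDistribution) -> float:
    """H = sqrt(1 - sum_cells sqrt(p*q)); 0 for identical UDs, 1 for
    disjoint supports; symmetric."""
    if not ud1.same_grid(ud2):
        raise ValueError("Hellinger distance requires UDs on the same grid")
    bc = np.sqrt(ud1.mass * ud2.mass).sum()
    return float(np.sqrt(max(0.0, 1.0 - bc)))


def site_fidelity(daily_uds: list[UtilizationDistribution],
                  orientation: str = "similarity") -> float:
    """Mean pairwise Hellinger distance over all day pairs of a unit.

    With ``orientation="similarity"`` (default) returns 1 - mean(H) so that
    larger values mean stronger fidelity to the same places; with
    ``orientation="distance"`` returns the raw mean Hellinger distance.
    """
    if orientation not in ("similarity", "distance"):
        raise ValueError("orientation must be 'similarity' or 'distance'")
    if len(daily_uds) < 2:
        raise ValueError("site fidelity needs at least 2 daily UDs")
    hs = [hellinger_distance(a, b)
          for a, b in itertools.combinations(daily_uds, 2)]
    mean_h = float(np.mean(hs))
    return 1.0 - mean_h if orientation == "similarity" else mean_h


def feeder_time(traj: Trajectory, pen: PenGeometry,
                hz: float | None = None) -> float:
    """Minutes spent inside the feeder zone: in-zone sample count divided
    by the sampling frequency (at 1 Hz, one point is one second).
    Boundary points count as inside."""
    if len(traj) == 0:
        return 0.0
    hz = traj.nominal_hz if hz is None else hz
    inside = pen.in_feeder(traj.x, traj.y)
    return float(inside.sum() / hz / 60.0)


# ---------------------------------------------------------------------------
# behaviour table assembly
# ---------------------------------------------------------------------------

@dataclass
class MetricsConfig:
    unit_days: int = 4
    drop_first_day: bool = True
    cell_size: float = 0.1
    bandwidth_rule: str | float = "href"
    buffer_m: float = 0.5
    min_points: int = 10
    gap_threshold_s: float = 10.0
    core_level: float = 0.5
    total_level: float = 0.95
    fidelity_orientation: str = "similarity"
    unit_coverage_min: float = 0.5
    daily_coverage_min: float = 0.5


def _unit_day_numbers(unit: TrajectoryUnit) -> list[int]:
    return [int(d.t.min() // SECONDS_PER_DAY) for d in unit.days if len(d)]


def _weaning_stage(unit_days: list[int], step_down_day, weaned_day) -> str:
    # stage holding on the majority of the unit's days; ties -> later stage
    counts = {"not_weaning": 0, "step_down": 0, "weaned": 0}
    for d in unit_days:
        if weaned_day is not None and not np.isnan(weaned_day) and d >= weaned_day:
            counts["weaned"] += 1
        elif (step_down_day is not None and not np.isnan(step_down_day)
              and d >= step_down_day):
            counts["step_down"] += 1
        else:
            counts["not_weaning"] += 1
    order = ["weaned", "step_down", "not_weaning"]  # later stages win ties
    return max(order, key=lambda s: (counts[s], -order.index(s)))


def _health_status(unit_days: list[int], treatment_days: list[int]) -> str:
    days = set(unit_days)
    for tr in treatment_days:
        if days & {tr - 2, tr - 1, tr}:
            return "sick"
    for tr in treatment_days:
        if days & {tr + 1, tr + 2, tr + 3}:
            return "convalescent"
    return "healthy"


def _parse_treatments(value) -> list[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    if isinstance(value, str):
        return [int(float(v)) for v in value.split(";") if v.strip()]
    if np.isscalar(value):
        return [int(value)]
    return [int(v) for v in value]


def unit_behaviours(unit: TrajectoryUnit, pen: PenGeometry,
                    cfg: MetricsConfig) -> dict:
    """The five behaviours for one individual-unit."""
    pooled = unit.pooled
    rec: dict = {
        "individual_id": unit.individual_id,
        "unit_index": unit.unit_index,
        "coverage_fraction": unit.coverage_fraction,
        "distance_m": total_distance(pooled, cfg.gap_threshold_s),
        "feeder_time_min": feeder_time(pooled, pen),
    }
    try:
        ud = estimate_ud(pooled.xy, pen, cfg.cell_size, cfg.bandwidth_rule,
                         cfg.buffer_m, cfg.min_points)
        rec["core_area_m2"] = area_at_isopleth(ud, cfg.core_level)
        rec["total_area_m2"] = area_at_isopleth(ud, cfg.total_level)
    except ValueError:
        rec["core_area_m2"] = np.nan
        rec["total_area_m2"] = np.nan

    expected_day = SECONDS_PER_DAY * (unit.days[0].nominal_hz if unit.days else 1.0)
    daily_uds = []
    for day in unit.days:
        if len(day) / expected_day >= cfg.daily_coverage_min and len(day) >= cfg.min_points:
            daily_uds.append(estimate_ud(day.xy, pen, cfg.cell_size,
                                         cfg.bandwidth_rule, cfg.buffer_m,
                                         cfg.min_points))
    if len(daily_uds) >= 2:
        rec["site_fidelity"] = site_fidelity(daily_uds, cfg.fidelity_orientation)
    else:
        rec["site_fidelity"] = np.nan
        logger.info("site fidelity skipped for %s unit %d: %d eligible days",
                    unit.individual_id, unit.unit_index, len(daily_uds))
    return rec


def build_behaviour_table(trajectories: list[Trajectory],
                          covariates: pd.DataFrame,
                          pen: PenGeometry,
                          temperature: pd.DataFrame | None = None,
                          cfg: MetricsConfig | None = None) -> pd.DataFrame:
    """Assemble the per-individual per-unit behaviour table.

    ``covariates`` has one row per individual: individual_id, cohort, sex,
    breed, birth_day (calendar-day number), and optionally step_down_day,
    weaned_day and treatment_days (semicolon-separated day numbers).
    ``temperature`` maps calendar day -> temperature_C. Rows with missing
    covariates are dropped (logged); units below the coverage threshold are
    flagged, not dropped.
    """
    cfg = cfg or MetricsConfig()
    cov = covariates.set_index("individual_id")
    temp_by_day = (temperature.set_index("day")["temperature_C"]
                   if temperature is not None else None)
    rows = []
    for traj in trajectories:
        if traj.individual_id not in cov.index:
            logger.warning("dropping %s: no covariate row", traj.individual_id)
            continue
        ci = cov.loc[traj.individual_id]
        units = segment_into_units(traj, cfg.unit_days, cfg.drop_first_day)
        for unit in units:
            rec = unit_behaviours(unit, pen, cfg)
            days = _unit_day_numbers(unit)
            if not days:
                continue
            rec["cohort"] = ci.get("cohort")
            rec["sex"] = ci.get("sex")
            rec["breed"] = ci.get("breed")
            birth = ci.get("birth_day", np.nan)
            rec["age_days"] = (max(days) - birth + 1
                               if not pd.isna(birth) else np.nan)
            if temp_by_day is not None:
                temps = [temp_by_day.get(d, np.nan) for d in days]
                rec["mean_temperature_C"] = float(np.nanmean(temps)) if temps else np.nan
            else:
                rec["mean_temperature_C"] = np.nan
            rec["weaning_stage"] = _weaning_stage(
                days, ci.get("step_down_day", np.nan), ci.get("weaned_day", np.nan))
            rec["health_status"] = _health_status(
                days, _parse_treatments(ci.get("treatment_days")))
            rec["low_coverage"] = unit.coverage_fraction < cfg.unit_coverage_min
            rows.append(rec)
    table = pd.DataFrame(rows)
    if len(table):
        front = ["individual_id", "unit_index", *BEHAVIOURS]
        table = table[front + [c for c in table.columns if c not in front]]
    return table
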