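"""Virtual-pasture study generator.

Emulates a warm-season household-pasture survey end to end so every
downstream stage (KDE intensity estimation, dung counting, calibration)
can be exercised without field data:

* a rectangular pasture of configurable area with a campsite concentrator
  and an optional riverbed strip;
* herd movement drawn hourly from a distance-decay field around the
  campsite, p(x) proportional to exp(-dist(x, campsite) / lambda), with
  positional persistence between hours and a pull toward the campsite at
  the start and end of the grazing day (night penning);
* dung deposition as a Poisson process per yak-hour at yak positions;
* exponential dung decay, accelerated inside the riverbed (washout);
* an observation model with flight-height-dependent detection
  probability, optional false positives, and GPS drift of the footprint.

All randomness flows through named substreams of the run seed, so the
movement, deposition, decay and detection stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from pydantic import BaseModel, ConfigDict, Field, model_validator
from shapely.geometry import Point, Polygon, box

from ._rng import substream
from .geometry import (Footprint, PastureGeometry, apply_exclusion_zones,
                       footprint_at, riverbed_image_filter,
                       waypoint_exclusion_reasons)
from .kde import (GridSpec, GrazingIntensityRaster, HerdSnapshot,
                  MonitoringPlan, TriangularKernel, month_label,
                  monthly_intensity)
from .profiles import CAMERA_PROFILES

#: Calendar lengths of the warm-season months (May..October).
DEFAULT_DAYS_IN_MONTH = {5: 31, 6: 30, 7: 31, 8: 31, 9: 30, 10: 31}


class SimConfig(BaseModel):
    """Full parameterisation of the virtual study.

    Defaults reproduce the study conditions: 278 yaks on a 113.64 ha
    pasture, May-October, 4-8 randomly monitored days per month with
    12-14 hourly snapshots per day, a 300 m movement/kernel scale, and
    detection probabilities 1.0 at 2 m and 0.9316 at 20 m flight height.
    Deposition and decay rates are free parameters of the simulator (the
    field study measures neither); defaults are one pat per yak-hour and
    a slow decay of 0.2 per month, tripled inside the riverbed.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    herd_size: int = Field(default=278, ge=0)
    pasture_area_ha: float = Field(default=113.64, gt=0)
    campsite_offset_frac: tuple[float, float] = (-0.18, -0.12)
    months: list[int] = Field(default_factory=lambda: [5, 6, 7, 8, 9, 10])
    days_in_month: dict[int, int] = Field(
        default_factory=lambda: dict(DEFAULT_DAYS_IN_MONTH))
    monitored_days_range: tuple[int, int] = (4, 8)
    snapshots_per_day_range: tuple[int, int] = (12, 14)
    grazing_hours_per_day: float = Field(default=13.0, gt=0)
    day_start_hour: int = 7

    movement_decay_length_m: float = 300.0   # lambda of the distance-decay field
    movement_persistence: float = Field(default=0.5, ge=0, le=1)  # rho
    campsite_pull: float = Field(default=0.6, ge=0, le=1)
    # Night-pen rotation: pens sit on a circle around the campsite and the
    # active pen (the field's concentrator) rotates monthly.
    night_pens: int = Field(default=4, ge=1)
    pen_radius_m: float = Field(default=150.0, ge=0)
    # Seasonal contraction of the movement range: in the peak growing
    # season yaks meet their intake needs within a smaller radius.
    lambda_month_multiplier: dict[int, float] = Field(
        default_factory=lambda: {7: 0.7, 8: 0.7, 9: 0.85})

    deposition_rate: float = Field(default=1.0, ge=0)   # pats per yak-hour
    dung_jitter_m: float = Field(default=0.5, ge=0)
    decay_rate: float = Field(default=0.2, ge=0)        # per month
    riverbed_enabled: bool = True
    riverbed_width_m: float = Field(default=100.0, ge=0)
    riverbed_offset_frac: float = Field(default=0.75, ge=0, le=1)
    riverbed_decay_multiplier: float = Field(default=3.0, ge=0)
    standing_crop: bool = True   # count all survivors since season start

    detection_prob_by_height: dict[float, float] = Field(
        default_factory=lambda: {2.0: 1.0, 20.0: 0.9316})
    false_positive_rate: float = Field(default=0.0, ge=0)  # per footprint
    gps_drift_max_m: float = Field(default=2.0, ge=0)

    fence_buffer_m: float = Field(default=50.0, ge=0)
    campsite_buffer_m: float = Field(default=150.0, ge=0)
    waypoint_grid: tuple[int, int] = (8, 8)
    waypoint_flight_height_m: float = 20.0
    camera_profile: str = "phantom3"
    riverbed_image_threshold: float = Field(default=0.5, gt=0, le=1)

    study_cell_size_m: float = Field(default=10.0, gt=0)
    kernel_bandwidth_m: float = Field(default=300.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for p in self.detection_prob_by_height.values():
            if not 0 <= p <= 1:
                raise ValueError("detection probabilities must lie in [0, 1]")
        lo, hi = self.monitored_days_range
        if not 1 <= lo <= hi:
            raise ValueError("monitored_days_range must satisfy 1 <= lo <= hi")
        lo, hi = self.snapshots_per_day_range
        if not 1 <= lo <= hi:
            raise ValueError("snapshots_per_day_range must satisfy 1 <= lo <= hi")
        missing = set(self.months) - set(self.days_in_month)
        if missing:
            raise ValueError(f"months without a day count: {sorted(missing)}")
        return self


@dataclass(frozen=True)
class DungPat:
    """A single simulated dung deposit."""

    id: int
    x_m: float
    y_m: float
    deposition_time: tuple[int, int, int]   # (month, day, hour)
    survived_until: float                   # month time, inf if censored
    in_riverbed: bool


@dataclass(frozen=True)
class DungCountSample:
    """Dung counted inside one image footprint at one waypoint and month."""

    waypoint_id: int
    month: int
    flight_height_m: float
    true_count: int
    observed_count: int
    footprint_area_m2: float
    detected_count: int = 0      # true pats detected (excludes false positives)


#: Columns of the bulk dung-pat table used by the pipeline.
PAT_COLUMNS = ["x_m", "y_m", "month", "day", "hour", "t_dep",
               "in_riverbed", "checked_until"]


def _empty_pats() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in PAT_COLUMNS})


def simulate_pasture(config: SimConfig) -> PastureGeometry:
    """Rectangular pasture of the configured area with campsite and riverbed."""
    side = float(np.sqrt(config.pasture_area_ha * 1e4))
    if 2 * config.fence_buffer_m >= side:
        raise ValueError("fence buffer exceeds the pasture span")
    boundary = box(0.0, 0.0, side, side)
    ox, oy = config.campsite_offset_frac
    campsite = Point(side / 2 + ox * side, side / 2 + oy * side)
    riverbed: Polygon | None = None
    if config.riverbed_enabled and config.riverbed_width_m > 0:
        x0 = config.riverbed_offset_frac * side
        riverbed = box(x0, 0.0, min(x0 + config.riverbed_width_m, side), side)
    return PastureGeometry(boundary=boundary, campsite=campsite,
                           riverbed=riverbed,
                           fence_buffer_m=config.fence_buffer_m,
                           campsite_buffer_m=config.campsite_buffer_m)


def active_pen(config: SimConfig, pasture: PastureGeometry,
               month: int) -> np.ndarray:
    """Centre of the night pen in use for a given month.

    Pens sit evenly on a circle of ``pen_radius_m`` around the campsite
    and rotate monthly, shifting the concentrator of the grazing gradient
    from month to month (clipped to the pasture interior).
    """
    cx, cy = pasture.campsite.x, pasture.campsite.y
    if config.pen_radius_m == 0 or config.night_pens == 1:
        return np.array([cx, cy])
    angle = 2 * np.pi * (month % config.night_pens) / config.night_pens
    p = np.array([cx + config.pen_radius_m * np.cos(angle),
                  cy + config.pen_radius_m * np.sin(angle)])
    xmin, ymin, xmax, ymax = pasture.boundary.bounds
    return np.clip(p, [xmin, ymin], [xmax, ymax])


def _draw_positions(rng: np.random.Generator, n: int, pasture: PastureGeometry,
                    decay_length_m: float,
                    center: np.ndarray | None = None) -> np.ndarray:
    """Rejection-sample n points from p(x) ~ exp(-dist(x, center)/lambda)."""
    if n == 0:
        return np.empty((0, 2))
    xmin, ymin, xmax, ymax = pasture.boundary.bounds
    if center is None:
        cx, cy = pasture.campsite.x, pasture.campsite.y
    else:
        cx, cy = center
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 256)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        accept = rng.random(m) < np.exp(-np.hypot(xs - cx, ys - cy) / decay_length_m)
        if accept.any():
            xs, ys = xs[accept], ys[accept]
            inside = shapely.contains_xy(pasture.boundary, xs, ys)
            xs, ys = xs[inside], ys[inside]
            take = min(len(xs), n - got)
            out[got:got + take, 0] = xs[:take]
            out[got:got + take, 1] = ys[:take]
            got += take
    return out


def simulate_day(config: SimConfig, pasture: PastureGeometry, month: int,
                 day: int, rng: np.random.Generator) -> list[HerdSnapshot]:
    """Hourly herd snapshots for one grazing day.

    The concentrator of the distance-decay field is the month's active
    night pen; the decay length carries the month's seasonal multiplier
    (range contraction in the peak growing season).  Each hour blends the
    previous positions with a fresh draw from the field (persistence rho);
    recorded positions are additionally pulled toward the pen near the
    start and end of the day, reflecting release from and return to it.
    """
    if config.movement_decay_length_m <= 0:
        raise ValueError("movement decay length must be > 0")
    lo, hi = config.snapshots_per_day_range
    n_snaps = int(rng.integers(lo, hi + 1))
    pen = active_pen(config, pasture, month)
    lam = (config.movement_decay_length_m
           * config.lambda_month_multiplier.get(month, 1.0))
    rho = config.movement_persistence

    snapshots = []
    state = _draw_positions(rng, config.herd_size, pasture, lam, pen)
    for i in range(n_snaps):
        if i > 0:
            proposal = _draw_positions(rng, config.herd_size, pasture, lam, pen)
            state = rho * state + (1 - rho) * proposal
        # Day-edge pull: strongest at the first/last hour, zero at midday.
        pull = config.campsite_pull * (1.0 - np.sin(np.pi * (i + 0.5) / n_snaps))
        recorded = state + pull * (pen - state)
        snapshots.append(HerdSnapshot(month=month, day=day,
                                      hour=config.day_start_hour + i,
                                      positions=recorded))
    return snapshots


def deposit_dung(snapshots: list[HerdSnapshot], config: SimConfig,
                 pasture: PastureGeometry | None = None,
                 rng: np.random.Generator | None = None,
                 hours_per_snapshot: float = 1.0) -> pd.DataFrame:
    """Poisson dung deposition at yak positions.

    Each snapshot stands for ``hours_per_snapshot`` yak-hours per yak; pat
    counts per yak are Poisson(deposition_rate * hours_per_snapshot) and
    pats land at the yak position plus a small Gaussian jitter, clipped to
    the pasture.
    """
    rng = rng or np.random.default_rng()
    frames = []
    for snap in snapshots:
        n = snap.herd_size
        if n == 0 or config.deposition_rate == 0:
            continue
        counts = rng.poisson(config.deposition_rate * hours_per_snapshot, n)
        total = int(counts.sum())
        if total == 0:
            continue
        pos = np.repeat(snap.positions, counts, axis=0)
        pos = pos + rng.normal(0.0, config.dung_jitter_m, size=pos.shape)
        if pasture is not None:
            xmin, ymin, xmax, ymax = pasture.boundary.bounds
            pos[:, 0] = np.clip(pos[:, 0], xmin, xmax)
            pos[:, 1] = np.clip(pos[:, 1], ymin, ymax)
        days = config.days_in_month.get(snap.month, 30)
        t_dep = snap.month + (snap.day - 1 + snap.hour / 24.0) / days
        in_rb = np.zeros(total, dtype=bool)
        if pasture is not None and pasture.riverbed is not None:
            in_rb = shapely.contains_xy(pasture.riverbed, pos[:, 0], pos[:, 1])
        frames.append(pd.DataFrame({
            "x_m": pos[:, 0], "y_m": pos[:, 1],
            "month": float(snap.month), "day": float(snap.day),
            "hour": float(snap.hour),
            "t_dep": t_dep, "in_riverbed": in_rb.astype(float),
            "checked_until": t_dep}))
    if not frames:
        return _empty_pats()
    out = pd.concat(frames, ignore_index=True)
    return out


def decompose(pats: pd.DataFrame, current_month: int, config: SimConfig,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Advance decay to the end of ``current_month``; return the survivors.

    Each pat survives the elapsed interval dt (months) with probability
    exp(-delta_eff * dt), where delta_eff is the decay rate, multiplied by
    the riverbed factor for pats lying in the riverbed (washout).  The
    survival clock resumes from each pat's last check, so repeated monthly
    calls compound correctly.
    """
    rng = rng or np.random.default_rng()
    if len(pats) == 0:
        return pats.copy()
    t_end = current_month + 1.0
    dt = np.clip(t_end - pats["checked_until"].to_numpy(), 0.0, None)
    delta = np.where(pats["in_riverbed"].to_numpy() > 0,
                     config.decay_rate * config.riverbed_decay_multiplier,
                     config.decay_rate)
    p_survive = np.exp(-delta * dt)
    keep = rng.random(len(pats)) < p_survive
    out = pats.loc[keep].copy()
    out["checked_until"] = np.maximum(out["checked_until"].to_numpy(), t_end)
    return out.reset_index(drop=True)


def observe_dung(pats: pd.DataFrame, footprint: Footprint,
                 flight_height_m: float, config: SimConfig,
                 rng: np.random.Generator | None = None,
                 waypoint_id: int = 0, month: int = 0) -> DungCountSample:
    """Count dung in one (GPS-drifted) image footprint with imperfect detection.

    The footprint centre is displaced by a uniform draw in a disc of
    radius ``gps_drift_max_m``; surviving pats inside the drifted
    rectangle are the true count, each detected with the height's
    configured probability; Poisson false positives are added.  Heights
    without a configured probability are an error (no interpolation).
    """
    rng = rng or np.random.default_rng()
    try:
        p = config.detection_prob_by_height[float(flight_height_m)]
    except KeyError:
        raise ValueError(
            f"no detection probability configured for height {flight_height_m} m")
    cx, cy = footprint.center_xy
    if config.gps_drift_max_m > 0:
        r = config.gps_drift_max_m * np.sqrt(rng.random())
        theta = rng.uniform(0, 2 * np.pi)
        cx, cy = cx + r * np.cos(theta), cy + r * np.sin(theta)
    hw, hl = footprint.width_m / 2, footprint.length_m / 2
    if len(pats):
        xs = pats["x_m"].to_numpy()
        ys = pats["y_m"].to_numpy()
        inside = (np.abs(xs - cx) <= hw) & (np.abs(ys - cy) <= hl)
        true_count = int(inside.sum())
    else:
        true_count = 0
    detected = int(rng.binomial(true_count, p)) if true_count else 0
    false_pos = int(rng.poisson(config.false_positive_rate)) \
        if config.false_positive_rate > 0 else 0
    return DungCountSample(
        waypoint_id=waypoint_id, month=month,
        flight_height_m=float(flight_height_m), true_count=true_count,
        observed_count=detected + false_pos,
        footprint_area_m2=footprint.area_m2, detected_count=detected)


@dataclass
class StudyDataset:
    """Everything a virtual survey produces, plus the recovery target.

    ``monthly_truth`` holds the binned ground-truth occupancy surface of
    ALL simulated hours (yak-hours per m^2), not just monitored days; the
    estimator's output is in ``monthly_estimate``.
    """

    config: SimConfig
    pasture: PastureGeometry
    grid: GridSpec
    waypoints: pd.DataFrame
    plans: dict[int, MonitoringPlan]
    snapshots: dict[int, list[HerdSnapshot]]
    monthly_estimate: dict[int, GrazingIntensityRaster]
    monthly_truth: dict[int, GrazingIntensityRaster]
    counts: pd.DataFrame
    pats: pd.DataFrame
    log: list = field(default_factory=list)

    def cumulative(self, surfaces: dict[int, GrazingIntensityRaster],
                   first: int, last: int) -> GrazingIntensityRaster:
        from .kde import cumulative_intensity
        months = [m for m in sorted(surfaces) if first <= m <= last]
        return cumulative_intensity([surfaces[m] for m in months])

    def cumulative_estimate(self, first: int, last: int) -> GrazingIntensityRaster:
        return self.cumulative(self.monthly_estimate, first, last)

    def cumulative_truth(self, first: int, last: int) -> GrazingIntensityRaster:
        return self.cumulative(self.monthly_truth, first, last)

    def footprint_for(self, waypoint_id: int) -> Footprint:
        row = self.waypoints.loc[self.waypoints.waypoint_id == waypoint_id].iloc[0]
        return Footprint(center_xy=(row.x_m, row.y_m),
                         width_m=row.width_m, length_m=row.length_m)

    def save(self, outdir) -> list[str]:
        from .io import save_study_dataset
        return save_study_dataset(self, outdir)


def _place_waypoints(config: SimConfig, pasture: PastureGeometry) -> pd.DataFrame:
    """Regular waypoint grid over the pasture with exclusion bookkeeping."""
    camera = CAMERA_PROFILES[config.camera_profile]
    xmin, ymin, xmax, ymax = pasture.boundary.bounds
    ncols, nrows = config.waypoint_grid
    dx, dy = (xmax - xmin) / ncols, (ymax - ymin) / nrows
    pts = [(xmin + (i + 0.5) * dx, ymin + (j + 0.5) * dy)
           for j in range(nrows) for i in range(ncols)]
    retained, _ = apply_exclusion_zones(pasture, pts)
    retained_set = set(retained)
    reasons = waypoint_exclusion_reasons(pasture, pts)
    rows = []
    for wid, ((x, y), reason) in enumerate(zip(pts, reasons)):
        fp = footprint_at(camera, config.waypoint_flight_height_m, (x, y))
        excluded = (x, y) not in retained_set
        if not excluded and pasture.riverbed is not None:
            if riverbed_image_filter(fp, pasture.riverbed,
                                     config.riverbed_image_threshold) == "exclude":
                excluded, reason = True, "riverbed"
        rows.append({"waypoint_id": wid, "route_kind": "Rectangle",
                     "x_m": x, "y_m": y,
                     "height_m": config.waypoint_flight_height_m,
                     "width_m": fp.width_m, "length_m": fp.length_m,
                     "excluded_flag": excluded, "exclusion_reason": reason})
    return pd.DataFrame(rows)


def run_virtual_study(config: SimConfig) -> StudyDataset:
    """Run the full virtual survey: movement, deposition, decay, observation.

    Deterministic given ``config.seed``.  Every simulated day contributes
    to dung deposition and to the ground-truth occupancy surface; only the
    randomly monitored days feed the KDE estimator, mirroring the field
    design.
    """
    rng_move = substream(config.seed, "movement")
    rng_plan = substream(config.seed, "monitoring-plan")
    rng_dep = substream(config.seed, "deposition")
    rng_decay = substream(config.seed, "decay")
    rng_detect = substream(config.seed, "detection")

    pasture = simulate_pasture(config)
    grid = GridSpec.from_polygon(pasture.boundary, config.study_cell_size_m)
    kernel = TriangularKernel(config.kernel_bandwidth_m)
    waypoints = _place_waypoints(config, pasture)
    active = waypoints[~waypoints.excluded_flag]

    pats = _empty_pats()
    plans: dict[int, MonitoringPlan] = {}
    monitored: dict[int, list[HerdSnapshot]] = {}
    est: dict[int, GrazingIntensityRaster] = {}
    truth: dict[int, GrazingIntensityRaster] = {}
    count_rows = []
    log: list[dict] = [{"event": "start", "seed": config.seed,
                        "waypoints_active": int(len(active))}]

    x_edges = grid.x0 + np.arange(grid.n_cols + 1) * grid.cell_size_m
    y_edges = grid.y0 + np.arange(grid.n_rows + 1) * grid.cell_size_m

    for month in config.months:
        dim = config.days_in_month[month]
        lo, hi = config.monitored_days_range
        n_mon = int(rng_plan.integers(lo, hi + 1))
        mon_days = sorted(rng_plan.choice(np.arange(1, dim + 1), size=n_mon,
                                          replace=False).tolist())
        snaps_per_day: dict[int, int] = {}
        month_snaps: list[HerdSnapshot] = []
        occupancy = np.zeros((grid.n_rows, grid.n_cols))
        month_pats = []

        for day in range(1, dim + 1):
            day_snaps = simulate_day(config, pasture, month, day, rng_move)
            w = config.grazing_hours_per_day / len(day_snaps)
            for s in day_snaps:
                if s.herd_size:
                    hist, _, _ = np.histogram2d(s.positions[:, 1],
                                                s.positions[:, 0],
                                                bins=[y_edges, x_edges])
                    occupancy += w * hist
            month_pats.append(deposit_dung(day_snaps, config, pasture,
                                           rng_dep, hours_per_snapshot=w))
            if day in mon_days:
                month_snaps.extend(day_snaps)
                snaps_per_day[day] = len(day_snaps)

        plan = MonitoringPlan(month=month, days_in_month=dim,
                              monitored_days=mon_days,
                              snapshots_per_day=snaps_per_day,
                              grazing_hours_per_day=config.grazing_hours_per_day)
        plans[month] = plan
        monitored[month] = month_snaps
        est[month] = monthly_intensity(month_snaps, plan, grid, kernel,
                                       method="binned")
        truth[month] = GrazingIntensityRaster(
            grid=grid, values=occupancy / grid.cell_area_m2,
            period=month_label(month),
            metadata={"kind": "truth-occupancy",
                      "cell_size_m": grid.cell_size_m})

        pats = pd.concat([pats, *month_pats], ignore_index=True)
        pats = decompose(pats, month, config, rng_decay)
        survey_pats = pats if config.standing_crop \
            else pats[pats.month == month]
        for row in active.itertuples():
            fp = Footprint(center_xy=(row.x_m, row.y_m),
                           width_m=row.width_m, length_m=row.length_m)
            sample = observe_dung(survey_pats, fp, row.height_m, config,
                                  rng_detect, waypoint_id=row.waypoint_id,
                                  month=month)
            count_rows.append(sample)
        log.append({"event": "month", "month": month,
                    "monitored_days": mon_days,
                    "pats_standing": int(len(pats))})

    counts = pd.DataFrame([vars(s) for s in count_rows])
    return StudyDataset(config=config, pasture=pasture, grid=grid,
                        waypoints=waypoints, plans=plans, snapshots=monitored,
                        monthly_estimate=est, monthly_truth=truth,
                        counts=counts, pats=pats, log=log)
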