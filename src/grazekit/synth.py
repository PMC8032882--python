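"""Synthetic paddock / herd generator.

Emulates the statistical structure the analysis pipeline assumes, for a
replicated continuous-grazing trial on 1-ha paddocks under three
grazing intensities (M = moderate, L = lenient, VL = very lenient):

* a patchy sward: a spatially correlated Gaussian herbage field on a
  1-m lattice, scaled to treatment-specific mean and SD of herbage on
  offer and floored at 0;
* a diurnally scheduled cow: a two-state (grazing / resting)
  biased random walk toward preferred short-sward feeding stations,
  with morning and evening activity peaks, emitting GPS fixes as true
  position plus isotropic Gaussian noise;
* a head-tilt stream: 64-s intervals whose head-up proportion is low
  while grazing and high otherwise, separated cleanly enough that the
  half-interval classification rule recovers the planted state;
* plate-meter sampling: 50 CSH points per paddock and date, plus 6-8
  destructive calibration cuts generated from a known linear
  CSH -> herbage relationship with configurable residual noise.

Every generated bundle carries a ground-truth manifest (true daily
distances, per-hour moving/stationary step counts, planted grazing
intervals, planted peak hours, true calibration coefficients) for
parameter-recovery testing.

The movement model is deliberately simple: the downstream inferences
need realistic distance budgets, diurnal structure and spatial
clustering, not a validated foraging model.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .io_model import (
    DEFAULT_TZ,
    DeploymentMeta,
    HerdRoster,
    PaddockSpec,
    Trajectory,
    period_duration,
    write_activity,
    write_calibration,
    write_csh,
    write_fixes,
)

__all__ = [
    "TreatmentPreset",
    "TREATMENT_PRESETS",
    "ScheduleEntry",
    "DEFAULT_SCHEDULE",
    "DEFAULT_PEAK_HOURS",
    "SimConfig",
    "SwardField",
    "GroundTruth",
    "ScenarioBundle",
    "sigma_from_mean_radial",
    "generate_sward_field",
    "sample_plate_meter",
    "simulate_cow",
    "simulate_stationary_collar",
    "scenario_suite",
    "write_bundle",
]


def sigma_from_mean_radial(mean_radial_m: float) -> float:
    """Per-axis Gaussian SD from a mean radial deviation (Rayleigh mean):
    mean = sigma * sqrt(pi/2). Collar accuracy is usually quoted as the
    mean radial deviation (0.6-1.9 m for the collars emulated here)."""
    return mean_radial_m / np.sqrt(np.pi / 2.0)


@dataclass(frozen=True)
class TreatmentPreset:
    """Per-treatment generator targets.

    Herbage means/SDs (g DM m-2) and stocking densities (LU ha-1) follow
    the published spring-period estimates for the three grazing
    intensities; station counts encode that moderate grazing keeps many
    dispersed short-sward feeding stations while very lenient grazing
    concentrates use on a few; the step scale reproduces the observed
    daily-distance ranking (M highest)."""

    mean_ho: float  # g DM m-2
    sd_ho: float  # g DM m-2
    n_stations: int
    station_spread: float  # fraction of the paddock side stations scatter over
    step_scale: float
    lu_per_ha: float


TREATMENT_PRESETS: dict[str, TreatmentPreset] = {
    "M": TreatmentPreset(235.0, 81.3, n_stations=14, station_spread=1.0, step_scale=1.1, lu_per_ha=5.3),
    "L": TreatmentPreset(319.0, 108.8, n_stations=8, station_spread=0.7, step_scale=0.95, lu_per_ha=3.8),
    "VL": TreatmentPreset(355.0, 119.2, n_stations=5, station_spread=0.5, step_scale=1.0, lu_per_ha=2.6),
}

DEFAULT_PEAK_HOURS: tuple[int, ...] = (5, 6, 7, 19, 20, 21)


@dataclass(frozen=True)
class ScheduleEntry:
    """One diurnal behaviour block (local hours)."""

    hours: tuple[int, ...]
    state: str
    p_move: float  # probability of a step per fix interval
    step_mean_m: float  # mean commute step length at the reference interval
    grazing_prob: float  # probability a 64-s interval is grazing
    pool: str = "stations"  # movement targets: 'stations' or 'rest'
    p_switch: float = 0.04  # probability per fix of moving on to a new target


# Morning/evening grazing peaks, daytime grazing/loafing, night rest.
# Step means are commute lengths; once at a station the cow takes
# LOCAL_STEP_FACTOR of them (a grazing bout around the station).
DEFAULT_SCHEDULE: tuple[ScheduleEntry, ...] = (
    ScheduleEntry(DEFAULT_PEAK_HOURS, "peak-grazing", 0.45, 26.0, 0.90, "stations", 0.08),
    ScheduleEntry(tuple(range(8, 19)), "day-grazing", 0.30, 22.0, 0.45, "stations", 0.04),
    ScheduleEntry((22, 23, 0, 1, 2, 3, 4), "night-rest", 0.05, 8.0, 0.05, "rest", 0.01),
)

LOCAL_STEP_FACTOR = 0.45  # grazing-bout steps relative to commute steps
LOCAL_RADIUS_M = 15.0  # 'at the station' distance


@dataclass
class SimConfig:
    """Full parameterization of one simulated collar deployment."""

    treatment: str = "L"
    paddock: PaddockSpec = field(
        default_factory=lambda: PaddockSpec(
            "L1", "1", "L", 600_000.0, 5_710_000.0, 600_100.0, 5_710_100.0
        )
    )
    fix_interval: float = 128.0  # s
    start_date: dt.date = dt.date(2017, 5, 18)
    end_date: dt.date = dt.date(2017, 6, 14)
    schedule: tuple[ScheduleEntry, ...] = DEFAULT_SCHEDULE
    step_reference_interval: float = 128.0  # step means refer to this interval
    step_cv: float = 0.5  # gamma step-length CV; 0 = fixed lengths
    gps_sigma_axis: float = sigma_from_mean_radial(1.0)  # ~0.8 m per axis
    mean_ho: float = 319.0  # g DM m-2
    sd_ho: float = 108.8  # g DM m-2
    patch_correlation_length: float = 10.0  # m
    calib_intercept: float = 50.0  # g DM m-2
    calib_slope: float = 25.0  # g DM m-2 cm-1
    calib_residual_sd: float = 70.0  # g DM m-2
    n_csh_points: int = 50
    n_cuts: int = 7
    n_stations: int = 8
    station_spread: float = 0.7  # fraction of the paddock side
    n_rest_sites: int = 2
    local_step_factor: float = LOCAL_STEP_FACTOR  # bout steps vs commute steps
    local_radius_m: float = LOCAL_RADIUS_M  # 'at the station' distance
    tz: dt.tzinfo = DEFAULT_TZ

    def __post_init__(self) -> None:
        hours = [h for e in self.schedule for h in e.hours]
        if sorted(hours) != list(range(24)):
            raise ValueError("schedule must cover each hour 0..23 exactly once")
        if self.gps_sigma_axis < 0 or self.step_cv < 0:
            raise ValueError("gps_sigma_axis and step_cv must be >= 0")
        for e in self.schedule:
            if not 0.0 <= e.p_move <= 1.0 or not 0.0 <= e.grazing_prob <= 1.0:
                raise ValueError("schedule probabilities must be in [0, 1]")

    @classmethod
    def for_treatment(cls, treatment: str, block: str = "1", **overrides) -> "SimConfig":
        preset = TREATMENT_PRESETS[treatment]
        paddock_id = f"{treatment}{block}"
        paddock = overrides.pop(
            "paddock",
            PaddockSpec(
                paddock_id, block, treatment, 600_000.0, 5_710_000.0, 600_100.0, 5_710_100.0
            ),
        )
        # more intensive grazing means both longer steps and more frequent
        # relocations between feeding stations
        schedule = overrides.pop("schedule", DEFAULT_SCHEDULE)
        schedule = tuple(
            dataclasses.replace(
                e,
                step_mean_m=e.step_mean_m * preset.step_scale,
                p_switch=min(e.p_switch * preset.step_scale, 1.0),
            )
            for e in schedule
        )
        return cls(
            treatment=treatment,
            paddock=paddock,
            schedule=schedule,
            mean_ho=overrides.pop("mean_ho", preset.mean_ho),
            sd_ho=overrides.pop("sd_ho", preset.sd_ho),
            n_stations=overrides.pop("n_stations", preset.n_stations),
            station_spread=overrides.pop("station_spread", preset.station_spread),
            **overrides,
        )

    @property
    def planted_peak_hours(self) -> tuple[int, ...]:
        """Hours of the schedule entry with the highest expected
        per-interval displacement (p_move x mean step)."""
        best = max(self.schedule, key=lambda e: e.p_move * e.step_mean_m)
        return tuple(sorted(best.hours))


@dataclass
class SwardField:
    """Herbage on offer (g DM m-2) on a 1-m lattice over the paddock."""

    values: np.ndarray  # (n_rows, n_cols) = (height, width), row = northing
    origin_easting: float
    origin_northing: float

    def at(self, easting, northing) -> np.ndarray:
        e = np.asarray(easting, dtype=float)
        n = np.asarray(northing, dtype=float)
        col = np.clip((e - self.origin_easting).astype(int), 0, self.values.shape[1] - 1)
        row = np.clip((n - self.origin_northing).astype(int), 0, self.values.shape[0] - 1)
        return self.values[row, col]


@dataclass
class GroundTruth:
    """Planted quantities stored alongside a generated bundle."""

    collar_id: str
    treatment: str
    daily: pd.DataFrame  # date, true_distance, n_steps, n_moving, n_stationary
    hourly: pd.DataFrame  # date, hour, true_distance, n_moving, n_stationary
    grazing: pd.DataFrame  # date, hour, n_grazing, n_intervals
    peak_hours: tuple[int, ...]
    gps_sigma_axis: float
    calibration: tuple[float, float, float]  # intercept, slope, residual sd
    field_mean: float
    field_sd: float

    def to_dict(self) -> dict:
        def frame(df: pd.DataFrame) -> list[dict]:
            out = df.copy()
            if "date" in out.columns:
                out["date"] = out["date"].astype(str)
            return out.to_dict(orient="records")

        return {
            "collar_id": self.collar_id,
            "treatment": self.treatment,
            "daily": frame(self.daily),
            "hourly": frame(self.hourly),
            "grazing": frame(self.grazing),
            "peak_hours": list(self.peak_hours),
            "gps_sigma_axis": self.gps_sigma_axis,
            "calibration": list(self.calibration),
            "field_mean": self.field_mean,
            "field_sd": self.field_sd,
        }


# ---------------------------------------------------------------------------
# sward field and plate-meter sampling


def generate_sward_field(cfg: SimConfig, rng: np.random.Generator) -> SwardField:
    """Spatially correlated herbage field, scaled to the target mean/SD
    and floored at 0 g DM m-2.

    White noise smoothed with a Gaussian kernel whose SD is the patch
    correlation length, then standardised and rescaled. Flooring can
    shift the realised mean when sd > mean; a >10% shift warns.
    """
    width = int(round(cfg.paddock.max_easting - cfg.paddock.min_easting))
    height = int(round(cfg.paddock.max_northing - cfg.paddock.min_northing))
    if cfg.sd_ho == 0:
        values = np.full((height, width), float(cfg.mean_ho))
        return SwardField(values, cfg.paddock.min_easting, cfg.paddock.min_northing)
    white = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(white, sigma=cfg.patch_correlation_length, mode="reflect")
    z = (smooth - smooth.mean()) / smooth.std()
    values = np.maximum(cfg.mean_ho + cfg.sd_ho * z, 0.0)
    if abs(values.mean() - cfg.mean_ho) > 0.10 * cfg.mean_ho:
        warnings.warn("flooring at 0 shifted the field mean by more than 10%", stacklevel=2)
    return SwardField(values, cfg.paddock.min_easting, cfg.paddock.min_northing)


def _true_csh(herbage: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Invert the planted calibration: CSH consistent with the field."""
    return np.maximum((herbage - cfg.calib_intercept) / cfg.calib_slope, 0.0)


def sample_plate_meter(
    field: SwardField,
    cfg: SimConfig,
    rng: np.random.Generator,
    dates: list[dt.date] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plate-meter (csh.csv layout) and calibration-cut tables.

    Per date, ``n_csh_points`` random CSH readings derived from the
    field through the inverted planted calibration, plus ``n_cuts``
    destructive pairs whose observed herbage is the planted line
    evaluated at CSH plus Gaussian residual noise (floored at 0).
    """
    if dates is None:
        dates = fortnightly_dates(cfg.start_date, cfg.end_date)
    h, w = field.values.shape
    csh_rows, cut_rows = [], []
    for date in dates:
        e = field.origin_easting + rng.uniform(0, w, cfg.n_csh_points)
        n = field.origin_northing + rng.uniform(0, h, cfg.n_csh_points)
        csh = _true_csh(field.at(e, n), cfg)
        for j in range(cfg.n_csh_points):
            csh_rows.append(
                {
                    "paddock_id": cfg.paddock.paddock_id,
                    "date": date,
                    "point_id": f"P{j + 1:02d}",
                    "csh_cm": csh[j],
                    "easting": e[j],
                    "northing": n[j],
                }
            )
        ce = field.origin_easting + rng.uniform(0, w, cfg.n_cuts)
        cn = field.origin_northing + rng.uniform(0, h, cfg.n_cuts)
        ccsh = _true_csh(field.at(ce, cn), cfg)
        herb = np.maximum(
            cfg.calib_intercept
            + cfg.calib_slope * ccsh
            + rng.normal(0.0, cfg.calib_residual_sd, cfg.n_cuts),
            0.0,
        )
        for j in range(cfg.n_cuts):
            cut_rows.append(
                {
                    "paddock_id": cfg.paddock.paddock_id,
                    "date": date,
                    "csh_cm": ccsh[j],
                    "herbage_g_dm_m2": herb[j],
                }
            )
    return pd.DataFrame(csh_rows), pd.DataFrame(cut_rows)


def fortnightly_dates(start: dt.date, end: dt.date, every_days: int = 14) -> list[dt.date]:
    """Plate-meter schedule: interior dates every two weeks from day 2."""
    dates = []
    d = start + dt.timedelta(days=1)
    while d < end:
        dates.append(d)
        d += dt.timedelta(days=every_days)
    return dates or [start + dt.timedelta(days=1)]


# ---------------------------------------------------------------------------
# cow movement and activity


def _pick_stations(
    field: SwardField, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Feeding stations at short-sward (low herbage) cells; rest sites
    anywhere. Coordinates are lattice-cell centres."""
    h, w = field.values.shape
    border = 10  # keep stations and rest sites clear of the fence line
    # stations scatter over a use-neighbourhood covering station_spread of
    # the paddock side: large under heavy grazing pressure (the whole
    # paddock is worked), small when use concentrates on a few clusters
    span_h = min(max(int(cfg.station_spread * h), 20), h - 2 * border)
    span_w = min(max(int(cfg.station_spread * w), 20), w - 2 * border)
    r0 = int(rng.integers(border, h - border - span_h + 1))
    c0 = int(rng.integers(border, w - border - span_w + 1))
    allowed = np.zeros((h, w), dtype=bool)
    allowed[r0 : r0 + span_h, c0 : c0 + span_w] = True
    flat = field.values.ravel()
    inside = allowed.ravel()
    if np.ptp(flat[inside]) > 0:
        candidates = np.flatnonzero(inside & (flat <= np.quantile(flat[inside], 0.2)))
    else:
        candidates = np.flatnonzero(inside)
    # greedy thinning: distinct feeding stations sit in distinct short-sward
    # patches, not stacked inside one (candidates cluster by construction)
    order = rng.permutation(candidates)
    rows, cols = np.divmod(order, w)
    chosen: list[int] = []
    min_sep = 25.0 * cfg.station_spread
    for j in range(len(order)):
        if len(chosen) >= cfg.n_stations:
            break
        if all(
            np.hypot(rows[j] - rows[c], cols[j] - cols[c]) >= min_sep for c in chosen
        ):
            chosen.append(j)
    if len(chosen) < cfg.n_stations:  # crowded neighbourhood: fill regardless
        extra = [j for j in range(len(order)) if j not in chosen]
        chosen.extend(extra[: cfg.n_stations - len(chosen)])
    stations = np.column_stack(
        [
            field.origin_easting + cols[chosen] + 0.5,
            field.origin_northing + rows[chosen] + 0.5,
        ]
    )
    ridx = rng.choice(np.flatnonzero(inside), size=cfg.n_rest_sites, replace=False)
    rrows, rcols = np.divmod(ridx, w)
    rest = np.column_stack(
        [field.origin_easting + rcols + 0.5, field.origin_northing + rrows + 0.5]
    )
    return stations, rest


def simulate_cow(
    cfg: SimConfig,
    rng: np.random.Generator,
    field: SwardField | None = None,
    collar_id: str | None = None,
) -> tuple[Trajectory, pd.DataFrame, GroundTruth]:
    """Simulate one collar deployment: noisy fixes, 64-s head-tilt
    intervals, and the ground truth behind both.

    Per fix interval the cow either relocates (probability from the
    schedule block of the local hour) toward its current target -
    a feeding station during grazing blocks, a rest site at night -
    with gamma step lengths and bearing noise, or holds position.
    Emitted positions add isotropic Gaussian GPS error. Step lengths are
    scaled by fix_interval / step_reference_interval so true daily
    distance does not depend on the sampling rate.
    """
    if field is None:
        field = generate_sward_field(cfg, rng)
    if collar_id is None:
        collar_id = f"C-{cfg.paddock.paddock_id}"
    stations, rest = _pick_stations(field, cfg, rng)
    pools = {"stations": stations, "rest": rest}

    n_days = period_duration(cfg.start_date, cfg.end_date)
    total_s = n_days * 86400
    interval = cfg.fix_interval
    n_fixes = int(total_s // interval)
    offsets = np.arange(n_fixes) * interval  # s since local midnight of day 1

    hour_of = ((offsets // 3600) % 24).astype(int)
    day_of = (offsets // 86400).astype(int)
    entry_of_hour = np.empty(24, dtype=int)
    for k, e in enumerate(cfg.schedule):
        for hh in e.hours:
            entry_of_hour[hh] = k
    entry_idx = entry_of_hour[hour_of]

    p_move = np.array([e.p_move for e in cfg.schedule])[entry_idx]
    step_scale = interval / cfg.step_reference_interval
    step_mean = np.array([e.step_mean_m for e in cfg.schedule])[entry_idx] * step_scale

    u_move = rng.random(n_fixes)
    u_switch = rng.random(n_fixes)
    bearing_noise = rng.normal(0.0, np.radians(30.0), n_fixes)
    if cfg.step_cv > 0:
        shape = 1.0 / cfg.step_cv**2
        step_draw = rng.standard_gamma(shape, n_fixes) / shape
    else:
        step_draw = np.ones(n_fixes)
    pick = rng.integers(0, 2**31 - 1, n_fixes)  # target choices, modded per pool

    min_e, min_n, max_e, max_n = cfg.paddock.bounds
    # keep the true path far enough from the fence that reported (noisy)
    # positions stay inside the paddock
    margin = max(2.0, 6.0 * cfg.gps_sigma_axis)
    x = (min_e + max_e) / 2.0
    y = (min_n + max_n) / 2.0
    xs = np.empty(n_fixes)
    ys = np.empty(n_fixes)
    xs[0], ys[0] = x, y
    step_true = np.zeros(n_fixes)  # step i = displacement between fix i-1 and fix i
    moving = np.zeros(n_fixes, dtype=bool)

    p_switch_of = np.array([e.p_switch for e in cfg.schedule])[entry_idx]
    prev_entry = -1
    tx, ty = x, y
    for i in range(1, n_fixes):
        e_i = entry_idx[i - 1]  # behaviour during the interval starting at fix i-1
        if e_i != prev_entry or u_switch[i] < p_switch_of[i - 1]:
            pool = pools[cfg.schedule[e_i].pool]
            tx, ty = pool[pick[i] % len(pool)]
            prev_entry = e_i
        if u_move[i] < p_move[i - 1]:
            # long commute steps toward the target; short local steps once
            # there (a grazing bout around the station) until a retarget
            bearing = np.arctan2(tx - x, ty - y) + bearing_noise[i]
            length = step_draw[i] * step_mean[i - 1]
            if np.hypot(tx - x, ty - y) < cfg.local_radius_m:
                length *= cfg.local_step_factor
            nx = min(max(x + length * np.sin(bearing), min_e + margin), max_e - margin)
            ny = min(max(y + length * np.cos(bearing), min_n + margin), max_n - margin)
            step_true[i] = np.hypot(nx - x, ny - y)
            moving[i] = step_true[i] > 0
            x, y = nx, ny
        xs[i], ys[i] = x, y

    if cfg.gps_sigma_axis > 0:
        xs_obs = xs + rng.normal(0.0, cfg.gps_sigma_axis, n_fixes)
        ys_obs = ys + rng.normal(0.0, cfg.gps_sigma_axis, n_fixes)
    else:
        xs_obs, ys_obs = xs, ys

    t0_local = dt.datetime.combine(cfg.start_date, dt.time(0, 0), tzinfo=cfg.tz)
    t0 = pd.Timestamp(t0_local).tz_convert("UTC")
    times = t0 + pd.to_timedelta(offsets, unit="s")
    traj = Trajectory(
        collar_id=collar_id,
        times=pd.DatetimeIndex(times),
        easting=xs_obs,
        northing=ys_obs,
        nominal_interval=interval,
    )

    # ground truth, bucketed by the start fix of each step (the same
    # convention the trajectory module uses)
    dates = np.array(
        [cfg.start_date + dt.timedelta(days=int(d)) for d in range(n_days)], dtype=object
    )
    step_frame = pd.DataFrame(
        {
            "date": dates[day_of[:-1]],
            "hour": hour_of[:-1],
            "true_distance": step_true[1:],
            "moving": moving[1:],
        }
    )
    hourly = (
        step_frame.groupby(["date", "hour"], sort=True)
        .agg(
            true_distance=("true_distance", "sum"),
            n_moving=("moving", "sum"),
            n_steps=("moving", "size"),
        )
        .reset_index()
    )
    hourly["n_stationary"] = hourly["n_steps"] - hourly["n_moving"]
    daily = (
        hourly.groupby("date", sort=True)
        .agg(
            true_distance=("true_distance", "sum"),
            n_moving=("n_moving", "sum"),
            n_stationary=("n_stationary", "sum"),
            n_steps=("n_steps", "sum"),
        )
        .reset_index()
    )

    # 64-s head-tilt stream
    n_int = int(total_s // 64)
    int_offsets = np.arange(n_int) * 64.0
    int_hours = ((int_offsets // 3600) % 24).astype(int)
    int_days = (int_offsets // 86400).astype(int)
    g_prob = np.array([e.grazing_prob for e in cfg.schedule])[entry_of_hour[int_hours]]
    grazing_flag = rng.random(n_int) < g_prob
    head_up = np.where(
        grazing_flag,
        rng.uniform(0.05, 0.45, n_int),
        rng.uniform(0.55, 0.95, n_int),
    )
    activity = pd.DataFrame(
        {
            "collar_id": collar_id,
            "start": pd.DatetimeIndex(t0 + pd.to_timedelta(int_offsets, unit="s")),
            "head_up_proportion": head_up,
        }
    )
    grazing_truth = (
        pd.DataFrame(
            {"date": dates[int_days], "hour": int_hours, "grazing": grazing_flag}
        )
        .groupby(["date", "hour"], sort=True)["grazing"]
        .agg(n_grazing="sum", n_intervals="size")
        .reset_index()
    )

    truth = GroundTruth(
        collar_id=collar_id,
        treatment=cfg.treatment,
        daily=daily,
        hourly=hourly,
        grazing=grazing_truth,
        peak_hours=cfg.planted_peak_hours,
        gps_sigma_axis=cfg.gps_sigma_axis,
        calibration=(cfg.calib_intercept, cfg.calib_slope, cfg.calib_residual_sd),
        field_mean=float(field.values.mean()),
        field_sd=float(field.values.std(ddof=1)),
    )
    return traj, activity, truth


def simulate_stationary_collar(
    sigma_axis: float,
    fix_interval: float,
    n_hours: float,
    rng: np.random.Generator,
    collar_id: str = "STATIC",
    start: dt.datetime | None = None,
) -> Trajectory:
    """A collar lying still: every reported fix is pure GPS noise around
    one true position. The workhorse for quantifying the spurious
    distance floor that position noise adds to hourly budgets."""
    if start is None:
        start = dt.datetime(2017, 5, 19, tzinfo=dt.timezone.utc)
    n_fixes = int(n_hours * 3600.0 // fix_interval) + 1
    times = pd.Timestamp(start) + pd.to_timedelta(np.arange(n_fixes) * fix_interval, unit="s")
    e = 600_050.0 + rng.normal(0.0, sigma_axis, n_fixes)
    n = 5_710_050.0 + rng.normal(0.0, sigma_axis, n_fixes)
    return Trajectory(
        collar_id=collar_id,
        times=pd.DatetimeIndex(times),
        easting=e,
        northing=n,
        nominal_interval=fix_interval,
    )


# ---------------------------------------------------------------------------
# full scenario bundles


@dataclass
class ScenarioBundle:
    """One treatments x blocks x period dataset with its ground truth."""

    seed: int
    fix_interval: float
    start_date: dt.date
    end_date: dt.date
    paddocks: list[PaddockSpec]
    deployments: list[DeploymentMeta]
    herds: list[HerdRoster]
    trajectories: dict[str, Trajectory]
    activity: pd.DataFrame
    csh: pd.DataFrame
    calibration: pd.DataFrame
    ground_truth: dict[str, GroundTruth]
    fields: dict[str, SwardField]


def _herd_weights(lu_target: float, rng: np.random.Generator) -> tuple[float, ...]:
    """Cow live weights (kg) whose LU sum is exactly the target."""
    n = max(1, int(round(lu_target * 500.0 / 660.0)))
    w = np.clip(rng.normal(660.0, 70.0, n), 450.0, 900.0)
    w *= lu_target * 500.0 / w.sum()
    return tuple(float(v) for v in w)


def scenario_suite(
    seed: int,
    treatments: tuple[str, ...] = ("M", "L", "VL"),
    n_blocks: int = 3,
    fix_interval: float = 128.0,
    start_date: dt.date = dt.date(2017, 5, 18),
    end_date: dt.date = dt.date(2017, 6, 14),
    period_id: str = "2017",
    **config_overrides,
) -> ScenarioBundle:
    """Generate the full replicated design: one collar per paddock,
    treatments x blocks, a single grazing period. Deterministic under
    the seed (independent child streams per paddock)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(treatments) * n_blocks)

    paddocks: list[PaddockSpec] = []
    deployments: list[DeploymentMeta] = []
    herds: list[HerdRoster] = []
    trajectories: dict[str, Trajectory] = {}
    truths: dict[str, GroundTruth] = {}
    fields: dict[str, SwardField] = {}
    activity_frames: list[pd.DataFrame] = []
    csh_frames: list[pd.DataFrame] = []
    cut_frames: list[pd.DataFrame] = []

    n_days = period_duration(start_date, end_date)
    k = 0
    for b in range(1, n_blocks + 1):
        for ti, treatment in enumerate(treatments):
            rng = np.random.default_rng(children[k])
            k += 1
            paddock_id = f"{treatment}{b}"
            origin_e = 600_000.0 + ti * 150.0
            origin_n = 5_710_000.0 + (b - 1) * 150.0
            paddock = PaddockSpec(
                paddock_id, str(b), treatment, origin_e, origin_n, origin_e + 100.0, origin_n + 100.0
            )
            cfg = SimConfig.for_treatment(
                treatment,
                block=str(b),
                paddock=paddock,
                fix_interval=fix_interval,
                start_date=start_date,
                end_date=end_date,
                **config_overrides,
            )
            field = generate_sward_field(cfg, rng)
            traj, activity, truth = simulate_cow(cfg, rng, field=field)
            csh, cuts = sample_plate_meter(field, cfg, rng)

            preset = TREATMENT_PRESETS[treatment]
            weights = _herd_weights(preset.lu_per_ha, rng)
            herds.append(HerdRoster(paddock_id, period_id, weights, n_days))
            deployments.append(
                DeploymentMeta(
                    collar_id=traj.collar_id,
                    cow_id=f"cow-{paddock_id}",
                    live_weight=weights[0],
                    paddock_id=paddock_id,
                    treatment=treatment,
                    period_id=period_id,
                    start_date=start_date,
                    end_date=end_date,
                )
            )
            traj.deployment = deployments[-1]
            paddocks.append(paddock)
            trajectories[traj.collar_id] = traj
            truths[traj.collar_id] = truth
            fields[paddock_id] = field
            activity_frames.append(activity)
            csh_frames.append(csh)
            cut_frames.append(cuts)

    return ScenarioBundle(
        seed=seed,
        fix_interval=fix_interval,
        start_date=start_date,
        end_date=end_date,
        paddocks=paddocks,
        deployments=deployments,
        herds=herds,
        trajectories=trajectories,
        activity=pd.concat(activity_frames, ignore_index=True),
        csh=pd.concat(csh_frames, ignore_index=True),
        calibration=pd.concat(cut_frames, ignore_index=True),
        ground_truth=truths,
        fields=fields,
    )


def write_bundle(bundle: ScenarioBundle, out_dir: str | Path) -> None:
    """Emit the five input files plus the ground-truth manifest.

    fixes.csv, activity.csv, csh.csv, calibration.csv, config.yaml and
    ground_truth.json; numeric columns use fixed decimal formatting so
    identical seeds give byte-identical output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fixes(bundle.trajectories, out / "fixes.csv")
    act = bundle.activity.copy()
    act["head_up_proportion"] = act["head_up_proportion"].round(4)
    write_activity(act, out / "activity.csv")
    csh = bundle.csh.copy()
    for c in ("csh_cm", "easting", "northing"):
        csh[c] = csh[c].round(4)
    write_csh(csh, out / "csh.csv")
    cuts = bundle.calibration.copy()
    for c in ("csh_cm", "herbage_g_dm_m2"):
        cuts[c] = cuts[c].round(4)
    write_calibration(cuts, out / "calibration.csv")

    config = {
        "seed": bundle.seed,
        "fix_interval": bundle.fix_interval,
        "timezone": "+02:00",
        "cell_size": 5.0,
        "paddocks": [
            {
                "paddock_id": p.paddock_id,
                "block_id": p.block_id,
                "treatment": p.treatment,
                "min_easting": p.min_easting,
                "min_northing": p.min_northing,
                "max_easting": p.max_easting,
                "max_northing": p.max_northing,
                "area_m2": p.area_m2,
            }
            for p in bundle.paddocks
        ],
        "herds": [
            {
                "paddock_id": h.paddock_id,
                "period_id": h.period_id,
                "live_weights": [round(w, 2) for w in h.live_weights],
                "days_on_pasture": h.days_on_pasture,
            }
            for h in bundle.herds
        ],
        "deployments": [
            {
                "collar_id": d.collar_id,
                "cow_id": d.cow_id,
                "live_weight": round(d.live_weight, 2),
                "paddock_id": d.paddock_id,
                "treatment": d.treatment,
                "period_id": d.period_id,
                "start_date": d.start_date.isoformat(),
                "end_date": d.end_date.isoformat(),
            }
            for d in bundle.deployments
        ],
    }
    (Path(out) / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    manifest = {cid: gt.to_dict() for cid, gt in sorted(bundle.ground_truth.items())}
    (Path(out) / "ground_truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
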