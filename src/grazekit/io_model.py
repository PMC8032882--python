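"""Domain types, CSV readers/writers and husbandry bookkeeping.

Coordinates are planar UTM metres (the zone is declared in the analysis
config, never transformed here). Timestamps are stored in UTC; all
day/hour bucketing downstream converts to a configurable analysis
timezone. The default, UTC+02:00, is Central European Summer Time,
matching the grazing seasons the pipeline is built for.

Husbandry conventions used throughout:

* one livestock unit (LU) = 500 kg live weight;
* period lengths are inclusive day counts (end - start + 1), which is
  the convention that reproduces published period durations from their
  start/end dates;
* stocking density is LU per hectare present at a given time, stocking
  rate is LU x days on pasture per hectare and 365-day year.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LU_REFERENCE_KG",
    "M2_PER_HA",
    "DAYS_PER_YEAR",
    "DEFAULT_TZ",
    "CsvDialect",
    "GPSFix",
    "DeploymentMeta",
    "Trajectory",
    "ActivityInterval",
    "PaddockSpec",
    "SwardSample",
    "CalibrationPair",
    "HerdRoster",
    "AnalysisConfig",
    "parse_timezone",
    "read_fixes",
    "write_fixes",
    "read_activity",
    "write_activity",
    "read_csh",
    "write_csh",
    "read_calibration",
    "write_calibration",
    "load_config",
    "trim_deployment",
    "period_duration",
    "livestock_units",
    "stocking_density",
    "stocking_rate",
]

LU_REFERENCE_KG = 500.0  # one livestock unit = 500 kg live weight
M2_PER_HA = 10_000.0
DAYS_PER_YEAR = 365.0
DEFAULT_TZ = dt.timezone(dt.timedelta(hours=2))

TREATMENTS = ("M", "L", "VL")


@dataclass(frozen=True)
class CsvDialect:
    """CSV flavour. Default is comma-separated with '.' decimals; European
    exports with ';' separators and ',' decimals are accepted too."""

    sep: str = ","
    decimal: str = "."


@dataclass(frozen=True)
class GPSFix:
    collar_id: str
    timestamp: dt.datetime  # timezone-aware, UTC
    easting: float  # m, UTM
    northing: float  # m, UTM


@dataclass(frozen=True)
class DeploymentMeta:
    collar_id: str
    cow_id: str
    live_weight: float  # kg
    paddock_id: str
    treatment: str  # M / L / VL
    period_id: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.live_weight <= 0:
            raise ValueError("live_weight must be > 0")
        if self.start_date > self.end_date:
            raise ValueError("deployment start_date after end_date")


@dataclass
class Trajectory:
    """Time-ordered GPS fixes of one collar deployment.

    Fixes are stored columnar (a UTC DatetimeIndex plus coordinate
    arrays) for vectorised downstream work; :meth:`fixes` materialises
    row objects on demand.
    """

    collar_id: str
    times: pd.DatetimeIndex
    easting: np.ndarray
    northing: np.ndarray
    nominal_interval: float  # s (60 or 128 in the study designs supported)
    deployment: DeploymentMeta | None = None

    def __post_init__(self) -> None:
        self.easting = np.asarray(self.easting, dtype=float)
        self.northing = np.asarray(self.northing, dtype=float)
        if not isinstance(self.times, pd.DatetimeIndex):
            self.times = pd.DatetimeIndex(self.times)
        if self.times.tz is None:
            self.times = self.times.tz_localize("UTC")
        else:
            self.times = self.times.tz_convert("UTC")
        n = len(self.times)
        if len(self.easting) != n or len(self.northing) != n:
            raise ValueError("times/easting/northing length mismatch")
        if n and not (
            np.all(np.isfinite(self.easting)) and np.all(np.isfinite(self.northing))
        ):
            raise ValueError(f"non-finite coordinates in collar {self.collar_id!r}")
        if n > 1:
            diffs = np.diff(self.times.asi8)
            if np.any(diffs <= 0):
                raise ValueError(
                    f"timestamps not strictly increasing for collar {self.collar_id!r}"
                )
        if self.nominal_interval <= 0:
            raise ValueError("nominal_interval must be > 0")

    def __len__(self) -> int:
        return len(self.times)

    def fixes(self) -> list[GPSFix]:
        return [
            GPSFix(self.collar_id, t.to_pydatetime(), e, n)
            for t, e, n in zip(self.times, self.easting, self.northing)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "collar_id": self.collar_id,
                "timestamp": self.times,
                "easting": self.easting,
                "northing": self.northing,
            }
        )

    def subset(self, mask: np.ndarray) -> "Trajectory":
        """New trajectory keeping fixes where ``mask`` is True (order kept)."""
        return replace(
            self,
            times=self.times[mask],
            easting=self.easting[mask],
            northing=self.northing[mask],
        )

    @classmethod
    def from_fixes(
        cls,
        fixes: Sequence[GPSFix],
        nominal_interval: float,
        deployment: DeploymentMeta | None = None,
    ) -> "Trajectory":
        if not fixes:
            raise ValueError("cannot build a Trajectory from zero fixes")
        collar_ids = {f.collar_id for f in fixes}
        if len(collar_ids) != 1:
            raise ValueError(f"fixes span several collars: {sorted(collar_ids)}")
        fixes = sorted(fixes, key=lambda f: f.timestamp)
        return cls(
            collar_id=fixes[0].collar_id,
            times=pd.DatetimeIndex([f.timestamp for f in fixes]),
            easting=np.array([f.easting for f in fixes]),
            northing=np.array([f.northing for f in fixes]),
            nominal_interval=nominal_interval,
            deployment=deployment,
        )


@dataclass(frozen=True)
class ActivityInterval:
    """One accelerometer summary interval: the proportion of the 64 s
    during which the head-tilt angle exceeded 15 deg (head *up*)."""

    collar_id: str
    start: dt.datetime
    head_up_proportion: float
    duration: float = 64.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.head_up_proportion <= 1.0:
            raise ValueError("head_up_proportion outside [0, 1]")
        if self.duration != 64.0:
            raise ValueError("activity intervals are 64 s in this design")


@dataclass(frozen=True)
class PaddockSpec:
    paddock_id: str
    block_id: str
    treatment: str
    min_easting: float
    min_northing: float
    max_easting: float
    max_northing: float
    area_m2: float = 10_000.0

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        w = self.max_easting - self.min_easting
        h = self.max_northing - self.min_northing
        if w <= 0 or h <= 0:
            raise ValueError("degenerate paddock bounds")
        if abs(w * h - self.area_m2) > 0.01 * self.area_m2:
            raise ValueError(
                f"paddock {self.paddock_id!r}: bounds area {w * h:.0f} m2 "
                f"disagrees with declared area {self.area_m2:.0f} m2 by >1%"
            )

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.min_easting, self.min_northing, self.max_easting, self.max_northing)


@dataclass(frozen=True)
class SwardSample:
    paddock_id: str
    date: dt.date
    point_id: str
    csh: float  # compressed sward height, cm
    easting: float | None = None
    northing: float | None = None

    def __post_init__(self) -> None:
        if self.csh < 0:
            raise ValueError("CSH must be >= 0")


@dataclass(frozen=True)
class CalibrationPair:
    paddock_id: str
    date: dt.date
    csh: float  # cm
    herbage: float  # g DM m-2

    def __post_init__(self) -> None:
        if self.csh < 0 or self.herbage < 0:
            raise ValueError("CSH and herbage must be >= 0")


@dataclass(frozen=True)
class HerdRoster:
    paddock_id: str
    period_id: str
    live_weights: tuple[float, ...]  # kg
    days_on_pasture: int

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.live_weights):
            raise ValueError("all live weights must be > 0")
        if self.days_on_pasture < 0:
            raise ValueError("days_on_pasture must be >= 0")


# ---------------------------------------------------------------------------
# timezone / config


def parse_timezone(spec: str | float | int | dt.tzinfo | None) -> dt.tzinfo:
    """Parse a fixed-offset timezone: '+02:00', '-05:30', 2, or a tzinfo."""
    if spec is None:
        return DEFAULT_TZ
    if isinstance(spec, dt.tzinfo):
        return spec
    if isinstance(spec, (int, float)):
        return dt.timezone(dt.timedelta(hours=float(spec)))
    s = spec.strip()
    if s.upper() in {"UTC", "Z"}:
        return dt.timezone.utc
    sign = 1
    if s[0] in "+-":
        sign = -1 if s[0] == "-" else 1
        s = s[1:]
    if ":" in s:
        hh, mm = s.split(":")
    else:
        hh, mm = s, "0"
    return dt.timezone(sign * dt.timedelta(hours=int(hh), minutes=int(mm)))


@dataclass
class AnalysisConfig:
    """Structured run configuration (paddocks, herds, deployments, knobs)."""

    paddocks: list[PaddockSpec] = field(default_factory=list)
    herds: list[HerdRoster] = field(default_factory=list)
    deployments: list[DeploymentMeta] = field(default_factory=list)
    timezone: dt.tzinfo = DEFAULT_TZ
    fix_interval: float = 128.0
    cell_size: float = 5.0
    peak_hours: tuple[int, ...] | None = None  # manual override; None = detect
    seed: int = 0

    def paddock(self, paddock_id: str) -> PaddockSpec:
        for p in self.paddocks:
            if p.paddock_id == paddock_id:
                return p
        raise KeyError(paddock_id)


def _parse_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return dt.date.fromisoformat(str(x))


def load_config(path: str | Path) -> AnalysisConfig:
    """Load the YAML analysis config (see README for the layout)."""
    raw = yaml.safe_load(Path(path).read_text())
    paddocks = [
        PaddockSpec(
            paddock_id=str(p["paddock_id"]),
            block_id=str(p.get("block_id", "1")),
            treatment=p["treatment"],
            min_easting=float(p["min_easting"]),
            min_northing=float(p["min_northing"]),
            max_easting=float(p["max_easting"]),
            max_northing=float(p["max_northing"]),
            area_m2=float(p.get("area_m2", 10_000.0)),
        )
        for p in raw.get("paddocks", [])
    ]
    herds = [
        HerdRoster(
            paddock_id=str(h["paddock_id"]),
            period_id=str(h["period_id"]),
            live_weights=tuple(float(w) for w in h["live_weights"]),
            days_on_pasture=int(h["days_on_pasture"]),
        )
        for h in raw.get("herds", [])
    ]
    deployments = [
        DeploymentMeta(
            collar_id=str(d["collar_id"]),
            cow_id=str(d["cow_id"]),
            live_weight=float(d["live_weight"]),
            paddock_id=str(d["paddock_id"]),
            treatment=d["treatment"],
            period_id=str(d["period_id"]),
            start_date=_parse_date(d["start_date"]),
            end_date=_parse_date(d["end_date"]),
        )
        for d in raw.get("deployments", [])
    ]
    peaks = raw.get("peak_hours")
    return AnalysisConfig(
        paddocks=paddocks,
        herds=herds,
        deployments=deployments,
        timezone=parse_timezone(raw.get("timezone")),
        fix_interval=float(raw.get("fix_interval", 128.0)),
        cell_size=float(raw.get("cell_size", 5.0)),
        peak_hours=tuple(int(h) for h in peaks) if peaks is not None else None,
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# CSV readers / writers

_FIX_COLUMNS = ["collar_id", "timestamp", "easting", "northing"]


def read_fixes(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    nominal_interval: float | None = None,
) -> dict[str, Trajectory]:
    """Read a collar fix table into one :class:`Trajectory` per collar.

    Rows are grouped by collar and sorted by time; duplicated
    (collar, timestamp) pairs are rejected (there is no defensible way
    to merge them). If ``nominal_interval`` is None it is inferred per
    collar as the median inter-fix gap.
    """
    df = pd.read_csv(
        path, sep=dialect.sep, decimal=dialect.decimal, dtype={"collar_id": str}
    )
    missing = [c for c in _FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: no fixes", stacklevel=2)
        return {}
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    for col in ("easting", "northing"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = ts.isna() | df["easting"].isna() | df["northing"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed row at line {line}")
    df = df.assign(timestamp=ts)
    dup = df.duplicated(subset=["collar_id", "timestamp"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: duplicate (collar, timestamp) at line {line}")

    out: dict[str, Trajectory] = {}
    for collar_id, g in df.groupby("collar_id", sort=True):
        g = g.sort_values("timestamp")
        times = pd.DatetimeIndex(g["timestamp"])
        if nominal_interval is None:
            if len(times) > 1:
                interval = float(np.median(np.diff(times.asi8)) / 1e9)
            else:
                interval = 60.0
        else:
            interval = float(nominal_interval)
        out[str(collar_id)] = Trajectory(
            collar_id=str(collar_id),
            times=times,
            easting=g["easting"].to_numpy(),
            northing=g["northing"].to_numpy(),
            nominal_interval=interval,
        )
    return out


def write_fixes(
    trajectories: Iterable[Trajectory] | Mapping[str, Trajectory],
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
) -> None:
    if isinstance(trajectories, Mapping):
        trajectories = list(trajectories.values())
    frames = [t.to_frame() for t in trajectories]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_FIX_COLUMNS)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    df.to_csv(path, sep=dialect.sep, decimal=dialect.decimal, index=False)


def read_activity(path: str | Path, dialect: CsvDialect = CsvDialect()) -> pd.DataFrame:
    """Read 64-s head-tilt intervals: collar_id, start, head_up_proportion."""
    df = pd.read_csv(path, sep=dialect.sep, decimal=dialect.decimal, dtype={"collar_id": str})
    needed = ["collar_id", "start", "head_up_proportion"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["start"] = pd.to_datetime(df["start"], utc=True, format="ISO8601")
    p = df["head_up_proportion"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError(f"{path}: head_up_proportion outside [0, 1]")
    return df.sort_values(["collar_id", "start"]).reset_index(drop=True)


def write_activity(df: pd.DataFrame, path: str | Path, dialect: CsvDialect = CsvDialect()) -> None:
    out = df.copy()
    out["start"] = pd.to_datetime(out["start"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S+00:00"
    )
    out.to_csv(path, sep=dialect.sep, decimal=dialect.decimal, index=False)


def read_csh(path: str | Path, dialect: CsvDialect = CsvDialect()) -> pd.DataFrame:
    """Read plate-meter samples: paddock_id, date, point_id, csh_cm
    (optionally easting, northing)."""
    df = pd.read_csv(path, sep=dialect.sep, decimal=dialect.decimal, dtype={"paddock_id": str})
    needed = ["paddock_id", "date", "point_id", "csh_cm"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if (df["csh_cm"].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative CSH")
    return df


def write_csh(df: pd.DataFrame, path: str | Path, dialect: CsvDialect = CsvDialect()) -> None:
    df.to_csv(path, sep=dialect.sep, decimal=dialect.decimal, index=False)


def read_calibration(path: str | Path, dialect: CsvDialect = CsvDialect()) -> pd.DataFrame:
    """Read calibration cuts: paddock_id, date, csh_cm, herbage_g_dm_m2."""
    df = pd.read_csv(path, sep=dialect.sep, decimal=dialect.decimal, dtype={"paddock_id": str})
    needed = ["paddock_id", "date", "csh_cm", "herbage_g_dm_m2"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if (df["csh_cm"].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative CSH")
    if (df["herbage_g_dm_m2"].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative herbage")
    return df


def write_calibration(df: pd.DataFrame, path: str | Path, dialect: CsvDialect = CsvDialect()) -> None:
    df.to_csv(path, sep=dialect.sep, decimal=dialect.decimal, index=False)


# ---------------------------------------------------------------------------
# deployment bookkeeping


def period_duration(start_date: dt.date, end_date: dt.date) -> int:
    """Inclusive day count of a grazing period (end - start + 1)."""
    start_date, end_date = _parse_date(start_date), _parse_date(end_date)
    if start_date > end_date:
        raise ValueError("start_date after end_date")
    return (end_date - start_date).days + 1


def trim_deployment(
    traj: Trajectory,
    start_date: dt.date | None = None,
    end_date: dt.date | None = None,
    tz: dt.tzinfo = DEFAULT_TZ,
) -> Trajectory:
    """Drop fixes on the first and last calendar day of the period.

    Data from the deployment and pickup days mix collar acclimatization
    and handling with grazing and are excluded from every analysis.
    Days are local calendar days in the analysis timezone.
    """
    if start_date is None or end_date is None:
        if traj.deployment is None:
            raise ValueError("no period dates given and trajectory has no deployment")
        start_date = start_date or traj.deployment.start_date
        end_date = end_date or traj.deployment.end_date
    start_date, end_date = _parse_date(start_date), _parse_date(end_date)
    if period_duration(start_date, end_date) < 3:
        raise ValueError("period shorter than 3 days: trimming would leave nothing")
    local_dates = traj.times.tz_convert(tz).date
    keep = np.array([(start_date < d < end_date) for d in local_dates])
    return traj.subset(keep)


def livestock_units(weights: Sequence[float]) -> float:
    """Sum of live weights expressed in 500-kg livestock units."""
    weights = list(weights)
    if not weights:
        warnings.warn("empty weight list: 0 LU", stacklevel=2)
        return 0.0
    if any(w <= 0 for w in weights):
        raise ValueError("live weights must be > 0")
    return float(sum(weights)) / LU_REFERENCE_KG


def stocking_density(lu: float, area_m2: float) -> float:
    """Instantaneous stocking density, LU per hectare."""
    if area_m2 <= 0:
        raise ValueError("area must be > 0")
    return lu / (area_m2 / M2_PER_HA)


def stocking_rate(lu: float, days_on_pasture: float, area_m2: float) -> float:
    """Annualised stocking rate: LU x days on pasture / (365 d x area in ha)."""
    if area_m2 <= 0:
        raise ValueError("area must be > 0")
    if days_on_pasture < 0:
        raise ValueError("days_on_pasture must be >= 0")
    return lu * days_on_pasture / (DAYS_PER_YEAR * (area_m2 / M2_PER_HA))
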