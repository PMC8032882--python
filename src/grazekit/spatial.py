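"""Paddock rasterization, time-in-cell budgets, Camargo evenness and
density-percentile map export.

Each paddock is rasterized into square cells (5 x 5 m by default, so a
1-ha paddock yields 400 cells). Every GPS fix deposits one nominal fix
interval of time into the cell containing it - per-location accounting,
with no interpolation of sub-interval paths. Cells are half-open
[x, x+s) x [y, y+s), so a fix exactly on an interior boundary belongs
to the higher-index cell.

The Camargo evenness index of a time-in-cell budget with proportions
p_i = seconds_i / total over all N cells (never-visited cells included,
which is what lets spatial clustering pull the index toward 0) is

    E = 1 - sum_{i<j} |p_i - p_j| / N

E = 1 for perfectly even use; a single occupied cell gives E = 1/N.
The pairwise sum is evaluated via the sorted identity
sum_{i<j} |p_i - p_j| = sum_k (2k - N - 1) p_(k) (ascending order
statistics), which is O(N log N).
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import DEFAULT_TZ, Trajectory
from .trajectory import PeakHours

__all__ = [
    "Grid",
    "CellTimeBudget",
    "EvennessResult",
    "build_grid",
    "assign_time",
    "split_active_other",
    "camargo_index",
    "density_percentile_map",
    "density_map_geojson",
]


@dataclass(frozen=True)
class Grid:
    origin_easting: float
    origin_northing: float
    cell_size: float
    n_cols: int
    n_rows: int

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_index(self, easting, northing) -> np.ndarray:
        """Flat row-major cell index per point; -1 for points outside."""
        e = np.asarray(easting, dtype=float)
        n = np.asarray(northing, dtype=float)
        col = np.floor((e - self.origin_easting) / self.cell_size).astype(int)
        row = np.floor((n - self.origin_northing) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        flat = row * self.n_cols + col
        return np.where(inside, flat, -1)

    def cell_polygon(self, row: int, col: int) -> list[list[float]]:
        x0 = self.origin_easting + col * self.cell_size
        y0 = self.origin_northing + row * self.cell_size
        s = self.cell_size
        return [[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s], [x0, y0]]


@dataclass
class CellTimeBudget:
    grid: Grid
    group: str  # 'active', 'other' or 'all'
    seconds: np.ndarray  # length n_cells, zeros included
    n_fixes: int
    n_outside: int

    def __post_init__(self) -> None:
        self.seconds = np.asarray(self.seconds, dtype=float)
        if len(self.seconds) != self.grid.n_cells:
            raise ValueError("seconds vector length != number of cells")
        if np.any(self.seconds < 0):
            raise ValueError("negative cell time")


@dataclass(frozen=True)
class EvennessResult:
    paddock_id: str
    period_id: str
    group: str
    camargo: float


def build_grid(
    bounds: tuple[float, float, float, float], cell_size: float = 5.0, pad: bool = False
) -> Grid:
    """Rasterize rectangular paddock bounds (min_e, min_n, max_e, max_n).

    Sides must be divisible by ``cell_size``; with ``pad=True`` the grid
    is instead extended to the next whole cell.
    """
    min_e, min_n, max_e, max_n = bounds
    w, h = max_e - min_e, max_n - min_n
    if w <= 0 or h <= 0 or cell_size <= 0:
        raise ValueError("degenerate bounds or cell size")
    cols, rows = w / cell_size, h / cell_size
    if pad:
        n_cols, n_rows = int(np.ceil(cols - 1e-9)), int(np.ceil(rows - 1e-9))
    else:
        if abs(cols - round(cols)) > 1e-9 or abs(rows - round(rows)) > 1e-9:
            raise ValueError(
                f"bounds {w:g} x {h:g} m not divisible by cell size {cell_size:g} m "
                "(use pad=True to extend)"
            )
        n_cols, n_rows = int(round(cols)), int(round(rows))
    return Grid(min_e, min_n, cell_size, n_cols, n_rows)


def assign_time(
    traj: Trajectory,
    grid: Grid,
    nominal_interval: float | None = None,
    group: str = "all",
    allow_outside: bool = False,
) -> CellTimeBudget:
    """Deposit one fix interval of time per fix into its containing cell.

    Fixes outside the grid extent are counted and excluded; more than 5%
    outside raises unless ``allow_outside`` (GPS error can push fixes
    just over a fence line, but a large outside share means the grid is
    wrong).
    """
    interval = traj.nominal_interval if nominal_interval is None else nominal_interval
    idx = grid.cell_index(traj.easting, traj.northing)
    outside = int(np.sum(idx < 0))
    if len(traj) and outside / len(traj) > 0.05 and not allow_outside:
        raise ValueError(
            f"{outside}/{len(traj)} fixes outside the grid extent "
            "(pass allow_outside=True to proceed)"
        )
    if outside:
        warnings.warn(f"{outside} fixes outside the grid extent excluded", stacklevel=2)
    seconds = np.bincount(idx[idx >= 0], minlength=grid.n_cells).astype(float) * interval
    return CellTimeBudget(grid, group, seconds, n_fixes=len(traj) - outside, n_outside=outside)


def split_active_other(
    traj: Trajectory, peaks: PeakHours, tz: dt.tzinfo = DEFAULT_TZ
) -> tuple[Trajectory, Trajectory]:
    """Partition fixes into 'active time' (local hour in the activity
    peaks) and 'other time' (everything else). Disjoint and exhaustive."""
    if not peaks.hours:
        warnings.warn("empty peak set: active partition is empty", stacklevel=2)
    hours = traj.times.tz_convert(tz).hour
    active_mask = np.isin(hours, list(peaks.hours))
    return traj.subset(active_mask), traj.subset(~active_mask)


def camargo_index(budget: CellTimeBudget | np.ndarray) -> float:
    """Camargo evenness of a time-in-cell budget (all N cells included).

    E = 1 - sum_{i<j} |p_i - p_j| / N in [0, 1]; 1 iff all cells share
    the time equally, 1/N when a single cell holds everything. Raises
    on an all-zero budget (evenness of nothing is undefined).
    """
    seconds = budget.seconds if isinstance(budget, CellTimeBudget) else np.asarray(budget, float)
    total = seconds.sum()
    if total <= 0:
        raise ValueError("total time is 0: evenness undefined")
    p = np.sort(seconds / total)  # ascending order statistics
    n = len(p)
    k = np.arange(1, n + 1)
    pairwise = float(np.sum((2 * k - n - 1) * p))
    return float(1.0 - pairwise / n)


def density_percentile_map(budget: CellTimeBudget, n_classes: int = 5) -> pd.DataFrame:
    """Class occupied cells into quantile bands of their nonzero time.

    Returns one row per cell with ``row, col, seconds, density_class``:
    class 0 = never visited, classes 1..n_classes = increasing quantile
    bands of the nonzero times (ties can collapse bands; fewer than
    ``n_classes`` occupied cells yield fewer classes, with a warning).
    """
    grid = budget.grid
    seconds = budget.seconds
    occupied = seconds > 0
    classes = np.zeros(grid.n_cells, dtype=int)
    n_occ = int(occupied.sum())
    if n_occ:
        if n_occ < n_classes:
            warnings.warn(
                f"only {n_occ} occupied cells: fewer than {n_classes} classes", stacklevel=2
            )
        qs = np.quantile(seconds[occupied], np.linspace(0, 1, n_classes + 1)[1:-1])
        edges = np.unique(qs)  # degenerate ties collapse classes
        classes[occupied] = np.searchsorted(edges, seconds[occupied], side="left") + 1
    rows, cols = np.divmod(np.arange(grid.n_cells), grid.n_cols)
    return pd.DataFrame(
        {"row": rows, "col": cols, "seconds": seconds, "density_class": classes}
    )


def density_map_geojson(budget: CellTimeBudget, classed: pd.DataFrame | None = None) -> dict:
    """GeoJSON FeatureCollection of cell polygons with time and class
    attributes (planar UTM coordinates, suitable for GIS styling)."""
    if classed is None:
        classed = density_percentile_map(budget)
    grid = budget.grid
    features = []
    for rec in classed.itertuples(index=False):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [grid.cell_polygon(int(rec.row), int(rec.col))],
                },
                "properties": {
                    "row": int(rec.row),
                    "col": int(rec.col),
                    "seconds": float(rec.seconds),
                    "density_class": int(rec.density_class),
                    "group": budget.group,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh)
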