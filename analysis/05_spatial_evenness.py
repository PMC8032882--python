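#!/usr/bin/env python
"""Rasterized space use and Camargo evenness.

Rasterizes each 1-ha paddock into 400 5 x 5 m cells, splits fixes into
active time (detected peak hours) vs other time, accumulates time per
cell, computes the Camargo evenness index per paddock and group, and
exports density-percentile maps (CSV for all paddocks, GeoJSON for one).
"""

import json
from pathlib import Path

import pandas as pd

from grazekit import io_model, spatial, trajectory

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    cfg = io_model.load_config(DATA / "config.yaml")
    trajs = io_model.read_fixes(DATA / "fixes.csv", nominal_interval=cfg.fix_interval)
    deployments = {d.collar_id: d for d in cfg.deployments}

    peak_df = pd.read_csv(OUT / "peaks.csv")
    peaks = trajectory.PeakHours(frozenset(peak_df["hour"]), "detected")
    print(f"active time = hours {sorted(peaks.hours)}")

    rows, cell_rows = [], []
    geojson_done = False
    for collar_id, traj in trajs.items():
        dep = deployments[collar_id]
        paddock = cfg.paddock(dep.paddock_id)
        grid = spatial.build_grid(paddock.bounds, cfg.cell_size)
        trimmed = io_model.trim_deployment(traj, dep.start_date, dep.end_date, cfg.timezone)
        active, other = spatial.split_active_other(trimmed, peaks, cfg.timezone)
        for group, part in (("active", active), ("other", other)):
            budget = spatial.assign_time(part, grid, cfg.fix_interval, group)
            rows.append(
                {
                    "paddock_id": paddock.paddock_id,
                    "treatment": dep.treatment,
                    "group": group,
                    "camargo": spatial.camargo_index(budget),
                }
            )
            classed = spatial.density_percentile_map(budget)
            classed.insert(0, "paddock_id", paddock.paddock_id)
            classed.insert(1, "group", group)
            cell_rows.append(classed)
            if not geojson_done and group == "active":
                gj = spatial.density_map_geojson(budget, classed.drop(columns=["paddock_id", "group"]))
                (OUT / "density_map.geojson").write_text(json.dumps(gj))
                geojson_done = True

    camargo = pd.DataFrame(rows)
    print("\nCamargo evenness by grazing intensity and group:")
    print(camargo.groupby(["group", "treatment"])["camargo"].mean().round(3))

    OUT.mkdir(exist_ok=True)
    camargo.to_csv(OUT / "camargo.csv", index=False)
    pd.concat(cell_rows, ignore_index=True).to_csv(OUT / "density_map.csv", index=False)
    print(f"\nwrote camargo.csv, density_map.csv, density_map.geojson under {OUT}/")


if __name__ == "__main__":
    main()
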