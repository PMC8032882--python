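#!/usr/bin/env python
"""Sward double-sampling: calibration, herbage summaries, allowance.

Fits the pooled CSH -> herbage OLS calibration from the destructive
cuts, predicts herbage at every plate-meter point, summarises herbage on
offer (mean, SD herbage, CV) per paddock-date, computes the herbage
allowance per livestock unit, and correlates mean daily walking distance
with SD herbage across paddocks.
"""

from pathlib import Path

import pandas as pd

from grazekit import io_model, sward

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    cfg = io_model.load_config(DATA / "config.yaml")
    cuts = io_model.read_calibration(DATA / "calibration.csv")
    csh = io_model.read_csh(DATA / "csh.csv")

    model = sward.fit_calibrations(cuts)["pooled"]
    print(f"calibration (pooled, n={model.n}): herbage = {model.intercept:.1f} "
          f"+ {model.slope:.2f} * CSH; R2_adj = {model.r2_adj:.2f}, RMSE = {model.rmse:.1f} g DM m-2")

    summary = sward.summarise_predictions(csh, model)
    summary["treatment"] = summary["paddock_id"].str.rstrip("123")
    by_treatment = summary.groupby("treatment")[["mean_ho", "sd_ho", "cv"]].mean()
    print("\nherbage on offer by grazing intensity (mean over paddocks and dates):")
    print(by_treatment.round(1))

    herd_lu = {
        h.paddock_id: io_model.livestock_units(h.live_weights) for h in cfg.herds
    }
    rows = []
    for paddock_id, g in summary.groupby("paddock_id"):
        paddock = cfg.paddock(paddock_id)
        lu = herd_lu[paddock_id]
        ha = sward.herbage_allowance(g["mean_ho"].mean(), paddock.area_m2, lu)
        rows.append(
            {
                "paddock_id": paddock_id,
                "treatment": paddock.treatment,
                "lu": lu,
                "mean_ho": g["mean_ho"].mean(),
                "mean_sd_ho": g["sd_ho"].mean(),
                "herbage_allowance": ha,
                "sqrt_allowance": float(sward.sqrt_transform([ha])[0]),
            }
        )
    allowance = pd.DataFrame(rows)
    print("\nherbage allowance (kg DM LU-1) by grazing intensity:")
    print(allowance.groupby("treatment")["herbage_allowance"].mean().round(0))

    daily = pd.read_csv(OUT / "budgets_daily.csv")
    daily = daily[~daily["outlier"]]
    dist = daily.groupby("collar_id")["distance"].mean().rename("daily_distance")
    merged = allowance.assign(collar_id="C-" + allowance["paddock_id"]).merge(
        dist, on="collar_id"
    )
    r, p = sward.distance_heterogeneity_correlation(
        merged, "daily_distance", "mean_sd_ho"
    )
    print(f"\nPearson r(mean daily distance, SD herbage) across paddocks: "
          f"{r:.2f} (p = {p:.2g})")

    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "herbage_summary.csv", index=False)
    allowance.to_csv(OUT / "allowance.csv", index=False)
    pd.DataFrame(
        [{
            "scope": model.scope, "intercept": model.intercept, "slope": model.slope,
            "n": model.n, "r2_adj": model.r2_adj, "rmse": model.rmse,
        }]
    ).to_csv(OUT / "calibration_models.csv", index=False)
    print(f"wrote calibration_models.csv, herbage_summary.csv, allowance.csv under {OUT}/")


if __name__ == "__main__":
    main()
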