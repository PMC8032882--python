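# grazekit

Analysis pipeline for the movement behaviour of GPS-collared suckler
cows on semi-natural grassland under contrasting grazing intensities —
moderate (M), lenient (L) and very lenient (VL) continuous grazing on
replicated 1-ha paddocks.

The pipeline answers two linked questions: how much do cows walk under
each grazing intensity, and how evenly do they use the paddock — and
relates both to how much herbage is on offer and how patchily it is
distributed. It is aimed at movement ecologists and precision-livestock
researchers working with collar GPS fix tables (60 or 128 s intervals),
collar accelerometer head-tilt summaries (64-s intervals), and
rising-plate-meter sward surveys.

## What it computes

**Walking-distance budgets** (`grazekit.trajectory`). Step distances
between consecutive fixes are planar Euclidean distances on the UTM
coordinates, d = √(Δe² + Δn²), summed per local hour and per local day
(each step belongs to the bucket of its start fix, so hourly budgets
add up to the daily budget exactly). Deployment and pickup days are
excluded. Outliers are fenced per Tukey: values outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] are masked. Hourly budgets feed a diurnal
profile from which the morning/evening activity peaks are detected
(hours reaching the top quartile of the 24 hourly means, provided
max/median ≥ 1.2). A stationary collar still records distance because
of GPS noise: with per-axis error SD σ, the expected spurious distance
over n steps is n·σ·√π — about 40 m per hour at a 128-s fix interval
and σ = 0.8 m.

**Grazing classification** (`grazekit.activity`). The collar reports,
per 64-s interval, the proportion of time the head-tilt angle exceeded
15° (head up). An interval is grazing when the head was lowered at
least half of the time: grazing ⇔ (1 − head_up_proportion) ≥ 0.5.
Grazing minutes per hour = (grazing intervals starting in the hour) ×
64/60, capped at 60, and are paired with hourly walking distance.

**Sward double sampling** (`grazekit.sward`). Compressed sward height
(CSH, cm) is read at 50 random points per paddock fortnightly;
occasional destructive cuts pair CSH with herbage dry matter. An OLS
calibration herbage = a + b·CSH converts every CSH reading into
predicted herbage on offer (HO, g DM m⁻²), from which per-paddock
summaries follow: mean HO, its within-paddock SD (*SD herbage*, the
spatial-heterogeneity proxy), CV, and the herbage allowance
HA = mean HO × area / 1000 / LU (kg DM per 500-kg livestock unit).

**Spatial evenness** (`grazekit.spatial`). Each 1-ha paddock is
rasterized into 400 5 × 5 m cells; every fix deposits one fix interval
of time into its cell. Fixes are split into *active time* (peak hours)
and *other time*. The Camargo evenness index over all N cells,

    E = 1 − Σ_{i<j} |p_i − p_j| / N,   p_i = seconds_i / total,

is 1 for perfectly even use and 1/N when a single cell holds all the
time. Density-percentile maps (quintiles of the nonzero cell times) are
exported as CSV and GeoJSON.

**Synthetic herd** (`grazekit.synth`). The study's raw collar data are
not public, so a simulator generates all five inputs with the structure
the analysis assumes: spatially correlated patchy sward fields with
treatment-specific mean/SD, a diurnally scheduled cow (biased random
walk between short-sward feeding stations, morning/evening peaks,
isotropic GPS noise), head-tilt streams tied to the behaviour state,
and plate-meter sampling from a known calibration line — all with a
ground-truth manifest for parameter-recovery testing.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
simulated replicated design (3 intensities × 3 blocks, one collar per
paddock, 28-day spring period, 128-s fixes, seed 42):

```
python analysis/01_simulate_herd.py
python analysis/02_distance_budgets.py
python analysis/03_grazing_classification.py
python analysis/04_sward_calibration.py
python analysis/05_spatial_evenness.py
```

Output of step 02 (distance budgets):

```
daily budgets: 234 rows, 3 Tukey outliers (1.3%)

mean daily walking distance (m) by grazing intensity:
             mean    std  count
treatment
L          3171.0  175.0     77
M          3587.0  219.0     78
VL         3184.0  170.0     76

detected activity-peak hours: [5, 6, 7, 19, 20, 21]
share of daily distance in peak hours: 0.44
```

Cows walk 3.2–3.6 km per day, most under moderate grazing, with
activity concentrated at 5–7 h and 19–21 h local time. Step 04 fits the
sward calibration and computes allowances:

```
calibration (pooled, n=126): herbage = 23.4 + 26.37 * CSH; R2_adj = 0.77, RMSE = 71.6 g DM m-2

herbage allowance (kg DM LU-1) by grazing intensity:
treatment
L      821.0
M      419.0
VL    1370.0

Pearson r(mean daily distance, SD herbage) across paddocks: -0.92 (p = 0.00037)
```

Herbage allowance rises from moderate to very lenient grazing while
walking distance correlates negatively with sward heterogeneity. Step
05 quantifies spatial clustering:

```
Camargo evenness by grazing intensity and group:
group   treatment
active  L            0.344
        M            0.383
        VL           0.247
other   L            0.324
        M            0.343
        VL           0.192
```

Space use is most even under moderate grazing and most clustered under
very lenient grazing, during the activity peaks and outside them.

## Layout

```
src/grazekit/      io_model, trajectory, activity, sward, spatial, synth
analysis/          numbered pipeline drivers (write tables under results/)
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical conventions, limitations
```
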