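# Methods

This note documents the models and conventions behind grazekit: what
each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Coordinates, time, bucketing

Fixes carry planar UTM coordinates (metres); no geodetic transforms are
performed. Timestamps are stored in UTC and converted to a fixed-offset
*analysis timezone* (default UTC+02:00, Central European Summer Time)
for all day/hour bucketing; a day is midnight-to-midnight local. Period
lengths are inclusive day counts (end − start + 1), the convention under
which published period start/end dates reproduce the published
durations. Fixes on the first and last calendar day of a deployment are
excluded everywhere: they mix collar handling and acclimatization with
grazing.

## Distance budgets

Step distance is the Euclidean distance between consecutive fixes.
Each step is assigned wholly to the local hour/day containing its
*start* fix. This avoids splitting steps across bucket boundaries; at
60–128-s fix intervals the assignment bias is far below the sampling
noise of an hourly budget, and it makes the hourly budgets of a day sum
to the daily budget exactly (tests assert agreement to 1e-12 relative,
the float summation-order limit). Bucket *completeness* is observed
fixes / expected fixes (3600/interval per hour, 86400/interval per day,
capped at 1); hours below 0.90 and days below 0.95 are flagged and
excluded from diurnal summaries. Collar-reported distance/speed columns,
when present in an export, are ignored — distances are always recomputed
from coordinates.

Outlier filtering uses single-pass Tukey fences,
[Q1 − 1.5·IQR, Q3 + 1.5·IQR], with quartiles by linear interpolation
between order statistics (the common statistical default; the field
wording of the rule is ambiguous but Tukey fences are the standard
reading). On Gaussian data the fences exclude ≈0.7% of points,
consistent with the ≲5% exclusion rates reported for collar distance
data. Filtering is applied once per treatment to the daily budgets
before summary; it is not iterated.

Hourly distances are log-transformed (natural log of distance + 1 m)
where a variance-stabilised scale is needed; the 1-m offset keeps
genuinely stationary hours finite.

### GPS-noise floor

Reported positions of a motionless collar are true position plus
isotropic Gaussian error with per-axis SD σ. The difference of two
consecutive errors has per-axis SD σ√2, so the mean step is
σ√2·√(π/2) = σ√π and the expected spurious distance over n steps is

    E[D] = n · σ · √π.

Collar accuracy is usually quoted as the mean radial deviation
r = σ·√(π/2); r = 1.0 m gives σ ≈ 0.80 m, and at a 128-s interval
(28.125 steps/hour) E[D] ≈ 39.9 m per hour — the night-time noise floor
visible in hourly budgets. `expected_noise_distance` implements the
closed form; the acceptance script verifies it against Monte-Carlo
through the full budget pipeline.

### Peak detection

The diurnal profile is the per-hour mean (± SE) of complete hourly
budgets, dates treated as replicates. Peak hours are those whose mean
reaches the q = 0.75 quantile of the 24 hourly means — six hours, the
width of the morning + evening grazing bouts of spring/summer cattle —
guarded by a flatness test (max/median ≥ 1.2; otherwise an empty set is
returned with a warning and the caller falls back to configured hours).
A manual hour list always wins over detection. The *active fraction* is
the share of daily distance walked in the peak hours, computed per
collar and averaged.

## Grazing classification

The accelerometer reports, per 64-s interval, the proportion of time
the head-tilt angle exceeded 15° (head **up**). Grazing ⇔
(1 − head_up_proportion) ≥ 0.5, i.e. head lowered at least half the
interval, with the tie classified as grazing ("at least half" read
inclusively). The threshold is a parameter to allow recalibration
against direct observation; validation itself is out of scope. Intervals
belong to the hour of their start instant (64 s ≪ 1 h; no proration),
so grazing minutes per hour are (grazing-interval count) × 64/60,
capped at 60. Overlapping intervals indicate a corrupt export and raise.
The paired grazing-minutes × hourly-distance table is produced for
downstream ANCOVA, which is delegated to general statistics packages.

## Sward double sampling

Calibration fits herbage (g DM m⁻²) on CSH (cm) by OLS (statsmodels).
Scope is pooled per period across paddocks — 6–8 cuts per paddock are
too few for stable paddock-level fits — with grouped fits available via
`fit_calibrations(by=...)`. Diagnostics: adjusted R² with the
one-regressor correction, RMSE as root *mean* squared residual (n
denominator; at n = 24 this underestimates the residual SD by a factor
√(22/24) ≈ 0.96, visible in recovery tests). Predictions are floored at
0 g DM m⁻² (physical constraint). SD herbage uses the sample SD (n − 1).
Because prediction is affine, SD herbage = |slope| × SD(CSH) exactly
when nothing is floored — a pipeline identity used as a test. Herbage
allowance per livestock unit (LU = 500 kg live weight) is
mean HO × area / 1000 / LU; period-level values average per-date values
with equal weights (measurement dates are fortnightly and roughly
evenly spaced). Allowance is square-root transformed where a
variance-stabilised scale is required. The correlation between mean
daily walking distance and SD herbage is exposed as an output; no
reference value exists for it.

## Rasterized space use and evenness

Paddock bounds are rasterized into square cells (default 5 m; a 1-ha
paddock gives 400 cells). Cells are half-open [x, x+s) × [y, y+s), so a
fix exactly on an interior boundary deterministically belongs to the
higher-index cell. Each fix deposits one nominal fix interval of time
into its cell — per-location accounting, no interpolation of
sub-interval paths. Fixes outside the grid are counted and excluded;
more than 5% outside raises unless explicitly allowed. Fixes are split
into active time (peak hours) vs other time before accumulation; the
two budgets conserve total time exactly.

The Camargo evenness index over all N cells (zeros included — this is
what lets clustering pull the index toward 0) is
E = 1 − Σ_{i<j}|p_i − p_j| / N. The denominator is N, following the
index's original definition; the single-occupied-cell closed form
E = 1/N is the regression test for that choice. The pairwise sum is
evaluated with the sorted identity Σ_{i<j}|p_i − p_j| =
Σ_k (2k − N − 1) p_(k) (ascending), O(N log N); tests compare it to the
O(N²) definition to 1e-12. Evenness is computed per collar; pooling
collars within a paddock is left to the caller (the emulated design has
one collar per paddock). Density maps class occupied cells into
quintiles of their nonzero times (ties collapse classes; zero cells are
their own class) and are exported as CSV and GeoJSON cell polygons in
UTM coordinates.

## The synthetic generator

The generator emulates the statistical structure the analysis needs,
not cattle cognition. Its defaults describe one spring period (18 May –
14 June, 28 days) on 1-ha paddocks at a 128-s fix interval.

**Sward field.** White noise on a 1-m lattice smoothed with a Gaussian
kernel (SD = patch correlation length, default 10 m), standardised,
scaled to the treatment's target mean/SD of herbage on offer and floored
at 0. Treatment targets (g DM m⁻²): M 235 ± 81, L 319 ± 109,
VL 355 ± 119 — the published spring-period estimates. CSH at any point
is obtained by inverting a planted calibration line (default
herbage = 50 + 25·CSH, residual SD 70 g DM m⁻², the published residual
scale); plate-meter sampling draws 50 points per date and 6–8
destructive pairs with Gaussian residuals.

**Movement.** A two-state diurnal schedule: grazing blocks (peak hours
5–7 and 19–21, daytime 8–18) and night rest (22–4). Per fix interval
the cow steps with probability p_move toward its current target — a
short-sward *feeding station* during grazing blocks, a rest site at
night — with gamma step lengths (CV 0.5) and 30° bearing noise; within
15 m of the target, steps shrink to 0.45× (a grazing bout around the
station). Targets switch stochastically (per-block switch rates), so a
station visit lasts tens of minutes. Feeding stations are drawn from
the lowest-quintile sward cells inside a *use-neighbourhood* covering
`station_spread` of the paddock side, with a minimum separation so
distinct stations occupy distinct patches. Treatment presets: M — many
stations (14) over the whole paddock, longest steps; VL — few stations
(5) in half the paddock; L intermediate. This reproduces the observed
structure: daily distances of 2.5–4 km with M highest, ~40% of distance
in the six peak hours, and space use most even under M and most
clustered under VL. Step means refer to a reference fix interval
(128 s) and scale with the actual interval, so true daily distance does
not depend on the sampling rate. The true path keeps max(2 m, 6σ) clear
of the fence so that noisy reported positions stay inside the paddock.

**Emission.** Reported fixes are true position + isotropic Gaussian
noise (per-axis σ, default from a 1.0-m mean radial deviation).
Head-tilt intervals draw grazing states from the schedule block's
grazing probability; head-up proportions are uniform on [0.05, 0.45]
(grazing) or [0.55, 0.95] (not grazing) — correlated with the movement
state through the shared schedule, and cleanly separated so the
half-interval rule recovers the planted state exactly. Herd rosters
scale cow live weights (≈660 ± 70 kg) to hit the treatment's stocking
density exactly (M 5.3, L 3.8, VL 2.6 LU ha⁻¹, the published spring
values).

**Ground truth.** Each deployment records true per-day distance,
per-hour moving/stationary step counts, planted grazing intervals per
hour, planted peak hours, and the calibration coefficients, enabling the
recovery tests below.

**What it does not emulate.** No sward regrowth or depletion within a
period, no put-and-take stocking adjustments, no herd-mate interaction
(one collar per paddock, as in the emulated design; a herd-size option
exists for correlated herd-mates but is off by default), no GPS fix
dropout or multipath error structure, no tri-state ethogram (grazing vs
rest only). Passing tests therefore show the *pipeline* is correct
under realistic distance, diurnal and clustering structure — not that
the movement model would predict real cattle.

## Recovery conventions and problem sizes

Daily-distance recovery compares the planted per-deployment mean daily
distance with the observed mean corrected by
`expected_noise_distance(σ, n_stationary)` using the ground-truth count
of stationary steps; agreement is within 2%. The correction deliberately
ignores the small noise inflation of *moving* steps (≈σ²/d per step of
length d), which is second-order at the default step scale; individual
days also carry ~0.7% Monte-Carlo noise, which is why the recovery claim
is about the mean. Calibration recovery checks 95% CI coverage of the
planted line over 500 replicates (≥93% per parameter). Peak-hour
recovery is exact when the diurnal effect ratio (max/median hourly mean)
is ≥2. Camargo discrimination (clustered VL-like vs dispersed M-like
scenarios) is checked over 15 paired seeds with short periods — sizes
chosen to keep the default suite fast while leaving the comparisons
well-powered.

Tests run on reduced problem sizes (single blocks, 5–8-day periods);
the analysis drivers use the full 3 × 3 × 28-day design. All randomness
flows from explicit seeds through numpy Generators; identical seeds give
byte-identical written bundles (fixed decimal formatting).

## Known limitations

* Fixed-offset timezone only; runs spanning a DST transition would need
  a zoneinfo timezone (trivially accepted by the API, untested).
* The calibration treats CSH as error-free (classical OLS double
  sampling); errors-in-variables calibration is out of scope.
* Camargo evenness depends on cell size; 5 m is the design default and
  no cross-scale correction is attempted.
* The Tukey filter is single-pass by design; heavy-tailed budgets are
  not iteratively re-fenced.
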