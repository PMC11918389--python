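# Methods

This note records the models, parameter choices and numerical conventions
behind each module, the design decisions that were genuinely open, and what
the synthetic generators do and do not emulate.

## Spectral indices and segmentation

NDVI and NDSI are plain normalized differences on co-registered reflectance
grids.  Pixels whose denominator is exactly zero, or whose inputs are masked,
are flagged invalid rather than clamped or NaN-propagated: the indices are
undefined there, and silent NaNs corrupt downstream statistics.  Reflectance
is assumed pre-scaled; digital-number scaling, atmospheric correction and
cloud masking are out of scope (mid-monsoon scenes are known to be unreliable
for NDVI regardless).

Segmentation runs K-means on the scalar index values of valid pixels — not on
raw band vectors — because the classes of interest (vigour tiers, salinity
tiers) are ordered along the index axis.  Small instances (≤256 values with a
tractable split count) are solved to the *global* within-cluster-sum-of-squares
optimum by exact search over contiguous sorted partitions, a property specific
to 1-D data; larger rasters use seeded Lloyd iterations with k-means++
restarts (10 inits).  Centroids are reported sorted descending with labels
remapped, so label 0 is always the highest-index class and the three salinity
tiers are named high/moderate/low deterministically.

No published NDVI cut-off exists for "healthy" vegetation in the mapping this
package reimplements, so the healthy mask defaults to the top-centroid
K-means cluster — reproducible without an unstated constant — with an
optional user-set fixed threshold as the alternative.  Vegetation area is an
exact pixel count times pixel_size² (default 30 m), hence always a multiple
of 900 m².

Raster I/O uses a four-line-header plain-text grid (ncols, nrows, pixel_size,
nodata), keeping the toolkit free of geospatial binary dependencies; grids
are row-major from the top-left.

## Yield regression and error metrics

MAE, MSE and RMSE follow their standard definitions; `EvalReport` enforces
MSE = RMSE² and RMSE ≥ MAE.  Published "accuracy" percentages derived from
loss functions rarely state their normalization (and a single normalization
cannot make MSE and RMSE percentages coincide unless the loss is 0 or 1), so
`accuracy_pct` is an explicit convention of this package:
100·(1 − loss/reference), clipped to [0, 100], with the mean absolute
observed value as the default reference (its square for MSE).  The harness
offers ordinary least squares and a bagged tree ensemble (random forest)
behind seeded fits, with an 80/20 seeded shuffled split.

The synthetic yield generator draws soil moisture on [5, 95] %, a
chlorophyll index on [0.5, 8], NDVI/NDSI on [−1, 1], and forms a linear
target with Gaussian noise (sd 0.25 by default).  It supports parameter-
recovery and sample-size-scaling checks; it does not emulate the spatial or
temporal correlation of real remote-sensing yield data, so passing tests
demonstrate correctness of the fitting machinery, not field-level predictive
skill.

## Crop recommendation

The packaged reference profiles are per-crop mean values of temperature,
humidity, pH, N, P, K for the five regionally grown crops; there is no
published moisture mean, so moisture is never part of the centroid distance.
Features are z-scored using the standard deviation across the profile means
themselves (min-max range as the degenerate-feature fallback): without
scaling, the mg/kg nutrients dominate every other unit.

The default distance uses only the N/P/K signature.  A probe sample's
temperature and humidity record the ambient at measurement time — indoor
samples all share lab room values — not the growing-season climate the
profile means describe, and soil pH varies within a single field by more
than it does across these five profiles.  Including them makes the centroid
match follow the measurement environment instead of the agronomy (a sample
whose NPK sits exactly on the maize profile would be pulled to jute by a
cool room and alkaline spot-pH).  The feature set is configurable for data
where ambient records are representative.  Ties break alphabetically.

The synthetic dataset generator draws Gaussian samples around each profile
(spread given per feature or as a fraction of the across-profile range),
truncated to valid ranges and balanced across classes.  It emulates the
structure of a labelled recommendation table, not the 22-crop diversity or
label noise of real collections; held-out accuracy near 1.0 at low spread
shows the classifiers separate well-separated classes, nothing more.

## Fertilizer dosing

The conversion kg/ha = mg/kg × thickness × density / 10 is kept parametric,
but the packaged chart factor is fixed at 0.36 — the unique value that
reproduces the published dosing chart exactly given the nutrient fractions
(10 × 0.36/0.46 = 7.83 → urea 7.8 kg/ha; 18 kg/ha TSP; 6 kg/ha MOP).  The
stated physical ranges (10–15 cm layer, 1.0–1.4 g/cm³) imply factors of
1.0–2.1, an inconsistency this package surfaces rather than resolves: custom
parameters that disagree with 0.36 trigger a warning, never an error.

Chart convention: the base row is computed at 10 mg/kg (urea rounded to one
decimal, TSP/MOP to integers) and larger rows scale the rounded base
linearly, matching the printed 7.8 → 78 progression.  `recommend` itself is
linear in the deficit before rounding; non-positive deficits are explicitly
"not applicable" rather than zero, because surplus soil needs no product.

## Crop water requirement

The FAO-56 Penman–Monteith equation takes Δ, γ, es, ea as *inputs*, matching
how daily records are tabulated; helpers derive them from temperature,
relative humidity and altitude using the standard auxiliary formulas and are
kept separate from the core equation.  A negative computed ET₀ (possible
when Rn < G) is clamped to zero with a warning — daily reference
evapotranspiration is physically non-negative here.  Reported values follow
the two-decimal truncation convention where a reference number is quoted
(1.15 × 5.5 = 6.325 → 6.32); full precision is kept internally.

`daily_water_requirement` rounds the irrigation depth to 0.1 mm before the
volume product by default (dosing is quoted at that resolution: 6.3 mm over
100 m² → 630 L/day); pass `depth_decimals=None` for the exact product.

## Irrigation controllers

Sensor polarity is dry-high: raw counts ≈ 975–1023 on dry soil, ≈ 120–330 on
wet soil.  The average-value controller compares the mean over *all* sensors
with one threshold and drives every valve together, fully open or fully
closed.  The threshold is not published; the reference scenario rows bound it
to (392.5, 491.5) and the default 450 is the midpoint.  A mean exactly at the
threshold reads as wet (valves off).

The fuzzy controller is per-valve: sensors 1–3 feed valve 1 and 4–6 feed
valve 2 (the reference scenario keeps valve 1 fully open at a group mean of
738 while valve 2 closes at 264, which fixes this grouping), the crisp input
is the group mean, inference is Mamdani (min activation, max aggregation,
centroid defuzzification) onto a 0–32 stepper-step universe, rounded half
away from zero.

Membership functions are not published and were calibrated once against the
two printed scenarios plus the stated control intent ("the tap position
approaches off as moisture nears the required level"):

* Wet [0, 0, 446, 450] → Closed [0, 0, 0, 1]
* Moist [446, 450, 452, 454] → Partial [14, 16, 16, 18]
* Dry [452, 454, 1023, 1023] → Open [31, 32, 32, 32]

The narrow partial band just above the required-level count (~450) is forced
by the data: one printed row fully opens a valve at a group mean of 454.67,
so the Dry core must start by 454, while wide Wet/Moist shapes reaching down
to ~330 would defuzzify that row mid-scale.  Under this calibration all 40
printed per-valve states reproduce, and the two controllers share the same
required moisture level — the fuzzy controller differs by per-zone decisions
and a ~2/32-step actuation quantum instead of bang-bang.  Day/night and
tank-level antecedents are supported in the rule base but default to neutral,
since no rules for them are published.  All shapes are configurable.

Water accounting: volume = open time × calibrated flow (500 mL per 194.60 s
≈ 2.5694 mL/s), scaled by opening fraction; ledger open-seconds are
full-open-equivalent so the identity holds for partial openings too.  In the
packaged four-day reference ledger the average-value day-3 volume is stored
as 234.60 mL: the printed cell (243.60) disagrees with both the printed total
(968.53) and the run-time reconstruction (91.31 s × 2.5694 = 234.61), and
totals must equal the sum of entries.  The printed "66.23 % faster" figure is
likewise not derivable from the run-time table (totals give 66.87 %) and is
not reproduced.

## Soil-bed simulation

The plant is first-order linear per segment — moisture gains
`infiltration_gain × allocated mL` (0.3 %/mL), loses `drying_rate × dt`
(0.5 %/min) and adds seeded Gaussian process noise (sd 0.02 %), clipped to
[0, 100] % — the simplest model reproducing the qualitative trial traces.
Water poured on a segment at 100 % is lost to runoff via the clip.  Sensors
apply an affine dry-high map (raw = 1023 − 9·moisture) with read noise
(sd 8 counts).  Dispensed water is drawn from a finite tank (10 L) and
allocated to the commanding valve's zone proportionally to segment area;
mass balance (tank decrease = total dispensed) is exact bookkeeping, tested
to 1e-9 relative.

The default configuration encodes the reference trial's bed preparation:
175.75 cm² split into two valve zones of three sensed segments, zone 1 loaded
with dried soil (5 % moisture) and zone 2 saturated (95 %).  The control
interval is 1 s and the default comparison horizon one simulated hour —
long enough that both controllers pass through their initial fill and settle
into regulation; the methods are compared on identical initial states and
identical random streams per seed.

Under these conditions the fuzzy controller dispenses less water and
accumulates less (full-open-equivalent) valve time than the average-value
controller in every seeded run, for two mechanical reasons visible in the
trajectories: the global-mean controller opens both valves while the bed is
on average dry, pouring water onto the saturated zone (lost to runoff), and
its 32-step bang-bang quantum overshoots the setpoint where the fuzzy
controller drips at ~2 steps.  The resulting ~17 % saving is specific to
this bed, horizon and calibration; the hardware trial's 61–70 % figures
depend on unpublished physical constants and are not simulation targets.
Shorter horizons can invert the volume ordering (the fuzzy controller spends
more up front filling the dry zone toward the shared setpoint), which is why
the comparison defaults to the full hour.

What the simulator does not model: soil-water redistribution between
segments, hydraulic head effects, evaporation's dependence on weather, or
sensor drift.  Passing the controller-ordering property therefore shows the
two control laws behave as designed on a plant with these idealizations, not
that the percentage savings transfer to any particular field.

## Reproducibility

Every stochastic component (generators, K-means restarts, forests, splits,
simulation noise) takes an explicit seed; `scripts/acceptance.py` derives all
of its seeds from one `--seed` argument and recomputes each reported number
at run time.  Problem sizes there — 100 weather records, 50 exhaustive
K-means instances, 20 simulation seeds at a one-hour horizon, 500-row crop
datasets — were chosen as the smallest sizes at which the checked properties
are stable.
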