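# Methods

This note records the models implemented in `pestclim`, the defaults and
why they were chosen, and what the synthetic evaluation does and does not
demonstrate.

## Mechanistic ecoclimatic index

The engine follows the classical ecoclimatic-index formulation: weekly
growth potential times an annual survival penalty, gated by a degree-day
limiting condition.

**Weekly climate.** Inputs are monthly Tmin, Tmax, precipitation and
09:00/15:00 relative humidity. Temperatures and humidity are interpolated
to a daily curve by periodic linear interpolation between month mid-points
(day 15.5 of each month, December wrapping to January) and averaged over
weeks; precipitation is apportioned to weeks by day overlap, which
conserves the annual total exactly. The year is 52 weeks of 7 days with the
365th day folded into week 52. The true interpolation used by the original
desktop tool is not published; ours is linear and isolated in
`climate_io.monthly_to_weekly`, so it can be swapped. Degree-days use
7 days for every week (so a year contributes 364 accounting days), the
simplest discretization consistent with weekly rates.

**Growth.** TI and MI are trapezoids over DV0..DV3 (°C, on weekly mean
temperature) and SM0..SM3 (fractions of soil water capacity): zero outside
the outer thresholds, one on the optimum interval, linear ramps between.
GIA = 100 × mean(TI·MI) over the 52 weeks.

**Soil moisture.** A weekly bucket: SM advances by (rain − E)/capacity and
is clipped to [0, sm_cap], with evapotranspiration
E = evap_coeff · max(0, Tmean) · (1 − RH/100), RH the mean of the two
observation times. Defaults: capacity 100 mm, evap_coeff
0.8 mm·°C⁻¹·week⁻¹ (order-of-magnitude realism; both are config). The year
is cycled from SM = 0.5 to a periodic steady state (≥3, ≤10 cycles,
tolerance 1e-6 — a warning, not an error, on non-convergence).

The bucket ceiling `sm_cap` defaults to **1.0 fraction of capacity**
(excess rain runs off). A ceiling at SM3 would pin every wet cell exactly
where MI = 0, extinguishing the moisture index in all humid climates; a
ceiling above the wet-stress threshold SMWS would make saturated cells
accumulate wet stress indefinitely. With the default, wet stress never
arises from the bucket itself; it is still fully computable when a soil
moisture series is supplied directly (`sm_override` / `sm_w` arguments),
which is also how controlled-moisture scenarios and the idealized EI = 100
cell are expressed.

**Stress.** Each of cold/heat/dry/wet stress is
min(100, 100 · |rate| · Σ_w excess_w): cold excess is how far weekly Tmin
falls below TTCS, heat how far Tmax exceeds TTHS, dry how far SM falls
below SMDS, wet how far SM exceeds SMWS. Published parameter tables print
some rates with negative signs as direction markers; magnitudes are used.
The linear capped accumulation is a deliberate simplification — the
desktop tool's exact (version-dependent, partly exponential) law is not
public — and lives in one function (`accumulate_stresses`) so it can be
replaced. Interaction stresses and diapause are not modelled (the shipped
species sets neither).

**EI scale.** EI = GIA × SI ∈ [0, 100] when the degree-day requirement
(Σ_w max(0, Tmean_w − DV0) · 7 ≥ PDD) is met, else 0. Classes: 0
unsuitable, (0, 5] low, (5, 12] medium, > 12 high. The 0–100 scale is the
one the class thresholds require.

A naive per-week scalar implementation (`weekly_cell_result`) is kept
alongside the vectorised grid engine and the two are asserted equal to
1e-12 on random grids.

## Correlative track

- **Rarefaction** is greedy in input order with great-circle (haversine)
  distances: a record is kept iff no previously kept record is within the
  radius (10 km default). The kept set depends on input order; that order
  is the file order, documented and deterministic.
- **Background ("pseudo-absence") sampling**: uniform draw without
  replacement from land cells farther than the exclusion buffer (default =
  rarefaction radius) from every presence; 4× the presence-cell count by
  default. Records sharing a cell collapse to one presence row first.
- **Predictors** are the 19 standard bioclim summaries computed internally
  from the monthly fields (quarters are any 3 consecutive months, wrapping;
  temperature seasonality is sd × 100 with sample sd; precipitation
  seasonality is 100·sd/(1 + mean)). Constant predictors are dropped with
  a warning (the synthetic worlds have a constant diurnal range, so bio2
  always drops).
- **Classifier**: a random forest (scikit-learn), stratified k-fold CV
  (default 10); within each fold a stratified 70% of the non-held-out rows
  trains the model and the held-out fold is scored. AUC is the normalized
  Mann–Whitney U with midranks; kappa and TSS are evaluated at the max-TSS
  threshold (the common SDM choice; the rule is an argument). The final
  model refits on all rows.
- **Permutation importance** refits a clone on a stratified 70% split and
  measures mean AUC drop per shuffled predictor on the held-out 30%,
  clipped at zero and normalized to 100%. In-sample evaluation was
  rejected: an overfit forest credits pure-noise predictors several
  percent. Because the bioclim summaries are strongly collinear (some are
  deterministic functions of others in simple worlds), importance may
  concentrate on any one proxy of a driver; the recoverable quantity, and
  the one the tests assert, is the temperature-group vs
  precipitation-group share.
- **Natural breaks**: `jenks_breaks` is the exact Fisher dynamic program
  (optimal 1-D partition by within-class squared deviation), not the common
  heuristic. Whole-raster classification bins probabilities to ≤1024
  weighted values first (exact on the binned data) to stay O(k·1024²).
  Cells at or below an epsilon (default 0.05) are forced to level 0; with
  a probabilistic classifier almost every cell is strictly positive, so a
  literal "probability greater than 0" rule would keep everything — the
  epsilon is the operational cut, and it is exposed. When occurrence-cell
  probabilities are supplied, the three level boundaries may each be
  *lowered* to at most a fixed quantile of the occurrence probabilities
  (defaults 0.05/0.25/0.5, order enforced) — a monotone calibration of
  "denser records mean higher suitability". Boundaries can only move down,
  so calibration never demotes a cell.

## Ensemble, areas, economics

Host surfaces are binarized at the same epsilon and unioned; both class
rasters are restricted to the host mask and combined as id = 4·c + r
(0–15). "Total suitable" aggregates ids 1–15 (suitable under at least one
model); "high suitability" defaults to id 15 (high under both), both
configurable. Cell areas are spherical, R = 6371.0088 km (IUGG mean);
nodata cells are excluded from numerator and denominator. Percent change
relative to a zero historical area is reported as undefined (None), never
infinity. The mean suitability index is the unweighted cell average of a
continuous surface over a region (an area-weighted variant is a flag); the
loss figure is production value × mean suitability × loss coefficient,
rounded to the nearest integer unit.

## Synthetic worlds and virtual species

The generator emulates the gross structure of gridded monthly
climatologies: monthly mean temperature t_eq − lapse·|lat| +
A(|lat|/90)·cos(seasonal phase) with hemisphere-antiphase seasons; fixed
diurnal half-range; annual rainfall scaled by latitude (wet tropics) and by
a longitudinal "continentality" harmonic producing wet and dry belts;
wet-season concentration within the year; humidity as a base level with
seeded Gaussian noise. Defaults: 90×180 cells at 2°, t_eq 28 °C, lapse
0.6 °C/°lat, amplitude 18 °C at the pole, half-range 5 °C, 1100 mm with
gradient 0.75 and continentality 0.4, RH 70 ± 5%. A uniform warming offset
emulates future scenarios. The default grid plus the full engine and five
CV fits runs in well under a minute on one CPU; tests mostly use a 45×90
4° world.

The default virtual species is a product of trapezoids on warmest-month
maximum temperature (bio5: 23/28/30.5/33 °C) and annual rainfall (bio12:
850/1100/1350/1650 mm), rescaled to max 1 — a warm-humid specialist
suitable on roughly 18% of the default world's land, mirroring the
restricted tropical/subtropical ranges of the pests this pipeline targets.
A generalist occupying half the globe would make presence and background
samples statistically indistinguishable no matter the classifier; niche
breadth is part of the study design, not a free parameter, and is fixed
here.

What the synthetic evaluation does **not** show: real climates have
topography, coastlines, interannual variability and spatially structured
observation bias, none of which the generator emulates; occurrence
databases carry taxonomic and geocoding error; and real predictor
collinearity differs from the synthetic one. Passing tests demonstrate
the correctness and internal consistency of the algorithms and the
recoverability of a known signal under clean conditions — not predictive
skill on real species.

## Numerical choices and degenerate inputs

- Trapezoids: closed optimum interval, open support; boundary values
  (x = DV0, x = DV3) give exactly 0; degenerate ramps (DV1 = DV2 allowed)
  are handled.
- Ties in AUC: midranks. Ties in the max-TSS threshold: the smallest
  maximizing threshold.
- Jenks with fewer distinct values than classes: raster classification
  reduces k and maps the top class to level 3 (so a surface with a single
  positive value puts those cells at "high"); `jenks_breaks` itself raises.
- ASCII rasters print floats with repr round-trip precision; read-back is
  bit-for-bit, and nodata cells become the land mask.
- All stochastic stages take explicit seeds; the pipeline splits one root
  seed per stage via SHA-256, and its manifest (config, versions, output
  hashes) makes bit-for-bit reproduction checkable.

## Known limitations

- The stress-accumulation law and the monthly-to-weekly scheme are
  plausible stand-ins for unpublished internals of the desktop tool;
  absolute EI values will differ from it, though thresholds, responses and
  the EI formula follow the published parameterization.
- The soil bucket has no runoff/drainage dynamics beyond the hard ceiling
  and no irrigation scenarios.
- The correlative stage is a single learner by design (the "ensemble" here
  is the mechanistic × correlative overlay, not multi-algorithm
  averaging).
- Area accounting assumes a spherical Earth and cell-registered rasters in
  geographic coordinates.
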