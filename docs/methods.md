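# Methods

## Scope and data model

The package analyses the habitability of Enceladus' subsurface ocean for
hydrogenotrophic methanogens with two independent components: a
presence-only ecological niche model trained on Earth data (or synthetic
stand-ins), and a substrate-budget growth model.  All geospatial inputs
are point occurrence tables (WGS84 decimal degrees) and co-registered
north-up raster grids.  Points are sampled by the containing cell
(cell-centre convention, row 0 northernmost).  Rasters are read and
written as GeoTIFF (single band, float32, geometry in the standard
ModelPixelScale/ModelTiepoint tags, nodata in the GDAL nodata tag) or as
ESRI ASCII grids, which keep every test fixture in plain text.  Grids
must already agree in shape, transform and nodata mask; the package
deliberately has no resampling or reprojection engine, so a mismatch is
an error rather than a silent alignment.

## Occurrence preprocessing

Exact-coordinate duplicates are removed (first record kept, order
otherwise preserved) so repeated database entries do not weight the
envelope.  Records on nodata cells or outside the grid are dropped with a
warning.  The cleaned set is partitioned at random into 75% training and
25% test records (`round(0.75·n)` training, at least one record on each
side); the split is random with a logged seed, since nothing about the
sampling design argues for stratification.

## Collinearity pre-filter

Pairwise Pearson correlations are computed over 10,000 random non-nodata
cells (without replacement when the grid has that many; with replacement
otherwise).  For every pair with |r| ≥ 0.8 the later-listed layer is
dropped, so the retained set depends deterministically on the
user-supplied layer order; zero-variance layers are dropped first.  The
greedy keep-the-earlier rule is documented rather than clever: with four
weakly coupled predictors the outcome matches any reasonable variant.

## Bioclim envelope

The envelope model stores, per variable, the sorted training extractions.
The marginal score is the percentile distance s = 2·min(F, 1−F) clipped
to [0, 1], using the midpoint ECDF F(x) = (#{v < x} + ½·#{v = x})/n, with
s = 0 outside the training min–max.  This is the dominant modern
convention for envelope scoring: it is bounded, peaks (s = 1) at the
median, falls linearly in rank toward the envelope edge, and reduces to
the classic min–max box at threshold 0.  Cells aggregate by the minimum
across variables, the standard weakest-link rule, so the overall score
never exceeds any marginal.  No percentile trimming is applied by
default; `trim_percentile` optionally clips the envelope to a central
band (e.g. 5–95%).  A variable whose training sample is constant
degenerates to a point envelope: score 1 at that value, 0 elsewhere, with
a warning.

Response curves evaluate the marginal score on a grid spanning the
envelope ±10% of its span, with the training values and median added to
the evaluation grid so the breakpoints and the unit peak are represented
exactly.

## Partial ROC

Sensitivity (1 − omission of test occurrences) and the proportion of the
valid landscape predicted present are computed at each threshold of the
suitability grid (its unique values, thinned to at most 200 quantile
steps).  Restricted to the domain where sensitivity ≥ 1 − E, the model's
trapezoidal area over the (area, sensitivity) curve is divided by the
area under the 1:1 line — the expectation for a model that ranks cells
randomly — giving the AUC ratio.  Each of 1000 bootstrap iterations
resamples ⌈50%·n_test⌉ test records with replacement; the p-value is the
fraction of iterations with ratio ≤ 1.  Defaults E = 0.05, 50%
resampling, 1000 iterations follow the method's originating convention.
A bootstrap iteration whose restricted domain collapses (fewer than two
curve points reach the required sensitivity — possible when a resample
carries more than a fraction E of zero-suitability records, since the
envelope scores exactly 0 outside its box) contributes a ratio of exactly
1, i.e. counts against the model.  A constant suitability grid returns
ratio 1, p 1 with a warning instead of dividing degenerate areas.

## Enceladus overlay

The published condition intervals are kept in a registry with explicit
units and provenance notes: salinity 5–40 PSU, ascending current velocity
0.01–0.05 m/s, temperature 0–50 °C, dissolved silica 0–2500 µM.  The
temperature entry spans the whole ambient-to-vent gradient because the
water–rock interaction zones must reach ≥50 °C while the bulk ocean sits
near 0 °C; the overlay therefore tests the gradient, and the maximum
suitability attained on the interval reports where along it the envelope
is favourable.  Parts of the literature quote the silica constraint in
µmol/m³ (a factor 10³ away from µM); the registry stores the µM reading,
records the ambiguity in the provenance note, and the overlay refuses any
unit mismatch rather than converting silently.  Verdicts are exact
interval arithmetic: `incompatible` iff the intervals are disjoint,
`compatible` iff the Enceladus interval is contained in the suitable
range, otherwise `partially compatible`.

## Hydrogen budget and growth model

The budget treats H₂ from serpentinization as the limiting substrate:
S_t = (theoretical yield − plume rate × solar-system age) /
(solar-system age × ocean volume).  With the registry defaults
(20 × 10¹⁹ mol, 5 × 10⁹ mol/yr, 4.56 Gyr, 1.70 × 10²² cm³) this gives
plume losses of 2.28 × 10¹⁹ mol, an ocean remainder of 17.72 × 10¹⁹ mol
and S_t = 2.286 × 10⁻¹² mol cm⁻³ yr⁻¹.  Direct recomputation from these
inputs is the value the package reports; the figure of ≈2.31 × 10⁻¹²
sometimes quoted for the same inputs differs by ~1%, consistent with
rounding of intermediates, and is treated as such rather than reproduced.

The Monod system is integrated with LSODA (stiff-capable, adaptive;
relative tolerance 10⁻⁸ by default), with the substrate clamped at zero
inside the right-hand side and a fatal check against drift below zero
beyond tolerance.  The growth equation is used with a positive sign,
dX/dt = +µ(S)·X: the yield relation dX = −Y·dS (consumption decreasing S
while X grows) fixes the intended orientation.  µ_max and K_s have no
measured values for this setting; they default to order-of-magnitude
placeholders for hydrogenotrophic methanogens (0.5 yr⁻¹, 10⁻¹² mol/cm³)
and only structural properties of the ODE are asserted about them — the
headline estimates use the supply-limited linear solution
X(t) = X₀ + Y·S_t·t, which is independent of both.

X₀ = 1 cell/cm³ enters the linear solution in mass units via the cell
mass (2 × 10⁻¹⁴ g).  The `full_ocean` scenario uses S_t as is; the
`hydrothermal` scenario multiplies it by the tiger-stripe area fraction
(0.09), confining harvestable hydrogen to the water column above the
hydrothermally active seafloor.  The published description of this
scenario (9% of the seafloor area with the same ocean thickness) does not
pin down the bookkeeping uniquely; scaling the volumetric supply by the
area fraction is the reading implemented, the fraction is a configurable
budget field, and the alternative reading (1.3 × 10¹¹ m² being already
the stripe area) is accommodated by overriding it.  Trajectories default
to 200 log-spaced times over [10⁶, 3.5 × 10⁹] yr.

## Synthetic data generator

Each environmental layer is an independent white-noise field smoothed by
an isotropic uniform (moving-average) kernel of configurable radius and
min–max rescaled to a realistic range for its variable (temperature −2 to
30 °C, salinity 25–41 PSU, current velocity 0–0.5 m/s, silicate 0–200 µM,
matching the global benthic ranges of the real layers).  Smoothing radius
5 on a 100×100 grid gives strong positive spatial autocorrelation
(Moran's I ≈ 0.9 with rook adjacency), which is what makes the
correlation pre-filter and cell-based sampling meaningful.  An optional
nodata fraction carves a contiguous mask to emulate land.

Occurrences are drawn uniformly from the cells inside a known true
envelope with probability 1 − ε and uniformly from all valid cells with
probability ε, at cell centres, so extraction is exact and the inside
fraction has the closed form 1 − ε(1 − p_in).  The default ground truth
for tests spans the central 25–75% quantile band of each layer, keeping a
workable joint inside-fraction with four variables.  The generator
reproduces the two properties the model exploits — spatial structure and
envelope-concentrated presences — but not real features such as sampling
bias toward coastlines or vents, spatially clustered survey effort,
bathymetry, or cross-correlated predictors; passing tests therefore
validate the algorithms, not the ecological fidelity of any particular
Earth dataset.  `true_suitability` scores cells under the generating
envelope (per-variable triangular score peaking at the envelope optimum,
weakest-link aggregation) and serves as the known-truth reference grid in
evaluation tests.

## Problem sizes and numerical choices

Tests and the reproduction script run at desk scale: 100×100 grids,
hundreds to thousands of synthetic occurrences, 200–1000 bootstrap
iterations, 100 replicates for the null calibration of the partial ROC —
sizes at which every stochastic assertion has comfortable margin (e.g.
envelope recovery at n = 3000 lands ~0.5% from the true limits against a
2% bound).  Determinism is enforced throughout: every stochastic function
takes a seed, and the pipeline derives per-stage seeds from one master
seed via a seed sequence so stages can be re-run in isolation.
Floating-point ties in the ECDF are handled by the midpoint convention;
envelope boundary points score 1/n (not 0) under the clipping rule.

## Known limitations

- The envelope model is intentionally simple: no Maxent/GLM/GAM
  alternatives, no background-point machinery, no spatial thinning beyond
  exact-duplicate removal.
- Published AUC ratios for the three real methanogen genera depend on the
  proprietary-sized GBIF/Bio-ORACLE inputs and are out of scope here; the
  synthetic evaluation shows the statistic behaves correctly (detects an
  informative model, stays calibrated on an uninformative one), not that
  any particular Earth value is reproduced.
- The growth model ignores co-limitation (pH, other nutrients), abiotic
  methanogenesis, and energy-flux arguments; its estimates are upper
  bounds under the hydrogen-only limitation assumption.
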