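# Methods

This note documents the models and procedures `ccm` implements, the
defaults it ships, and the choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Observational grid and occupancy

Feeding locations are snapped to half-open square cells
`[edge, edge + s) × [edge, edge + s)` with floor indexing, `s = 50 m` by
default. Half-open intervals make cell assignment a partition of the
plane (no point belongs to two cells); the grid origin defaults to (0, 0)
of the projected coordinate system and is configurable, since determinism
requires fixing it somewhere. Repeated visits to one (species, cell)
collapse to a single presence that keeps the earliest date and a visit
count. Records without a species identification are excluded from species
presence but still mark their cell as *visited*: visitation is evidence of
space use regardless of whether the item was resolved. The visited-cell
universe is feeding-defined (cells the consumer fed in), matching how the
surveyed area is counted; a travel-inclusive universe would require the
full tracklog and is intentionally not the default.

Size minima (tree ≥ 20 cm DBH, liana ≥ 5 cm, inclusive boundaries)
reflect the smallest stems the consumer treats as a feeding patch; stems
with missing DBH are dropped from size-filtered analyses and counted.

## Kernel home range and percent kernel

The utilization distribution is a product-Gaussian kernel density
estimate of the recorded positions, computed by binning points on the
evaluation raster (25 m, half an observational cell, so cell-center
lookup is well posed) and convolving with a Gaussian. The raster extends
five bandwidths past the data bounding box, so truncated kernel mass is
negligible, and the surface is renormalized to unit mass. The default
bandwidth is the two-dimensional reference rule, mean per-axis SD times
n^(−1/6); any fixed bandwidth can be passed instead. Binned evaluation is
numerically equivalent to the direct kernel sum whenever the bandwidth
spans several pixels — always the case for home ranges smoothed at tens
to hundreds of meters — and is orders of magnitude faster.

The *percent kernel* of a location is 100 × the total mass of all pixels
at least as dense as the location's (bilinearly interpolated) density:
the level of the smallest isopleth containing it. Small values are core,
100 is far periphery; locations outside the raster are assigned 100 with
a warning. Cells take the percent of their center, plots of their
centroid. Isopleth cell sets `{cell : percent ≤ p}` are nested in p by
construction, and a greedy-by-density cell set is the smallest set
holding at least p% of mass. On an analytic bivariate Gaussian surface
the implementation reproduces the closed form
`percent(r) = 100(1 − exp(−r²/2))` at Mahalanobis radius r to within
~0.3 percentage points at 25 m resolution (the acceptance script
recomputes this).

## Indices, ranks, and responses

The CCM Index divides a species' presence cells inside the p% isopleth by
all cells inside it; Plot Density and Plot Presence are classical
fixed-area estimates over 50 × 50 m plots (0.25 ha each). Consumption
rank orders species by distinct presence cells, ties broken
lexicographically so ranking is deterministic; top-k diet subsets use
ranks from the full dataset, not per-window recomputation.

Accumulation curves count cumulative unique (species, cell) presences
against a 1-based day index; *accumulation speed* is the first day the
curve reaches 90% of its final value (threshold configurable — the
notion of "speed" has no canonical cutoff, so the default is explicit).
The *density difference* response z-scores log CCM Index and log Plot
Density across species and subtracts them (positive = CCM overestimates
relative to plots); species with a zero in either index drop out of the
logs. DBH selectivity is a Welch two-sample t on raw DBH, signed fed
minus plot. Miss rates map plot detections and CCM presences onto a
coarse grid and report, per species, the share of plot-detected cells
with no CCM presence — restricted by default to cells the consumer
visited at all, since an unvisited cell cannot logically contain a CCM
presence (a switch lifts the restriction).

## Agreement engine

All cross-method correlations are Pearson's r on log-transformed index
values, pairwise-complete after dropping zeros (a zero index carries no
log-scale information). p-values are computed and reported but never used
to filter: the sweep evaluates thousands of non-independent correlations,
so inference rests on the coefficients. A comparison is emitted only when
it rests on ≥ 10 species with plot presence and ≥ 10 plots in scope;
failing grid points are omitted, not zero-filled.

The sweep recomputes the CCM Index denominator at every isopleth level
20–95% (1% steps) and restricts plots to centroids inside the isopleth
(the stricter of the two readings of "plots within the home range").
The moving window slides a percent band across 20–95%, growing its
half-width in 1% steps until ≥ 20 plots and ≥ 200 observational cells
fall inside — 200 cells ≈ 20 plots by covered area (both 5 ha) — and
recomputes all indices inside the band only; unsatisfiable centers are
flagged rather than dropped. Temporal stability recomputes the CCM Index
on day-prefixes (default stride 30 days) against the fixed full plot
estimates and reports the first evaluation day after which r stays within
ε = 0.05 of its final value.

## Dispersion

Both data streams are aggregated onto 500/1000/1500 m grids sharing the
50 m origin, so observational cells nest exactly. The consumer stream
counts distinct 50 m feeding locations per species per cell (individuals
cannot be distinguished below cell scale, so a location stands in for an
individual); the plot stream takes mean stems per plot within each cell,
excluding cells with no plots, so uneven plot sampling does not inflate
counts. Morisita's Id uses the standard quadrat formula; the Smith-Gill
standardized variant (rescaled to [−1, 1] against chi-square bounds) is
available as `variant="standardized"`, and one test cross-checks both
against R's `vegan::dispindmorisita`. Because Id is heavy-tailed across
species, the cross-method comparison reports raw-Pearson, log-Pearson,
and rank (Spearman) correlations side by side rather than committing to
a single normalizing transform; rank is the recommended default.

## Distribution models

Per species, aggregation cells carrying plot data become datapoints:
response = consumer count, test predictor = plot-mean abundance, control
= mean percent kernel of the cell's plots (the consumer samples its core
harder than its periphery, which would otherwise masquerade as a
distribution signal). At 500 m counts are sparse and zero-heavy, so a
zero-inflated Poisson is fitted — count part log-linear in the
predictors, zero part an intercept-only logit, the simplest identifiable
choice since nothing constrains the zero model's covariates — via maximum
likelihood (statsmodels) with moment-based starting values (π₀ from
excess zeros, λ₀ from the mean). At 1000/1500 m ordinary least squares
suffices. Goodness of fit is Nagelkerke's pseudo-R² for count models,
classical r² for linear ones.

Significance of the plot-abundance slope is assessed at two-sided
p < .05 by a likelihood-ratio test in the ZIP models: Wald p-values in
zero-heavy samples of ~100 cells are mildly anti-conservative (simulation
puts them near 5.5–6% rather than 5%), while the LR test is calibrated.
No multiplicity correction is applied, and the 5% chance baseline is
always printed next to the share of significant species, with both the
fitted-species and full-species denominators.

Presence/absence agreement is modelled per species as a fixed-effects
logistic regression — CCM presence on plot presence and percent kernel —
with slopes pooled across species by inverse variance. This is a declared
simplification of a crossed-random-effects binomial mixed model (cell ×
species); every summary carries a note saying so. Species with complete
separation or a single outcome class are flagged and excluded from
pooling.

## Synthetic ecosystem

The generator's defaults are the study conditions the rest of the package
is validated under, not tuning knobs:

- **Landscape**: 8 × 8 km window; home range a 2-D Gaussian with 1260 m
  per-axis SD, giving a ~30 km² 95% isopleth.
- **Forager**: 9.5 feeding locations/day (Poisson; a negative-binomial
  day count is exposed as an extension point), isotropic GPS error of
  8.75 m per axis so the typical error *between two recorded points* is
  ~15–20 m, size minima 20/5 cm, and visit probability ∝ preference ×
  UD(stem)^core_bias with neutral preference and core_bias = 1 as the
  baseline. The forager is a marked point sampler, not a movement model:
  none of the downstream analyses use within-day path geometry, so the
  tracklog is the visit sequence.
- **Community**: 25 species, log-spaced true densities 15–400 stems/km²
  (a strongly skewed stem table, as tropical forests have), about half
  clumped (Thomas process: Poisson parents, mean 8 offspring, 60 m
  cluster SD, parent intensity derived so expected density is exact) and
  the rest complete spatial randomness; ~30% lianas. DBH is lognormal
  with per-species parameters, and every fourth species is small-statured
  with median DBH near its consumption minimum — mirroring the field
  observation that for roughly a quarter of consumed species, plots hold
  more sub-minimum individuals than qualifying ones. This is what gives
  size-minima filtering of plot data its measurable effect.
- **Plot survey**: 4 plots per 1 km² cell (the field design averaged
  ~4.1), placed without replacement on the cell's 50 m subgrid —
  guaranteeing non-overlap and exact alignment with observational cells —
  and inventorying exactly the stems inside each footprint, unfiltered
  (analyses apply their own minima).

Everything is deterministic under (config, seed); child seeds are spawned
per stage. What the simulator does *not* emulate: phenology and seasonal
fruiting dynamics (a per-species day-of-year consumption window exists,
but fruit abundance does not vary), stem mortality/recruitment, consumer
memory or route planning, and observer effort gaps. Passing recovery
tests therefore show that the pipeline's estimators are consistent under
the stated sampling model — not that real feeding data are free of the
behavioral biases the agreement analyses exist to measure.

## Numerical and scale choices

Tests and the acceptance script scale the simulations to run comfortably
on a single CPU: the shared test scenario uses 20 species over 250 days
on a 4 × 4 km landscape, the end-to-end acceptance experiment the full
default conditions (25 species, 600 days, 8 × 8 km, ~5,800 records), the
Morisita calibration 1,000 Poisson replicates over 200 units, ZIP
recovery n = 5,000, and the permutation null 500 replicates of 120 cells
(a 30 km² home range on the 500 m grid). ZIP convergence is BFGS with
moment starts; an all-zero response is rejected as non-identifiable, and
a fit whose gradient has not converged is flagged rather than dropped.
Correlations require ≥ 3 pairwise-complete species and flag constant
input as undefined rather than raising. Degenerate KDE inputs (all points
identical) require an explicit bandwidth.

## Known limitations

Plot percent-kernel assignment uses the plot centroid, not the plot-area
integral; at 50 m plots against ≥ 100 m smoothing the difference is
negligible. The coarse-grid aggregation of a 50 m cell uses its center,
exact only for aligned multiples of 50 m (a warning covers the rest).
The pooled logistic presence model understates between-species
heterogeneity relative to a crossed mixed model; its pooled coefficients
should be read as precision-weighted averages, not population effects.
CRS handling is a label: all coordinates must arrive in one projected
metric system.
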