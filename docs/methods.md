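# Methods

This note documents the models the package implements, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. It is written for a user deciding
whether the machinery fits their data, and for a maintainer wondering
why a particular choice was made.

## Study calendar and inclusion rules

Three biological periods tied to white-tailed deer fawn availability
partition the season: preparturition (PPP, May 1–26), fawn limited
mobility (LMP, May 27–June 30) and fawn social mobility (SMP, July
1–August 31). Assignment is by month-day, inclusive on both ends,
ignoring the year and any time-zone structure (collar timestamps are
taken as local study time). Dates outside May 1–August 31 belong to no
period.

Deer are included per period only with enough relocations — at least 20
VHF fixes for adults, at least 5 for fawns; the lower fawn bar avoids
biasing the population RUF toward fawns that survived long enough to
accumulate 20 fixes. Wolves and coyotes are never count-filtered: their
inclusion reflects collar data recovery, not fix counts.

## Brownian bridge movement models

### Motion variance

Between consecutive fixes the animal's path is modeled as a Brownian
bridge with diffusion rate σ²ₘ (m²/min — the time unit is minutes
throughout). σ²ₘ is estimated by maximizing the leave-one-out
likelihood: each interior fix zᵢ is predicted from its neighbours,

    zᵢ ~ N( zᵢ₋₁ + a (zᵢ₊₁ − zᵢ₋₁),  s·I₂ ),
    a = (tᵢ − tᵢ₋₁) / (tᵢ₊₁ − tᵢ₋₁),    T = tᵢ₊₁ − tᵢ₋₁,
    s = T·a(1−a)·σ²ₘ + (1−a)²δ²ᵢ₋₁ + a²δ²ᵢ₊₁ + δ²ᵢ,

where δ are per-fix location-error SDs. The final δ²ᵢ term — the tested
fix's own observation error — is included deliberately: without it the
estimator absorbs location error into σ²ₘ, which matters exactly in the
regime collar data occupy (bridge SD comparable to GPS error; at 15-min
fixes with 5 m error the classic endpoint-only form overestimates a
true σ²ₘ of 2.0 m²/min by ~165%). Optimization is bounded Brent on
log σ²ₘ over [10⁻⁶, 10³] m²/min, with a coarse-scan guard against local
optima in the top-level fit.

Triples whose span T exceeds a maximum lag are skipped; for VHF deer
data the lag is 48 h, so only temporally related relocations inform the
estimate. Sampling error of the MLE is irreducibly ~√(2/(2m)) relative
(m = number of triples), i.e. ±20–30% for a 21-triple window — relevant
to interpreting the dynamic profiles below.

### Dynamic variant (change points)

A window of 23 fixes (5.75 h at 15-min fixes) slides one fix at a time.
Within each window a no-break model competes against single-break
models at every interior fix at least 5 fixes (the margin) from either
edge. Model choice is by BIC on the window's leave-one-out likelihood,
with two choices worth recording:

- the triple centred on the candidate break fix is assigned to the
  left-hand model so both models sum the likelihood over the *same*
  triples — otherwise the split model wins spuriously by simply
  dropping a data point;
- the break model's penalty is 3·ln m + 2·ln c (two variances plus the
  break position, plus a multiplicity correction for selecting the best
  of c candidate positions). Without the 2·ln c term about 10% of
  windows on a constant-σ track sprout spurious breaks; with it, under
  0.5% do.

Each inter-fix segment's final σ²ₘ is the mean of the estimates from
all windows covering it. Tracks shorter than one window fall back to
the static fit with a warning. Because per-window estimates carry the
sampling noise noted above, a "flat" profile on a constant-σ track is
flat in its mean and median (within a few percent of the static fit),
not cell-by-cell.

### Occurrence distributions

For each retained segment the bridge density — Gaussian with mean
moving linearly between the endpoint fixes and variance
T·a(1−a)·σ²ₘ + ((1−a)δ₀)² + (aδ₁)² at fractional time a — is integrated
over the segment with a midpoint rule in 10 equal time steps
(configurable; against a 10⁵-step quadrature the default agrees to
better than 3 significant figures on a stationary bridge), weighted by
segment duration, evaluated at cell centers, truncated at 5 SDs, and
normalized to sum to 1 over the grid.

Activity-specific ODs retain a segment only when *both* endpoint fixes
carry the requested state; mixed segments are dropped, and fixes with
no accelerometer interval within one fix interval are labelled unknown
and excluded from both states. The 99% contour is the smallest set of
cells (ranked by height, ties at the threshold all included) whose
summed height reaches the level; it defines the available area for the
regression stage. When no grid is supplied, the grid is the track's
bounding box buffered by 3× the 99th-percentile mid-bridge SD.

## Resource utilization functions

Individual RUFs are ordinary least squares of OD height on covariates
over the in-contour cells. Continuous covariates are z-scored over the
used cells of that individual, so standardized slopes are comparable
across individuals before averaging; land cover is dummy-coded against
a deciduous-forest reference (the most common class), with collinear or
absent-class dummies dropped. Plain OLS is used rather than a
spatially-correlated-error fit: population-level inference below
consumes only the between-individual spread of coefficients, not the
cell-level standard errors, so modeling within-individual spatial
autocorrelation would not change the reported intervals. OD heights
enter untransformed.

Covariate screening precedes fitting: Pearson |r| > 0.7 between two
continuous covariates (over the cells actually used) drops the one
lower in a configured ecological-priority order; |r| = 0.7 exactly is
not a conflict. A conflict involving a covariate absent from the
priority list is a configuration error rather than a silent choice.

Population-level coefficients treat individuals as random draws:

    β̄ᵢ = (1/n) Σⱼ β̂ᵢⱼ,      Var(β̄ᵢ) = 1/(n−1) Σⱼ (β̂ᵢⱼ − β̄ᵢ)²,

with t-based CIs and p-values on n−1 df at α = 0.05. This conservative
variance carries both intra- and inter-individual variation. A
covariate absent from one individual's design (a land-cover class
missing from its range) contributes 0 for that individual.

Prediction surfaces use the unstandardized population means, min-max
rescaled to [0, 1] as relative use. Pipeline ordering is enforced:
coyote models require the wolf prediction surface (the avoidance
covariate) and abort if none was fit — the surface used is the wolf
*active-state* population prediction for the matching period, active
use being the relevant encounter risk; deer surfaces are fit per period
and replace the prey-occurrence rasters for that period's canid models.

### Cross-validation

Leave-one-individual-out: refit the population RUF without one animal,
predict the landscape, pair predictions with the withheld OD's heights
over its in-contour cells, sort by prediction, split into 8 bins of
equal cell counts (remainder cells to the last bin), regress summed OD
on summed prediction across bins, and average slope and R² over folds.
Bins are unweighted. One numerical caveat is worth knowing: the
remainder rule gives the top bin extra cells whenever the cell count is
not divisible by 8, which adds a small positive slope bias; validation
experiments in this package therefore use cell counts divisible by the
bin count.

## Activity analysis

An individual is active in a 5-min interval when the collar's summed
acceleration is ≥ 30.7 (unitless; the boundary itself is active), a
threshold from field calibration of these collars. Time-active
proportions are compared between species by a one-tailed Welch t test
on per-individual proportions (the subordinate species predicted less
active).

Daily activity densities are von Mises kernel estimates on the 24 h
circle over the start times of active intervals, pooled across
individuals within species with equal weight per interval (clock time,
not solar time). The kernel concentration follows the rule-of-thumb
plug-in ν = [3n κ̂² I₂(2κ̂) / (4√π I₁(κ̂)²)]^{2/5} with κ̂ the ML von
Mises concentration of the sample, times an adjustable multiplier
(default 1). Densities are evaluated on a 512-point grid; the
coefficient of overlapping Δ = ∫ min(f̂₁, f̂₂) is computed by
trapezoidal quadrature closed around the circle. Δ is exactly
symmetric, rotation invariant, and agrees with a 10⁶-point numeric
oracle to 3 decimals on von Mises test cases. No bootstrap CI on Δ is
provided (point estimates only).

## Diet analysis

Scats with confirmed tracks take that species regardless of diameter.
Otherwise diameter decides: ≤ 28.1 mm coyote, ≥ 29.0 mm wolf, strictly
between excluded as ambiguous (the band where the two species' diameter
distributions overlap). Diet proportions pᵢ are means over scats of
per-scat volume fractions — each scat one vote, matching how per-item
percent means are reported — with a pooled (volume-weighted)
alternative behind a flag. Breadth B = 1/Σpᵢ² ranges from 1 to the item
count; overlap is Pianka's α = Σpᵢqᵢ/√(Σpᵢ²·Σqᵢ²), which is bounded in
[0, 1] and symmetric (the radical is essential for both properties).
Per-item volumes are compared between species by one-way ANOVA on
per-scat fractions. The item taxonomy is fixed at seven classes
(adult deer, fawn, hare, grouse, rodent, seeds, other); "other" absorbs
unknowns.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, with known truth for recovery tests. Defaults are chosen once
to emulate the motivating field system:

- **Landscape**: seven-class land cover as smoothed random patches
  (argmax of per-class smooth Gaussian fields shifted by log class
  weight; default weights approximate a northern forest mosaic), random
  road/stream polylines with exact Euclidean distance layers, exact
  rook-adjacency patch sizes, distance-to-edge from a Euclidean
  distance transform, and smooth positive prey fields.
- **Movement**: a two-state walk on a 5-min lattice. State is Bernoulli
  from a crepuscular schedule (two von Mises bumps at dawn 05:30 and
  dusk 20:30, concentration 3, baseline activity 0.10, peak 0.90 —
  giving overall time-active near the 0.2–0.5 range of collared
  canids). Motion variance is 150 m²/min active and 8 m²/min inactive,
  i.e. canid-scale travel of roughly 5–10 km/day; GPS error 10 m, VHF
  triangulation error 50 m. Optional biases: pull toward a polyline
  (road-seeking deer) and Langevin drift (σ²Δt/2)·∇P on a log-preference
  surface P, whose stationary density is ∝ exp(P) — a log-linear
  resource preference with known coefficients, giving the RUF stage a
  recoverable signal.
- **Accelerometer**: active intervals draw threshold + Gamma(2, 15),
  inactive threshold × Beta(2, 4), so thresholding recovers the true
  states exactly — classification is validated separately from
  movement.
- **Scats**: per-scat compositions are Dirichlet with mean equal to the
  species/period diet vector and concentration 10 (per-scat variability
  is not reported in field studies; 10 gives realistic single-prey-
  dominated scats). Diameters are Normal(25.2, 4.4) mm for coyotes and
  Normal(33.3, 6.1) mm for wolves, matching track-confirmed field
  calibration; by default 20% of scats carry confirmed tracks. Diet
  vectors differ by species and period (no fawn mass in PPP, wolf diets
  deer-concentrated, coyote diets spread over smaller prey), placing
  breadth near B ≈ 3.1–3.9 (wolf) and 3.6–5.0 (coyote) and overlap
  α ≈ 0.85–0.99.

All generators are pure functions of (scenario, seed). What the
generator does **not** emulate: territoriality or interaction between
individuals (no avoidance of simulated wolves by simulated coyotes —
the wolf-surface covariate in synthetic runs therefore tests plumbing,
not a behavioural effect), habitat-dependent activity schedules,
fix-loss/habitat-bias in GPS acquisition, collar failure, seasonal
drift in diet within a period, and misidentified prey items. Passing
tests show the estimators recover known structure of this generative
family; they do not certify behaviour under field pathologies outside
it.

## Problem sizes

Validation experiments run at sizes chosen to make sampling noise small
relative to the tolerances while keeping the whole suite quick on one
core: 500–600-fix tracks for variance recovery and change-point
location, 48×48-cell landscapes (2304 cells, divisible by the 8 CV
bins), 5,000 scats for composition recovery, 200 simulated populations
of 10 individuals for CI coverage, and a full pipeline study of three
wolves, three coyotes and nine deer at 288 fixes per period. The
acceptance script reruns all of these from a single seed.

## Known limitations

- The RUF stage is plain OLS; spatial autocorrelation of OD heights is
  not modeled (a correlated-error fit can be slotted behind the same
  interface).
- Segment state assignment drops mixed active/inactive segments rather
  than splitting them at the (unknown) transition time.
- The dBBMM window combiner averages overlapping-window estimates,
  which smooths genuine sharp transitions over ~one window width; the
  change-point location itself is recovered to within the margin.
- Circular densities pool individuals with equal weight per interval;
  individuals with more active intervals contribute more.
- Period boundaries are calendar-fixed, not estimated from fawn
  phenology.
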