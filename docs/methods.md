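# Methods

This note records the models implemented in `bathytherm`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic study
system does and does not emulate.

## Coordinate system

All planar work uses an oblique Mercator projection centred on 35.0°N,
75.0°W, realised as Mercator on a rotated sphere (mean radius 6371.0088 km)
so the centre maps to the origin. Local scale error is below 0.1% over the
shelf study region and the forward/inverse round-trip is accurate to well
under a metre. A spherical rather than spheroidal earth is used throughout
(distances via haversine); at 10-km grid resolution the spheroidal
correction is negligible. Points within 1° of the rotated poles are
rejected explicitly.

## Track processing

**Speed filter.** Fixes implying a speed above 5 km/h (great-circle
distance over raw lon/lat divided by elapsed time) are removed before any
model fitting, by iterative worst-offender deletion: while violations
remain, the single fix whose removal most reduces the number of violating
pairs is deleted, ties broken by the larger implied speed against its
neighbours, then by the later fix. The result never violates the bound and
the filter is idempotent. On small tracks with well-separated planted
jumps this greedy rule matches the brute-force maximum-retention subset.

**CTCRW.** The movement model is the integrated Ornstein–Uhlenbeck
velocity process per axis: `dv = −β v dt + σ dW`, position integrating
velocity, with three parameters shared across axes — reversion rate β
(1/h), diffusion σ (m·h^−3/2; stationary velocity sd is σ/√(2β)), and an
isotropic Gaussian observation error sd τ (m). The likelihood is evaluated
by a Kalman filter using the exact closed-form transition over each
irregular gap; it matches a dense joint-Gaussian evaluation to better than
1e−8 on short tracks. The prior at the first fix is position ~ N(first
observation, (10 km)²), velocity ~ N(0, stationary variance); because the
prior mean equals the first observation the first innovation is zero, so
the prior acts as near-diffuse while preserving floating-point precision.
One τ is estimated per track (no per-tag error classes; the data model
leaves room to add them).

Fitting maximises the likelihood over log-parameters with L-BFGS-B and a
deterministic multi-start schedule; standard errors come from a
finite-difference Hessian at the optimum. On a 2,000-fix simulated track
all three parameters are recovered within three standard errors, and
95% Wald intervals cover the truth at nominal rate over 50 replicate
tracks.

**Daily interpolation** evaluates the RTS smoother at daily midnights
(UTC) spanning the track — midnight is a convention; nothing downstream
depends on the time of day. Position uncertainty grows inside transmission
gaps and shrinks near fixes.

## Gridding and the occurrence table

Daily positions are binned onto the uniform 10-km lattice with half-open
cell intervals (a position on a shared edge belongs to exactly one cell)
and by calendar month. The study region is continental-shelf water:
depth strictly less than 200 m, latitude between 33.5 and 41.6°N.

The occurrence table has one row per shelf cell per study month. A cell ×
month is a presence (y = 1) if at least one daily position of any animal
fell in it, regardless of how many — the model is Bernoulli, not
count-valued. **Every other shelf cell × month is an absence.** This
"pseudo-absence by omission" convention is the only reading consistent
with a Bernoulli model over the full grid, but it deserves emphasis: an
absence means *no tagged animal was estimated there*, not that the species
was absent, and no tagging-effort correction is applied.

Monthly SST is matched to occurrences as the per-cell monthly mean field
(a climatology, to match the monthly resolution of the projections), not
daily SST at fix time. Coarse SST rasters are up-sampled to the grid by
unweighted averaging of the coarse pixel centres falling in each cell,
with nearest-pixel fallback for cells containing none; regridding is
linear, so it commutes with adding anomaly fields. Depth is positive-down
and constant in time. In the synthetic scenario there is no interannual
variability, so the per-calendar-month climatology over a single year is
the study-period climatology.

## Habitat model

A Bernoulli GLM with logit link on (SST, SST², Depth, Depth²) in natural
units (°C, m). Fitting is Newton/IRLS with step-halving (the
log-likelihood never decreases) on internally standardised covariates for
conditioning, back-transformed exactly afterwards; convergence requires
the score norm below 1e−6 and a positive-definite negative Hessian, and
non-convergence (e.g. separation) is flagged, not silently accepted.
Coefficients agree with an independent IRLS implementation to 1e−6 and
are invariant to affine covariate rescaling.

Model selection is forward stepwise from the intercept: at each step the
admissible candidate (quadratic terms require their linear parent) with
the lowest AIC enters, provided it both lowers AIC and raises the percent
deviance explained, `100·(1 − residual/null deviance)`. The full trace is
recorded.

Diagnostics use Dunn–Smyth randomized quantile residuals. A caution
established while testing: for binary outcomes the *marginal* distribution
of these residuals is uniform for any marginally calibrated fit, so a
marginal normality test has essentially no power against omitted
covariates; misspecification must be sought in residual-vs-covariate
structure (the test suite checks the association of residuals with the
omitted covariate's curvature). No spatial or temporal autocorrelation
correction is applied beyond daily interpolation — a known limitation
shared with the modelling tradition this follows.

## Classification

ROC candidate thresholds are the unique observed scores (prediction
positive iff score ≥ threshold); Se and Sp are exact count ratios and AUC
is the trapezoid over the full curve, which equals the tie-corrected
Mann–Whitney statistic to 1e−12. The cut-point minimises
`IU(c) = |Se − AUC| + |Sp − AUC|` by exhaustive scan, ties broken by
smaller |Se − Sp| and then the smaller threshold (the second tie-break is
arbitrary but deterministic).

The core-habitat envelope is the covariate region with `p ≥ c`, evaluated
on a fine (default 701 × 501) SST × depth grid; for the concave quadratic
surface this region is an ellipse-like set, so each bounding interval is
attained at the other covariate's optimum and matches the closed-form
quadratic roots. The top-quartile rule flags cells at or above the 75th
percentile (linear-interpolation quantile) of unmasked values; it is a
rank property, invariant to monotone transforms. Note that in a
low-prevalence scenario the 75th percentile of predicted values can fall
*below* the IU cut-point, making the "top-quartile" covariate envelope
wider than the core envelope; both are reported without adjustment.

## Projection

The delta method adds monthly SST anomalies to the observed climatology;
depth is unchanged. A year with zero anomalies reproduces the fitted-era
probabilities bit-for-bit. Seasons are Jan–Mar (winter), Apr–Jun (spring),
Jul–Sep (summer), Oct–Dec (fall); year-bins are 10 or 20 years wide with
bin 0 denoting the observed era. The occupied fraction classifies the
seasonal-bin *mean probability* field at c and takes the share of shelf
cells classified occupied (`mean-then-classify`); the alternative
(`classify-then-mean`, averaging monthly occupancy) is available behind a
flag. Binning averages predictions rather than re-predicting from
bin-averaged anomalies; with anomalies linear in time the two differ only
through the response curvature within a bin, which is small at decadal
width.

## The synthetic study system

The generator emulates what the pipeline is sensitive to, with defaults
fixed once as the study conditions:

- **Grid**: 10-km lattice over 76–69.5°W, 33–42.2°N, bounded west by a
  parametric coastline.
- **Bathymetry**: linear offshore ramp to 300 m with 5 m noise; ramp width
  grows northward from 100 to ~500 km, emulating the first-order geometry
  of this margin — a narrow southern shelf broadening several-fold into
  the wide northern banks. This geometry matters: it is why habitat gained
  in the north outweighs habitat lost in the south under warming.
- **SST climatology**: 19 °C annual mean at 33.5°N falling 0.9 °C per
  degree of latitude, a 7 °C annual harmonic peaking in August (the
  observed amplitude runs ~6 °C south to ~7.5 °C north; a single harmonic
  cannot follow the sharp winter front at the shelf's southern edge, so
  the synthetic winter shelf is uniformly below the habitat envelope),
  plus 0.3 °C noise.
- **Warming deltas**: linear growth to a 3 °C spatial-mean anomaly at year
  80, with the north end warming about twice as fast as the south
  (normalised so the end-year spatial mean is exactly 3 °C); anomalies are
  season-independent.
- **Truth surface**: optimum 21.5 °C / 50 m, curvatures 0.05 (°C⁻²) and
  0.002 (m⁻²), peak logit 0.5 — giving a realistic thermal envelope
  (p ≥ 0.08 between roughly 14–29 °C and 12–88 m) and ~6% prevalence.
- **Tracks**: CTCRW with β = 0.3/h, σ = 1500 m·h^−3/2 (stationary per-axis
  speed sd ~1.9 km/h, a plausible foraging pace), τ = 500 m; shifted-
  exponential transmission gaps (mean 2 h, minimum 0.5 h — tags are
  duty-cycled, and without the floor observation noise alone implies
  filter-tripping speeds over back-to-back fixes); 2% of interior fixes
  displaced far enough to violate the speed bound against both neighbours.

What it does **not** emulate: Argos location-class error structure,
behavioural switching or habitat-seeking movement, interannual SST
variability, the Gulf Stream winter front, currents/tides, and real
coastline geometry. Because simulated movement is habitat-blind, the
pipeline's default occurrence table is drawn directly from the truth
surface (`occurrence_source="truth"`), which is what lets model recovery
be checked against known coefficients; `occurrence_source="tracks"`
exercises the full track→table path instead, but its presences carry no
planted habitat signal. Passing tests therefore demonstrate correctness of
the machinery under the stated generative model, not ecological validity
on real tags.

## Problem sizes and determinism

Default pipeline scale: a 60 × 103 cell grid (~1,750 shelf cells), 12
animals × 120 days of tracks, a 21,000-row occurrence table, and a full
80-year × 12-month projection; the complete run takes well under a minute
on one core, and the test suite uses reduced variants of the same system.
Every stochastic stage takes an explicit seed; the pipeline spawns
per-stage seeds from the config seed, stamps outputs with the config hash,
and identical configs produce byte-identical outputs.

## Known limitations

- Pseudo-absence construction and no effort correction (above).
- One observation-error parameter per track; no tag-type distinction.
- The IU cut-point is computed on all cell × month rows, unbalanced
  classes included; no cross-validation of the threshold.
- The quadratic surface forces symmetric responses about the optimum;
  real thermal tolerance may be skewed.
- Projections condition on a fixed fitted model: no prey, no behavioural
  adaptation, no bathymetry or circulation change.
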