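# Methods

This note documents the models, conventions, and numerical choices behind
`farmvisits`. The package reimplements, as a tested pipeline, a movement-
ecology analysis of how GPS-tagged scavengers (territorial and
non-territorial vultures on a semi-arid island) use livestock farms as food
sources, and pairs it with a synthetic generator whose ground truth makes
every stage verifiable.

## Spatial units: farm areas

Farms enter the registry as points with per-semester herd counts. The
analysis unit is the *farm area*: around each farm a disk of radius
`r = 180 m` is drawn (the radius within which dumped carcasses plausibly
belong to the farm), and overlapping disks are merged transitively. Two
farms merge exactly when their points are strictly closer than `2r`;
equality does not merge, consistent with the strictly-less-than visit
thresholds. The resulting partition is the set of connected components of
the proximity graph and is independent of input order. Disks are rendered
as 64-segment polygons (sub-metre error at 180 m, far below any
covariate's sensitivity). A merged area's herd is the sum over members; its
carcass value is the maximum over members (any member abandoning carcasses
makes the area a potential food source). All covariate distances are
measured from the centroid of the merged polygon — the polygon, not the
mean of member points, is the defined object.

Coordinates are planar metric throughout (projected, UTM-like). Geographic
input is out of scope for the core; conversion belongs to I/O tooling.

## Visit detection

A GPS fix is a visit to a farm area when all three criteria hold:

* the fix lies inside the area polygon (boundary counts as inside; farm
  areas are disjoint by construction, so containment is unique);
* altitude above ground `< 25 m`, where ground elevation comes from
  bilinear interpolation of the DEM at the fix coordinate;
* instantaneous speed `< 2 m/s`.

Both thresholds are strict. Qualifying fixes collapse to one *visit day*
per (bird, farm area, UTC calendar date). Fixes outside the DEM extent are
excluded and counted. The detector is a pure function of the fix set: fix
order never changes the visit-day set, and raising either threshold can
only add visit days.

Tracking eligibility: a day counts as "with data" when the bird has at
least one fix that date; a bird-semester enters the analyses only when
*every* month of the semester has at least 15 data days. The binomial
denominator for individual-level models is the total number of data days
in the semester.

## Home ranges

Per bird-semester, the utilization distribution is a fixed-bandwidth
bivariate Gaussian kernel density (one isotropic kernel of SD `h = 750 m`
per fix) on a grid of 100 m cells padded 4h beyond the fix bounding box.
The smoothing factor is interpreted as the kernel SD in metres, the
convention of the standard kernel-home-range implementations. The density
is built by binning fixes and convolving with the Gaussian kernel
(`truncate = 8` SDs, discarded tail mass < 1e-14), then normalized to unit
volume.

Isopleths are smallest-area regions: cells sorted by density descending
and accumulated until the target volume (95% = home range, 50% = core
area) is reached; the area is the cell count times the cell area, and the
cell set is traced into polygons by an exact coverage union of
grid-aligned squares. For a single fix the isopleth is a disk of radius
`h * sqrt(-2 ln(1 - p))` — 1835.8 m (10.59 km²) at 95% and 882.9 m at 50%
for h = 750 — which the implementation reproduces within one cell ring at
100 m cells; halving the cell size changes areas by < 2%.

A farm area is a *candidate* food source for a bird-semester when its
centroid lies inside the 95% polygon (consistent with the centroid
convention of every other covariate). No coastline clipping is applied;
synthetic extents have no coastline.

## Carcass-abandonment model

Interviewed farms answer whether they abandon carcasses (1/0). A
binomial-logit GLM of that answer on five predictors (distances to the
garbage dump, the nearest artificial feeding station, the nearest road,
the nearest urban area, and herd size) is selected by AICc over all
predictor subsets, excluding subsets that contain a pair with
|Spearman rho| > 0.5 and discarding models with uninformative parameters
(below). Predictors are z-scored within the fitting set; scaling constants
are stored so prediction accepts raw units; AICc is invariant to this
reparameterization (checked to 1e-6). Fit quality is summarized by the
adjusted explained deviance

    D²_adj = 1 − (1 − (1 − D/D₀)) · (n − 1)/(n − k),

with D the residual and D₀ the null deviance. The selected model imputes
an abandonment probability for uninterviewed farms; interviewed farms
always keep their hard 0/1 answer, so the carcass covariate mixes 0/1 and
probabilities in one column, exactly as used downstream.

## Binomial mixed models (Laplace)

Responses are binomial proportions with a logit link:

* FARM — distinct eligible birds visiting each active farm area per
  semester, over eligible birds that semester; random intercepts for farm
  area and semester.
* VULTURE — visit days per eligible bird-semester and candidate farm, over
  days tracked; random intercepts for farm area, semester, and bird;
  separate analyses for territorial and non-territorial bird-semesters.
  The FARM denominator counts all eligible birds that semester regardless
  of home-range overlap ("birds with available information").

Writing `u = sigma_f z` per factor with spherical `z ~ N(0, I)`, the
marginal likelihood is approximated by Laplace's method. Estimation runs
in two stages: (1) a fast profiled search over the variance parameters,
with (beta, z) maximized jointly by penalized Newton iterations; (2) a
joint bounded quasi-Newton search over (theta, beta) with the
random-effect mode solved inside — the same objective the reference
mixed-model implementations maximize. On a packaged synthetic fixture the
fit agrees with a frozen lme4::glmer (Laplace) reference to about 1e-4 on
all coefficients, random-effect SDs, and the log-likelihood. Variance
parameters are bounded below by zero; boundary fits are retained and
flagged singular, and the model then degenerates exactly to the ordinary
logistic GLM. Standard errors of the fixed effects come from the
fixed-effect block of the inverse joint Hessian at the mode.

Random-effect structures are fixed per analysis as stated above, not
searched. Ranking ties break by fewer parameters, then lexicographic term
order (the enumeration order is deterministic and the AICc sort is
stable).

## Multimodel inference

* Candidates: every subset of the analysis's term menu from the intercept-
  only model to the full set, excluding subsets containing a collinear
  pair (|Spearman rho| > 0.5); additionally, for each subset, one model
  per two-way interaction of interest whose main effects the subset
  contains — never more than one interaction per model.
* AICc: `−2ℓ + 2k + 2k(k+1)/(n − k − 1)`, with `k` counting fixed
  coefficients plus variance components and `n` the number of rows.
* Uninformative parameters: working down the ranking, a model is
  discarded when a retained model with strictly lower AICc is nested
  within it (terms a strict subset) and the gap is ≤ 2 AICc units — the
  extra terms failed to buy a net AICc reduction.
* Averaging: if the best model holds ≥ 0.9 of the Akaike weight it is
  reported alone. Otherwise models with weight > 0.001 are averaged in
  full (zero substitution for absent terms, weights renormalized).
  Unconditional SEs follow the revised combination
  `SE = Σ w_i sqrt(se_i² + (b_i − b̄)²)`; relative importance is the
  summed weight of models containing the term; confidence limits are the
  7.5% and 92.5% normal quantiles (z ≈ 1.4395).

## Diagnostics

* VIF per design column from regressing it (centred) on the others.
* Overdispersion: sum of squared conditional Pearson residuals over
  `n − k`. With few rows per random-effect level this ratio sits below 1
  even for well-specified data, because random-effect shrinkage absorbs
  residual variation that the `n − k` denominator does not account for;
  calibration checks therefore use designs with ~20 rows per group level,
  where the ratio concentrates near 1.
* Pseudo-R² on the latent scale: marginal
  `var(Xb) / (var(Xb) + Σ sigma_f² + π²/3)` and conditional with the
  random-effect variance moved to the numerator.
* Moran's I on per-farm mean Pearson residuals with row-standardized
  15-nearest-neighbour weights; the p-value is a seeded one-sided
  permutation test (999 permutations, so the smallest attainable p is
  0.001).
* Mann–Whitney U (exact enumeration when the pooled sample is ≤ 12 and
  tie-free, normal approximation with tie correction otherwise) and
  Spearman rank correlations for the descriptive sex/season comparisons.

## The synthetic generator

`simulate_dataset` produces a complete, internally consistent study:
clustered farms with lognormal herd sizes (mu = 5.2, sigma = 1.0, mean
~300 head, matching an island-wide census of ~90k head over ~300 farms);
roads, urban polygons, one dump and two feeding stations (together the
highly predictable feeding places); a smooth positive DEM (200 m cells);
a bird roster with sexes, birth years, territorial status and nests; true
disposal behaviour from a known logistic model (abandonment rising with
distance to urban areas and to the dump) with ~30% of farms "interviewed";
and true visit days drawn from a known binomial mixed model (farm,
semester, and bird intercept SDs 0.5/0.3/0.4) with fixed effects at the
magnitudes of the empirical farm-use model (intercept −4.41, herd 0.44,
carcass 0.56, road distance 0.60, HPFP distance −0.86, breeding 0.49,
breeding×HPFP 0.31, on z-scored covariates).

Rendering is adversarial by construction: each true visit day gets 1–3
fixes inside the polygon with altitude above ground in (2, 20) m and
speed in (0, 1.8) m/s, offset from a member farm point by a truncated
|N(88, 41)| m jitter (the scale of real visit-fix distances); background
flight is always fast (6–15 m/s) so it can never qualify; decoys over
farms violate exactly one criterion each — a high pass (≥ 30 m above
ground), a fast transit (≥ 2 m/s), or a near-miss just outside the
polygon. Detection applied to rendered tracks must therefore return
exactly the true visit-day set; this identity holds with precision and
recall of 1 and is asserted in the tests.

Generator defaults mirror the empirical scale (318 farms, 45 birds, seven
semesters from 2013-S2, 300 s fixes). The tests and the acceptance script
run deliberately smaller configurations — e.g. 40 farms, 6 birds, 2
semesters, ~60% tracked days, 5 active hours per day (~150k fixes), and
the parameter-recovery experiment at 250 farms × 8 semesters (2000 rows,
denominators 50, 16 candidate models, 50 replicates) — chosen so the full
suite exercises every stage at meaningful sizes.

What the generator does **not** emulate: behaviourally realistic movement
(correlated random walks, Lévy flights), heterogeneous pre-2015 sampling
intervals (3 s–20 min), weather, coastline-clipped home ranges, or
interval-censored fix loss. Passing tests therefore demonstrate
correctness of the pipeline's logic and estimators under known ground
truth, not robustness to every field artefact of real telemetry.

## Degenerate inputs and edge conventions

* A point exactly on an area boundary counts as inside.
* Coincident farms merge with a warning; duplicate farm ids are an error.
* Zero-variance covariates are dropped from standardization with a
  warning; constant residual vectors make Moran's I an error.
* Random factors with a single level in a response table are dropped with
  a log entry before fitting (a one-semester pipeline run is legitimate).
* Perfectly separated carcass GLMs are flagged and excluded from ranking.
* The "success" covariate refers to the calendar year containing the
  semester; the alternative reading (previous breeding attempt) is noted
  as ambiguous.

## Known limitations

* The Laplace approximation is the estimation contract; no adaptive
  quadrature or Bayesian alternative is provided.
* Beta-binomial refits for overdispersed individual-level models are out
  of scope (the overdispersion diagnostic detects the inflation; the
  binomial fits are retained for comparability).
* Spline correlograms are not implemented; Moran's I is the spatial
  autocorrelation diagnostic.
* Visit-day truth requires the rendered criteria to be clean by design;
  real data with GPS altitude error near the 25 m threshold will not
  enjoy the exact-identity property.
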