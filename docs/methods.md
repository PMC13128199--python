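# Methods

This note documents the models, conventions and numerical choices behind
`lidarhab`, and what the synthetic test bed does and does not establish
about analyses of real airborne-laser-scanning (ALS) and telemetry data.

## Synthetic landscape

The generator emulates a pre-classified national ALS product over a
riparian mosaic. The landscape is a rectangle of 1-m² cells; a buffered
polyline forms the water channel and labelled polygons assign each cell to
a vegetation zone (meadow, herb, reedbed, shrub, forest). Water is
represented by the *absence* of returns — water cells emit no points of any
class — because that is the operational signature of open water in the ALS
data this workflow targets, and it is what the distance-to-water variable
detects.

Per land cell the generator emits:

* **ground returns** — a jittered grid guaranteeing at least one ground
  point per cell (plus Poisson excess up to the configured density,
  default 2.5 pt/m²). The guarantee makes k-NN ground interpolation
  well-posed everywhere; a pure Poisson process would leave empty cells.
* **vegetation returns** — Poisson counts at the zone's density (default
  7 pt/m² in vegetated zones, 3 in meadow) with heights uniform on the
  zone's range (herb 0.1–1 m, reedbed 0.5–2.5 m, shrub 1–5 m). Forest
  cells draw a canopy height uniformly on 10–22 m and emit returns between
  40% and 100% of it — a vertical crown column that yields realistic
  Q90/canopy-cover behaviour without modelling crown geometry.

Total densities (≈6–10 pt/m² in vegetated areas) match the leaf-off survey
regime the workflow is built for. Ground elevation is constant, a linear
slope, or a smoothed Gaussian random field (default amplitude 0.4 m,
correlation length 20 m). The default landscape is 300 × 300 m — desk-scale
while everywhere larger than the 25-m analysis radius; all layout
coordinates scale with the extent.

Because heights are drawn from known per-cell distributions, every
structural metric has a closed-form expectation (`TruthRasters`): the
expected band density of `[lo, hi)` is the uniform-overlap fraction times
the vegetation share of returns, and the true Q90 is the distribution
quantile. These truth rasters are the oracle for the metric tests.

What the generator does **not** emulate: scan-angle and intensity effects,
multiple returns per pulse, classification errors, buildings/structures,
phenology, and registration error between survey and tracking years. Tests
passing on the synthetic landscape therefore demonstrate the correctness of
the computations and the recoverability of planted preferences under clean
sampling noise — not robustness to sensor artefacts.

## Telemetry simulation

Individuals are tracked in 15-min bouts of up to four fixes at 5-min
spacing (default 4 bouts per tracking day, attachment durations spread over
0.6–9 days). The first fix of a bout is drawn over the individual's range
disc (default radius 60 m) with probability proportional to
exp(η), where η is the planted linear predictor of the *true* cell-level
habitat variables; fixes 2–4 are drawn from the same intensity within 10 m
of the previous fix, reproducing the within-bout spatial autocorrelation
that motivates first-of-bout filtering. Sampling picks a cell by its
intensity weight and a uniform position within it — equivalent in
distribution to rejection sampling from the piecewise-constant intensity.
Isotropic Gaussian GPS jitter (SD 3 m, the accuracy class of handheld
receivers) is added to every fix.

Bouts are truncated to 1–3 fixes with probability 0.2 and lose their first
fix with probability 0.03, so the first-of-bout filter's bookkeeping (the
retained count is *not* one quarter of the fixes; headless bouts are
dropped with a warning) is exercised by default. In the pipeline, release
points are drawn proportional to the habitat-use intensity itself, because
capture transects in such studies are placed in known or suitable habitat;
durations are spread evenly over the study range so the duration–area
correlation is estimable.

The default planted preference is a quadratic optimum at 30% vegetation
density below 1 m (weight 0.004 per squared percentage point), −0.05 per m
of Q90 vegetation height and −0.01 per m of distance to water — directions
and an optimum chosen to mimic a dense-herb-layer, water-associated small
mammal.

Home ranges are minimum convex polygons (Qhull); fewer than three unique,
non-collinear fixes yield NaN rather than an error, matching how
briefly-tracked individuals are reported in field studies. The
duration–area association is a Pearson correlation with df = n − 2 and a
two-sided t-based p-value.

## Habitat variables

Plot chain per position: clip at 10 m (vertical) / 35 m (horizontal) →
normalize heights → re-clip to 5 m / 25 m, discarding the normalization
buffer. Normalization subtracts an inverse-distance-weighted (p = 2) mean
of the k = 10 nearest ground returns in 2-D; a point horizontally
coincident with a ground return (distance < 1e−12 m) takes that return's
elevation exactly; plots with fewer than k ground returns use all of them
with a warning, and plots with none raise a normalization error (reported
as NaN rows by the batch extractor, never fatal).

Conventions the source workflow leaves open, fixed here:

* **Band densities** divide vegetation-class returns in `[lo, hi)` by *all*
  returns in the plot (ground included); restricting the numerator to the
  vegetation class keeps ground returns from counting as sub-metre
  "vegetation". Bands are half-open: [0,1), [1,5), [5,10), [10,∞). Canopy
  cover uses a strict `> 3 m` threshold.
* **Quantiles** use linear interpolation between order statistics (the
  common scientific-software default), so heights {1,…,10} give Q90 = 9.1.
* **Vegetation height** is the Q90 of vegetation returns (the operational
  definition), 0 for bare plots.
* **Rasterization**: 1-m² cells, half-open [x,x+1)×[y,y+1); a cell belongs
  to a plot iff its centre lies within the radius; boundary points at
  exactly the clip radius are retained (≤ convention).
* **Forest edge** counts unit sides shared between a forest cell
  (cell Q90 > 3 m) and an in-plot non-forest cell — ecotone length — with
  plot-boundary sides excluded; water cells count as non-forest. A
  `perimeter` mode (4 × forest-cell count) is available behind a flag.
* **SD/variance** of heights are population moments (ddof = 0),
  switchable.
* **Distance to water** rasterizes a 250-m plot, escalating to 400 m, and
  returns the distance to the nearest zero-return cell centre (0 if the
  query's own cell is water; NaN if both radii are dry). The
  implementation precomputes one global occupancy raster per cloud, which
  is equivalent to per-position rasterization and far cheaper.

Point-cloud I/O uses a plain CSV dialect (`x,y,z,class`, metres, ASPRS
codes 2/3/4/5/9 or names); coordinates are stored at millimetre precision.

## Maximum-entropy SDM

The model is the Gibbs density q(x) ∝ exp(λ·f(x)) relative to the
background sample. Features are linear + quadratic terms of
background-standardized variables (optional hinge terms, off by default:
quadratic features suffice to express the unimodal density response this
workflow reports, and keep the fit small and deterministic). The penalized
likelihood is maximized with monotone proximal-gradient descent
(Barzilai–Borwein steps, backtracking that enforces a non-increasing
penalized objective, soft-thresholding for the L1 term), converging when
the KKT residual falls below 1e−6 or the objective change below 1e−9.

The L1 weight per feature is β · s_j / √n₁ (s_j the feature's background
SD, n₁ the presence count, β = 1 by default) — scale-free and vanishing
with sample size, mirroring the default regularization behaviour of
standard Maxent implementations without reproducing their per-feature-class
tables. When a training split is linearly separable in feature space the
unpenalized likelihood is unbounded; the fit detects the coefficient
divergence (‖λ‖∞ > 30 on standardized features) and raises, and the
bootstrap ensemble retries such runs with a 4×-escalated penalty before
excluding them — each run records the penalty it used.

Outputs follow the two standard scalings: `raw` = e^{λ·f}/Z̄ averages 1
over the training background; `logistic` = p·e^H/(1 + p·e^H), with p the
sum-to-one raw distribution over the training background and H its entropy,
so an uninformative model predicts 0.5 everywhere. Evaluation on held-out
rows uses AUC (rank probability with half-credit ties), COR (point-biserial
correlation of the logistic output with the 0/1 label), TSS (max over a
threshold sweep of all unique predictions, their midpoints and one value
above the maximum), and deviance (−2 × mean Bernoulli log-likelihood with
predictions clipped to [1e−9, 1−1e−9]).

The ensemble draws 70% of presences and 70% of background *without*
replacement per run (the subsampling reading of "bootstrap"; classical
resampling is available behind `replace=True`), fits, evaluates on the
remainder, and — with the run's own RNG — permutes each variable once in
the test rows to get the AUC-drop importance, truncated at 0 and
normalized per run to sum to 1. Response curves sweep one variable over
its observed range with the others at their combined-table mean, summarized
by the per-run mean and 2.5/97.5 percentiles. Backward selection repeatedly
drops the lowest-importance variable while the mean held-out AUC does not
fall by more than a tolerance (default 0.01).

Collinearity screening precedes fitting: the pair with the largest
|Spearman ρ| > 0.7 loses its member with the lower single-variable training
AUC (a one-variable Maxent fit), iterating until no pair exceeds the
threshold. The field practice weighs "ecological relevance" at this step;
a univariate-AUC criterion is the reproducible proxy used here.

## Problem sizes and determinism

Default analysis scale: 300 × 300 m landscape (~0.6 M returns), 20
individuals (~350 first-of-bout positions plus matched background), 100
ensemble runs — a few minutes on one CPU, with feature extraction the
dominant cost. Tests run reduced versions of the same conditions (smaller
extents, fewer runs) chosen for rapid iteration. All randomness flows from
one master seed through `numpy.random.SeedSequence` spawning; pipeline
stages consume the *persisted* artifact of the previous stage (CSVs written
with round-trip precision), so a stage-wise run reproduces the monolithic
run byte for byte and two runs with the same master seed produce identical
manifests.

## Known limitations

* The synthetic ensemble's discrimination (held-out AUC ≈ 0.7 at default
  settings) is below what strongly selective species yield in the field,
  because the synthetic mosaic offers usable habitat over much of the
  landscape and home-range discs confine individuals regardless of
  preference; the planted-signal recovery tests, not the absolute AUC,
  are the validation target.
* Importance is one permutation per run per variable; with few runs the
  between-run SD is wide.
* The logistic output is used for response curves; cloglog and other
  transforms are not implemented.
* No geographic prediction surfaces or map rendering; the unit of analysis
  is the position, not the raster.
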