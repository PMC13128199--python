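# lidarhab

Fine-scale habitat-use analysis from airborne-LiDAR vegetation structure and
radio-telemetry, built around the workflow used to study the Eurasian Water
Shrew (*Neomys fodiens*) in riparian landscapes: telemetry fixes are
contrasted with random background positions through LiDAR-derived habitat
variables in a maximum-entropy species distribution model (SDM).

Field data of this kind (classified national ALS point clouds, tracked
animals) are rarely redistributable, so the package ships a seeded synthetic
module that generates a classified riparian point cloud **with known ground
truth** and simulates telemetry from a planted habitat preference. Every
stage of the analysis is therefore testable end to end: the habitat metrics
are checked against the generator's truth rasters and brute-force oracles,
and the SDM against the planted preference it is supposed to recover.

The package is aimed at spatial ecologists who want a transparent,
dependency-light reference implementation of this pipeline — and a test bed
for its statistical behaviour — rather than a GIS product.

## The pipeline

1. **Synthetic landscape** (`lidarhab.landscape`) — a parameterized habitat
   mosaic (water channel, meadow, herb band, reedbed, shrub, forest) emitted
   as a classified point cloud (ASPRS classes; water = zero returns) plus
   per-cell truth rasters.
2. **Telemetry** (`lidarhab.telemetry`) — fixes in 15-min bouts of four
   5-min positions drawn from an intensity ∝ exp(planted linear predictor of
   the true habitat variables), with 3-m GPS jitter; first-of-bout
   filtering; uniform background sampling; minimum-convex-polygon home
   ranges and the attachment-duration/area correlation.
3. **Habitat variables** (`lidarhab.metrics`) — for each position, plots are
   clipped at 10/35 m, height-normalized by inverse-distance-weighted k-NN
   ground interpolation (k = 10, p = 2), re-clipped to 5/25 m, and reduced
   to 11 variables: vegetation density below 1 m, 1–5 m, 5–10 m and above
   10 m, Q90 vegetation height, height SD (structural complexity), canopy
   cover above 3 m, open area (1-m² cells with Q90 ≤ 0.5 m), variance of
   cell Q90, forest-edge length (ecotone sides of cells with Q90 > 3 m) and
   distance to the nearest zero-return (water) cell within 250/400 m.
4. **SDM** (`lidarhab.sdm`) — Spearman collinearity screening (|ρ| > 0.7,
   keep the member with the higher single-variable AUC), then the
   maximum-entropy model

   q(x) ∝ exp(λ·f(x)),  λ̂ = argmax (1/n₁) Σ_presence λ·f − log[(1/n₀) Σ_background e^{λ·f}] − β Σⱼ sⱼ|λⱼ|

   with linear + quadratic features of background-standardized variables and
   an SD-scaled L1 penalty, fitted by monotone proximal-gradient descent.
   A 100-run stratified 70/30 ensemble yields held-out AUC, COR, TSS and
   deviance, permutation (AUC-drop) variable importance, response curves
   with 95% bands, and optional backward selection.
5. **Pipeline/CLI** (`lidarhab.pipeline`, `lidarhab.cli`) — one seeded run
   producing all artifacts and a `manifest.json` with every count and stage
   seed; byte-reproducible from the master seed.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
300 × 300 m landscape (seed 42):

```sh
python analysis/01_simulate_landscape.py
python analysis/02_simulate_telemetry.py
python analysis/03_extract_features.py
python analysis/04_fit_sdm.py
python analysis/05_response_curves.py
```

Stage 2 prints the tracking bookkeeping and home ranges:

```
fixes recorded        : 1,326
first-of-bout retained: 369
individuals with MCP  : 19 of 20
duration-area Pearson : r = 0.726, df = 17, p = 0.00043
```

1,326 raw fixes collapse to 369 analysis positions because only the first
fix of each 15-min bout is kept (bouts can be incomplete, so the ratio is
not exactly 4); one briefly-tracked individual has too few unique positions
for a home-range polygon; longer transmitter attachment goes with larger
observed ranges.

Stage 4 screens collinear variables and fits the ensemble:

```
model rows            : 682 (56 dropped with undefined variables)
variables retained    : lt1_density, open_areas, forest_edge, dist_water
  auc      : 0.727 ± 0.028
variable importance (normalized permutation AUC drop):
  lt1_density        0.579 ± 0.132
  forest_edge        0.350 ± 0.136
  dist_water         0.065 ± 0.057
  open_areas         0.007 ± 0.014
```

The planted preference (an optimum at 30% low-vegetation density, water
affinity, aversion to tall vegetation) is recovered: the <1 m density is
the top-ranked variable and its response curve peaks at 26.7% (stage 5).

Equivalently via the CLI: `lidarhab run --seed 42 --out results/run`.

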