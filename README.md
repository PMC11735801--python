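# biofilmflow

Quantitative analysis of biofilm growth under laminar channel flow, from
volumetric (OCT-style) greyscale scans to a friction-limited growth law.

The package covers the complete measurement chain:

* **`biofilmflow.phantom`** — synthetic scan generator with exact voxel-level
  ground truth: Gaussian background noise, a bright (optionally tilted)
  substratum plane, leaning-pillar microcolonies with downstream streamer
  filaments, and growth time series driven by the erosion–growth balance
  model (colonies arrive as a Poisson process).
* **`biofilmflow.preprocess`** — volume rotation, substratum detection
  (per-column argmax + radius-11 disk median filter), integer-shift
  flattening, and cross-correlation registration of scan pairs.
* **`biofilmflow.segmentation`** — histogram-inflexion thresholding (mode →
  maximum second derivative right of the mode → +3 offset), strict
  binarisation, removal-only outlier filtering, and top trimming.
* **`biofilmflow.morphometrics`** — height *h*, thickness *T*, solidity
  *T/h* maps, streamer classification (*T/h* ≤ 2/3), substratum coverage
  (bottom-layer and max-projection variants), biovolume and mean thickness.
* **`biofilmflow.hydrodynamics`** — plane-Poiseuille wall shear stress
  τ_w = 6 μQ/(H² w), hydraulic diameter, Reynolds number, tip-shear
  amplification, and the streamer-fluidisation viscosity estimate.
* **`biofilmflow.growth_model`** — colony height ODE dh/dt = g − (C/μ_b) h τ_w
  with its closed-form solution, equilibrium height h_max = g μ_b/(C τ_w),
  population biovolume V_b = K t/τ_w, and nonlinear least-squares fitting of
  T̄ = a·t·τ_w^k.
* **`biofilmflow.pipeline`** / CLI — configurable end-to-end workflow.

## Command line

```sh
# synthetic scan with ground-truth sidecar
biofilmflow phantom --shape 64 96 96 --tilt 2 --seed 1 --out scan.tif

# binarise a TIFF stack (flatten -> threshold -> denoise -> trim)
biofilmflow segment scan.tif --out binary.tif --report segment.json

# morphometric summary of a binary stack
biofilmflow quantify binary.tif --time 24 --tau-w 0.068 --out summary.json

# power-law fit of a thickness table (columns t, tau_w, T_bar)
biofilmflow fit thickness.csv --out fit.json

# full pipeline from a YAML config
biofilmflow run --config examples/demo.yaml --out scratch/demo_out
```

`run` emits `summaries.csv` (t, tau_w, SC, V_b, T_bar), per-scan JSON
reports with the chosen thresholds, and the fitted (a, k) with standard
deviations when at least two shear levels are present.

## Conventions

* Volumes are indexed `[z][y][x]`, z increasing away from the bottom;
  default voxel pitch 12 μm lateral, 2.1 μm axial.
* After flattening, the substratum voxel sits at z = 0; the quantification
  path drops that layer, so morphometrics sees z = 0 as the first layer
  above the plane.
* Heights use the top-face convention: a column whose highest set voxel has
  index k has height (k+1)·voxel_axial.
* The growth model works in μm / hours / Pa; `GrowthParams.with_si_viscosity`
  accepts μ_b in Pa·s.
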