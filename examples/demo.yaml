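# Demo pipeline run: two shear levels, three scan times each.
# Completes in well under a minute on one CPU:
#   biofilmflow run --config examples/demo.yaml --out scratch/demo_out
seed: 1
tau_w: [0.068, 0.27]
times: [24.0, 48.0, 72.0]
shape: [64, 72, 72]
tilt_deg: 2.0
noise_mean: 30.0
noise_sigma: 5.0
growth:
  g: 22.0            # colony height growth rate, um/h
  C: 1.0             # erosion coefficient
  mu_b_pa_s: 1000.0  # biofilm viscosity, Pa s
  beta: 0.08         # colony appearance rate, 1/h
  A_fp: 22000.0      # colony footprint area, um^2
segmentation:
  smooth: true
  offset: 3
  denoise: true
  outlier_radius: 2
  trim_margin: 3
quantify:
  drop_bottom_layers: 1
  edge_crop: 12
  sc_variant: bottom-layer
fit: true
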