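# Named synthetic-domain presets.
#
# primaryA   — large "primary" domain: rough (clinical-style) annotations,
#              moderate bias and noise.
# challengeB — challenge domain with clean annotations and anisotropic
#              voxels (0.6 x 0.6 x 1.5 mm).
# challengeC — challenge domain with clean annotations and low contrast.
# oodD       — out-of-domain task: off-centre multi-lobed distractor target.

primaryA:
  grid_shape: [48, 48, 36]
  spacing_mm: [1.0, 1.0, 1.0]
  organ_radius_frac: 0.30
  shape_irregularity: 0.15
  organ_intensity: 1.0
  background_intensity: 0.2
  contrast_gradient: 0.3
  noise_sd: 0.05
  bias_strength: 0.3
  annotation_roughness_mm: 2.0
  task: organ

challengeB:
  grid_shape: [64, 64, 24]
  spacing_mm: [0.6, 0.6, 1.5]
  organ_radius_frac: 0.28
  shape_irregularity: 0.20
  organ_intensity: 0.9
  background_intensity: 0.25
  contrast_gradient: 0.15
  noise_sd: 0.08
  bias_strength: 0.2
  annotation_roughness_mm: 0.0
  task: organ

challengeC:
  grid_shape: [48, 48, 36]
  spacing_mm: [1.0, 1.0, 1.0]
  organ_radius_frac: 0.30
  shape_irregularity: 0.18
  organ_intensity: 0.55
  background_intensity: 0.35
  contrast_gradient: 0.1
  noise_sd: 0.06
  bias_strength: 0.25
  annotation_roughness_mm: 0.0
  task: organ

oodD:
  grid_shape: [48, 48, 36]
  spacing_mm: [1.0, 1.0, 1.0]
  organ_radius_frac: 0.30
  shape_irregularity: 0.10
  organ_intensity: 0.35
  background_intensity: 0.7
  contrast_gradient: 0.1
  noise_sd: 0.07
  bias_strength: 0.2
  annotation_roughness_mm: 0.0
  task: distractor
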