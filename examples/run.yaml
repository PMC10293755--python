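# Reduced-scale example: 4 groups x 4 samples on a 1 mm grid (~30 s).
# Remove the tissue/cohort overrides to run the full-resolution default
# (0.5 mm voxels, 16 samples per group).
seed: 1
threshold_c: 60.0
cohort:
  n_per_group: 4
  dt_s: 0.05
  dropout_rate: 0.05
tissue:
  dims: [30, 30, 20]
  voxel_mm: 1.0
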