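# Reduced end-to-end demo configuration (a full-size run uses the
# defaults: 1830 trials, 23 HC + 31 CHR, 4.25 x 5.38 mm x 2 ms voxels).
paradigm:
  n_trials: 200
cohort:
  n_hc: 4
  n_chr: 6
  effect_link: 0.0
glm:
  regressors: [epsilon2]
  voxel: [12.0, 12.0]
  time_step: 8.0
inference:
  n_perm: 200
hgf:
  fit: false
seed: 7
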