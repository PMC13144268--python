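# Example experiment config: start from the fast profile and override fields.
# Any ExperimentConfig field may appear here; phantom_spec mirrors PhantomSpec.
profile: fast
master_seed: 1
output_dir: out/example
n_cases: 35
methods: [short, gaussian, bilateral, unet_l4]
reference_method: unet_l4
train:
  epochs: 60
  lr_switch_epoch: 45
phantom_spec:
  n_slices: 15
  pixel_size: 3.29
  psf_fwhm: 10.0
  counts_per_cycle: 300000.0
  background_texture: 0.4
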