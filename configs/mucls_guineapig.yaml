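# Compact-light-source scan of a guinea-pig cochlea: 25 keV inverse-Compton
# beam, fiber-coupled sCMOS (6.5 um pixels), long propagation distance
# (F_eff ~ 0.61, strong edge enhancement).
geometry:
  z01_mm: 3769.0
  z02_mm: 4856.5
  pixel_um: 6.5
  energy_kev: 25.0
  source_fwhm_um: 98.0     # ~2.355 * 41.5 um rms spot
phantom:
  grid_size: 64
  voxel_um: 5.05           # matches the effective pixel p/M
  n_turns: 2.0
  shell_thickness_um: 25.0
  membrane_thickness_um: 6.0
  include_metal: false
  seed: 0
simulation:
  n_angles: 120
  angular_range_deg: 360.0
  mean_counts: 10000.0
  model: fresnel
  flat_gain_sigma: 0.02
retrieval:
  alpha: 0.005
  gamma: 0.025
reconstruction:
  filter_name: ram-lak
  ring_window: 9
seed: 0
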