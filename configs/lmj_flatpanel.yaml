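# Liquid-metal-jet source with a flat-panel detector (74.8 um pixels) at
# high magnification: same effective pixel, smaller Fresnel number (~1.69),
# the geometry optimized for propagation contrast.
geometry:
  z01_mm: 120.0
  z02_mm: 1783.0
  pixel_um: 74.8
  energy_kev: 9.25
  source_fwhm_um: 10.0
phantom:
  grid_size: 64
  voxel_um: 5.05
  n_turns: 2.0
  shell_thickness_um: 25.0
  membrane_thickness_um: 6.0
  include_metal: true
  seed: 0
simulation:
  n_angles: 120
  angular_range_deg: 360.0
  mean_counts: 4000.0
  model: fresnel
  flat_gain_sigma: 0.02
retrieval:
  alpha: 0.02
  gamma: 0.09
reconstruction:
  filter_name: ram-lak
  ring_window: 9
seed: 0
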