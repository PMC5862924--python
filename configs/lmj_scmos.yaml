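# Liquid-metal-jet source with the same sCMOS detector: short stand-off
# (F_eff ~ 3.46 at the Ga-K_alpha line, weak edge enhancement). The printed
# Fresnel number follows the 9.25 keV Ga-K_alpha wavelength.
geometry:
  z01_mm: 247.0
  z02_mm: 317.8
  pixel_um: 6.5
  energy_kev: 9.25
  source_fwhm_um: 10.0
phantom:
  grid_size: 64
  voxel_um: 5.05
  n_turns: 2.0
  shell_thickness_um: 25.0
  membrane_thickness_um: 6.0
  include_metal: false
  seed: 0
simulation:
  n_angles: 120
  angular_range_deg: 360.0
  mean_counts: 2000.0      # photon-starved relative to the compact source
  model: fresnel
  flat_gain_sigma: 0.02
retrieval:
  alpha: 0.03
  gamma: 0.035
reconstruction:
  filter_name: ram-lak
  ring_window: 9
seed: 0
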