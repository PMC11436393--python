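# Example synthetic time-course study.
# A two-ring section keeps runtimes short; raise n_rings for a full device.
design:
  nominal_diameter: 3.0
  n_rings: 2
  crowns_per_ring: 6
  links_between_rings: 2
  strut_width: 0.11
  strut_thickness: 0.11
  ring_pitch: 1.4
  crown_amplitude: 0.55

# implantation-style schedule (months); erosion depth defaults to k * t with
# k set by t_complete_months below
schedule:
  - {time_months: 1.0}
  - {time_months: 6.0, cut_fraction: 0.2}
  - {time_months: 12.0, cut_fraction: 0.55, dilation: 1.1}
  - {time_months: 18.0, cut_fraction: 0.9, dilation: 1.2}

rendering:
  spacing: 0.02      # mm/voxel
  psf_sigma: 1.0     # voxels
  noise_sd: 7.0      # grayvalue units

t_complete_months: 23.5
substitution_fraction_dense: 0.0
substitution_fraction_lucent: 0.0
measurement_mode: grayscale
seed: 7
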