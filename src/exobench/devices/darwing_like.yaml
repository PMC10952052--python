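# SYNTHETIC fixture parameterization of a Darwing-Hakobelude-class soft
# exosuit (bands spanning shoulder blade to lumbar region). Plausible scale,
# NOT manufacturer data.
name: darwing_like
type: soft
loading:
  # band force (N) vs elongation (mm), per band
  coeffs: [0.0, 0.55]
unloading:
  # ~75% of loading -> ~25% hysteresis loss
  coeffs: [0.0, 0.4141]
elongation_range_mm: [0.0, 120.0]
band_marker_labels: [[LBAND_T, LBAND_M], [RBAND_T, RBAND_M]]
moment_arm_m: 0.10
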