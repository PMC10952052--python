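# SYNTHETIC fixture parameterization of a Laevo-Flex-class rigid back-support
# exoskeleton (gas-spring hip module). Plausible scale, NOT manufacturer data.
name: laevo_like
type: rigid
loading:
  # torque (Nm) vs exo angle alpha (deg), ascending coefficients;
  # peaks ~33.6 Nm near alpha = 61 deg
  coeffs: [0.0, 1.1, -0.009]
unloading:
  # ~66% of the loading branch -> ~34% hysteresis loss
  coeffs: [0.0, 0.7293, -0.005967]
alpha_range_deg: [0.0, 110.0]
attachment_labels: [CLAV, EXO_HIP, EXO_THIGH]
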