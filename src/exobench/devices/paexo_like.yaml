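# SYNTHETIC fixture parameterization of a Paexo-back-class rigid exoskeleton;
# assistance keeps rising toward deep flexion. Plausible scale, NOT
# manufacturer data. Its hip hinge does not allow squatting.
name: paexo_like
type: rigid
loading:
  # torque (Nm) vs exo angle alpha (deg); ~32 Nm at alpha = 85 deg
  coeffs: [0.0, 0.25, 0.0015]
unloading:
  # ~68% of loading -> ~32% hysteresis loss
  coeffs: [0.0, 0.1708, 0.0010245]
alpha_range_deg: [0.0, 110.0]
attachment_labels: [CLAV, EXO_HIP, EXO_THIGH]
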