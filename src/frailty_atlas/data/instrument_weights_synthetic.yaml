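# SYNTHETIC weight set for the five-component weighted frailty instrument.
#
# The published gender-specific discrete-factor weights and frailty thresholds
# are applied in real analyses but are carried here as *data*, not code. This
# shipped default is a constructed stand-in with plausible magnitudes and signs
# (deficits load positively, grip strength negatively, thresholds between the
# healthy and fully-deficient extremes); it is NOT the published set. Replace it
# with a transcription of the published weights for real analyses.
provenance: >
  SYNTHETIC stand-in weight set constructed for this package's demonstrations
  and tests; schema-compatible with a transcription of the published
  gender-specific discrete-factor weights and thresholds.
genders:
  female:
    intercept: 2.0
    weights:
      grip_strength: -0.07
      fatigue: 0.9
      appetite_loss: 0.6
      mobility_difficulty: 1.0
      low_activity: 0.8
    threshold: 1.6
  male:
    intercept: 2.6
    weights:
      grip_strength: -0.065
      fatigue: 0.9
      appetite_loss: 0.6
      mobility_difficulty: 1.0
      low_activity: 0.8
    threshold: 1.4
# Grip-weakness cutoffs (kg) for the auxiliary unweighted phenotype-count mode
# (frail if >= 3 of 5 deficits). Non-canonical; provided for weight-free testing.
fried_cutoffs:
  female: 20.0
  male: 32.0
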