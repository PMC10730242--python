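# SCORE2-style linear-predictor configuration.
#
# NON-CLINICAL PLACEHOLDER COEFFICIENTS. The published risk-score coefficients
# live in their original publications and are not reproduced here; these values
# are synthetic stand-ins that preserve the structure of the score (log/centred
# transformations, a baseline survival, and the two-parameter region
# recalibration) and the monotone direction of every risk factor. Replace this
# file with externally sourced coefficients for any clinical use.
schemes:
  SCORE2:
    horizon_years: 3.0
    baseline_survival: 0.97
    # transform: value applied as coefficient * (transform of the raw variable)
    terms:
      age:        {coefficient: 0.35, center: 60.0, scale: 5.0}
      sbp:        {coefficient: 0.18, center: 120.0, scale: 20.0}
      ldl:        {coefficient: 0.15, center: 3.0, scale: 1.0}
      smoking:    {coefficient: 0.30, center: 0.0, scale: 1.0}
      diabetes:   {coefficient: 0.40, center: 0.0, scale: 1.0}
      sex_female: {coefficient: -0.20, center: 0.0, scale: 1.0}
    calibration: {scale1: 0.0, scale2: 1.0}
    thresholds: {low_upper: 0.05, moderate_upper: 0.10}
  SCORE2-OP:
    horizon_years: 10.0
    baseline_survival: 0.90
    terms:
      age:        {coefficient: 0.25, center: 73.0, scale: 5.0}
      sbp:        {coefficient: 0.15, center: 120.0, scale: 20.0}
      ldl:        {coefficient: 0.10, center: 3.0, scale: 1.0}
      smoking:    {coefficient: 0.25, center: 0.0, scale: 1.0}
      diabetes:   {coefficient: 0.35, center: 0.0, scale: 1.0}
      sex_female: {coefficient: -0.15, center: 0.0, scale: 1.0}
    calibration: {scale1: 0.0, scale2: 1.0}
    thresholds: {low_upper: 0.075, moderate_upper: 0.15}
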