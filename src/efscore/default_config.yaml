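# Default configuration shipped with efscore.
#
# truncation_bounds: physiologic plausibility limits applied when drawing
# synthetic clinical variables from normal distributions (values outside the
# bounds are redrawn).  Units follow the variable name.
truncation_bounds:
  age_yr: [30.0, 95.0]
  bmi: [10.0, 45.0]
  pack_years: [0.0, 300.0]
  fvc_pct_pred: [10.0, 160.0]
  dlco_pct_pred: [10.0, 160.0]
  bal_lymphocytes_pct: [0.0, 100.0]
  bal_neutrophils_pct: [0.0, 100.0]
  bal_eosinophils_pct: [0.0, 100.0]
  ef_score_pct: [0.0, 100.0]

# Grayscale luminance weights (applied to R, G, B) used by the scoring chain
# unless overridden.
grayscale_weights: [0.299, 0.587, 0.114]

# Reported-value rounding, matching clinical-table convention.
rounding:
  p_decimals: 3
  percent_decimals: 1
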