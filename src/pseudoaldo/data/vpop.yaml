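# Virtual elderly population: distributions of the three sensitivity factors.
# The published analysis estimated these distributions from external
# literature samples (n = 31 OATP1B1 expression, n = 16 colonic transit,
# n = 21 plasma cortisol:cortisone ratio) whose raw values are not printed;
# the hyperparameters below are therefore editable stand-ins with a
# documented mapping and the K_co bootstrap vector is a SYNTHETIC sample
# centred on the elderly colonic transit constant.
cl_up_multiplier:
  distribution: lognormal
  median: 1.0
  # 4.9-fold inter-individual range read as the 95% interval of the
  # lognormal: sigma = ln(4.9)/(2*1.96) = 0.4057
  sigma_log: 0.4057
K_co:                       # 1/h, elderly colonic transit (bootstrap)
  distribution: bootstrap
  samples: [0.0150, 0.0165, 0.0178, 0.0188, 0.0196, 0.0204, 0.0210, 0.0215,
            0.0219, 0.0224, 0.0230, 0.0238, 0.0247, 0.0259, 0.0275, 0.0302]
  samples_provenance: synthetic (centred on the elderly value 0.0217 1/h)
k_ox0:                      # l/h, elderly 11beta-HSD2 baseline clearance
  distribution: truncated_normal
  mean: 0.02
  sd: 0.004
  lower: 0.012              # truncation at the sample extremes
  upper: 0.028
  bounds_provenance: synthetic (sample-extreme convention)
dose_limit:
  baseline_K: 4.18          # mmol/l, median of the 3.5-5.0 normal range
  threshold_K: 3.5          # mmol/l, hypokalemia boundary
  eval_day: 28
  bracket_mg: [10.0, 2000.0]
  tol_mg: 1.0
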