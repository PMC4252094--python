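# Human (70 kg) parameter set for the GL/GA/GAM PBPK model.
# Units: volumes l, flows l/h, doses mg.
# Clearance units follow the published table: CL_up and CL_b are l/h
# (fitted directly in human), while K_12_r, CL_met and PS_eff are ml/h
# (scaled from the rat ml/h values by cardiac-output ratio, liver-weight
# ratio and allometry; e.g. the GA sinusoidal efflux 28179 ml/h = 28.18 l/h).
# The loader converts the ml/h entries for the litre-based model.
species: human
physiology:
  body_weight: 70.0          # kg
  volumes:                   # l
    liver: 1.8
    guts: 1.15
    kidneys: 0.3
    liver_venous: 0.18
    vascular: 5.0
  flows:                     # l/h (blood)
    hepatic_artery: 19.4
    portal_vein: 71.5
    kidney: 69.0
  # Three-segment gut transit constants (1/h). Literature-informed defaults:
  # gastric emptying ~30 min, small-intestinal transit ~4 h, colonic
  # residence ~25 h in healthy adults. The elderly colonic constant used in
  # the sensitivity/virtual-population analyses is 0.0217 1/h.
  transit:
    K_st: 2.0
    K_s: 0.25
    K_co: 0.04
  transit_provenance: literature-sourced
  meal_times: [0.0, 5.0, 10.0]   # h after the start of each simulated day
compounds:
  GL:
    K_12_r: 1241      # ml/h
    K_21_r: 0.13      # 1/h
    f_u: 0.004
    f_ut: 0.008
    hematocrit: 0.42
    CL_up: 431        # l/h
    CL_b: 454.0       # l/h
    CL_met: 50516     # ml/h
    PS_eff: 1809      # ml/h
    P_k: 0.14
    P_g: 0.015
    K_abs_si: 0.13    # 1/h (enterohepatic recycling absorption)
    KH_co: 0.19       # 1/h
    molecular_weight: 822.93
  GA:
    K_12_r: 9016
    K_21_r: 0.46
    f_u: 0.0008
    f_ut: 0.0016
    hematocrit: 0.42
    CL_up: 20000
    CL_met: 371546
    PS_eff: 28179
    P_k: 0.15
    P_g: 0.06
    K_abs_si: 0.084
    K_abs_co: 0.40
    molecular_weight: 470.68
  GAM:
    f_ut: 0.008
    hematocrit: 0.42
    CL_b: 454.0
    KH_co: 0.1
    molecular_weight: 646.81
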