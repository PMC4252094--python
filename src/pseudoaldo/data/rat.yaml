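# Rat (250 g) parameter set for the GL/GA/GAM semi-PBPK model.
# Units: volumes ml, flows ml/h, clearances ml/h, rates 1/h, V_max umol/h,
# K_m umol/ml, doses interpreted as mg/kg for rat regimens.
species: rat
physiology:
  body_weight: 0.25          # kg
  volumes:                   # ml
    liver: 10.3
    guts: 13.75              # sum of small + large intestine
    kidneys: 1.875
    liver_venous: 1.2
    vascular: 18.75
  flows:                     # ml/h (blood)
    hepatic_artery: 104.6
    portal_vein: 762.0
    kidney: 553.8
  # Gastrointestinal transit constants (1/h). Not part of the printed
  # physiology table; literature-sourced defaults (rodent GI transit:
  # gastric emptying ~20 min, small-intestinal transit ~2 h over three
  # segments, cecal residence ~4 h, colonic residence ~7 h). Required at
  # load time; override for other transit assumptions.
  transit:
    K_st: 2.0
    K_sa: 1.5
    K_sb: 1.5
    K_sc: 1.5
    K_ce: 0.25
    K_co: 0.15
  transit_provenance: literature-sourced
compounds:
  GL:
    K_12_r: 20        # ml/h
    K_21_r: 0.46      # 1/h
    f_u: 0.006
    f_ut: 0.012
    hematocrit: 0.5
    V_max: 9.0        # umol/h
    K_m: 0.0014       # umol/ml (unbound)
    V_max_B: 4.7      # umol/h
    K_m_B: 0.00037    # umol/ml (unbound)
    CL_met: 737       # ml/h
    PS_eff: 26        # ml/h
    P_k: 0.14
    P_g: 0.015
    KH_ce: 0.29       # 1/h
    KH_co: 0.11       # 1/h
    molecular_weight: 822.93   # g/mol, formula-derived
  GA:
    K_12_r: 143
    K_21_r: 1.6
    f_u: 0.008
    f_ut: 0.016
    hematocrit: 0.5
    V_max: 9.0
    K_m: 0.0004
    CL_met: 2666
    PS_eff: 411
    P_k: 0.15
    P_g: 0.06
    K_abs_si: 0.47
    K_abs_co: 0.58
    molecular_weight: 470.68
  GAM:
    f_ut: 0.012
    hematocrit: 0.5
    V_max_B: 4.7
    K_m_B: 0.00037
    KH_ce: 0.03
    KH_co: 0.03
    molecular_weight: 646.81
extras:
  bile_transit: 1.0   # 1/h, first-order bile-duct delay (no printed value)
  ip_absorption: 2.0  # 1/h, peritoneal depot -> portal stream
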