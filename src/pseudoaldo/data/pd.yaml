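# Pharmacodynamic parameters: 11beta-HSD2 inhibition module and the
# aldosterone secretagogue model.
hsd2:
  IC50: 0.000234        # umol/ml kidney GA (optimized)
  V_app: 5.2            # l, apparent cortisone distribution volume (optimized)
  V_k: 0.3              # l, kidney volume (physiology)
  # Baseline endocrine inputs. These are REQUIRED literature-sourced values
  # (healthy-adult cortisol/cortisone physiology); they are not part of the
  # optimized parameter table and may be overridden.
  baselines:
    F_0: 100.0            # ug/l plasma cortisol (~10 ug/dl)
    E_0: 17.0             # ug/l plasma cortisone (~1.7 ug/dl)
    K_tp_cortisol: 1.5    # kidney:plasma cortisol concentration ratio
    urinary_cortisol_24h: 84.5    # ug/24 h (baseline ratio 0.65)
    urinary_cortisone_24h: 130.0  # ug/24 h
  # Derived normal-adult k_ox0 = urinary_cortisone_24h/(24*K_tp*F_0)
  # = 0.036 l/h; the elderly value used in the sensitivity and
  # virtual-population analyses is 0.02 l/h (~1.8-fold lower).
  k_ox0_elderly: 0.02     # l/h
raas:
  K_gen_aldo: 62.8      # ng/dl/h
  S_max: 92.63
  SC50_K: 4.577         # mmol/l
  SC50_AngII: 94.129    # pg/ml
  K_deg_aldo: 18.67     # 1/h
  hill_K: 9.97          # Hill coefficient on the potassium secretagogue
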