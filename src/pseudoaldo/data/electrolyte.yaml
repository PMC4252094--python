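# Reduced renin-angiotensin + body-fluid/electrolyte system.
# The reduction gains below are the single calibration config for the module:
# they are chosen so that (i) the no-drug state is an exact fixed point and
# (ii) the clinical one-week deltas under sustained mineralocorticoid-receptor
# activation (potassium fall, mild sodium/volume retention, compensatory
# renin-angiotensin suppression) are reproduced. Swap this file to recalibrate
# or to stand in a fuller body-fluid model behind the same contract.
baselines:
  K_serum: 4.18         # mmol/l (scenario configs may override)
  Na_serum: 141.0       # mmol/l
  AngII: 54.4           # pg/ml
  V_ecf: 15.0           # l extracellular fluid
  K_intracellular_pool: 3200.0   # mmol
  K_intake: 70.0        # mmol/day
  Na_intake: 150.0      # mmol/day
gains:
  beta_cortisol: 3.0    # cortisol:aldosterone baseline MR-contribution ratio
  gamma_mr: 2.99936     # convexity of the cortisol->MR transduction
  g_pressure: 2.0       # relative arterial-pressure gain per relative blood-volume change
  g_gfr: 1.34422        # relative GFR gain per relative pressure change
  g_renin: 5.47995      # renin suppression per relative pressure rise
  k_renin: 0.030619     # 1/h renin turnover (chronic resetting)
  k_angii: 2.0          # 1/h angiotensin II turnover
  a_gfr_excretion: 1.0  # GFR exponent in urinary K and Na excretion
  b_k: 0.345223         # serum-K exponent in urinary K excretion
  b_na: 2.0             # serum-Na exponent in urinary Na excretion
  g_ald_K: 0.011316     # MR-signal gain on urinary K excretion
  g_ald_Na: 0.030516    # MR-signal gain on urinary Na retention
  k_exchange: 0.698256  # l/h intracellular-extracellular K exchange
  k_water: 0.242281     # 1/h ECF volume relaxation
  h_volume: 0.948963    # fraction of relative Na-pool change expressed as volume
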