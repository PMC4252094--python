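# Scenario catalogue

Shipped scenarios (run with `pseudoaldo simulate <name>`):

- `rat-gl-iv-10` (rat, pk): GL 10 mg/kg i.v., bile fistula — Shimamura et al. biliary excretion study
- `rat-gl-iv-25` (rat, pk): GL 25 mg/kg i.v. — Ichikawa et al. disposition study
- `rat-gl-iv-100` (rat, pk): GL 100 mg/kg i.v. — Ishida et al. kinetic study
- `rat-gl-po-100` (rat, pk): GL 100 mg/kg p.o. (GA appears via gut hydrolysis) — oral GL pharmacokinetic study
- `rat-ga-iv-5.7` (rat, pk): GA 5.7 mg/kg i.v., intact recirculation — Takeda et al. recirculation study
- `rat-ga-ip-25` (rat, pk): GA 25 mg/kg i.p., biliary conjugate excretion — Parke et al. biliary excretion study
- `human-gl-iv-40` (human, pk): GL 40 mg i.v. — Yamamura et al. i.v. study
- `human-gl-iv-80` (human, pk): GL 80 mg i.v. — Yamamura et al. i.v. study
- `human-gl-iv-120` (human, pk): GL 120 mg i.v. — Yamamura et al. i.v. study
- `human-ga-po-130` (human, pk): GA 130 mg single oral dose — Ploeger et al. volunteer study
- `human-ga-po-130x5` (human, pk): GA 130 mg/day for 5 days (accumulation) — Ploeger et al. multiple-dose study
- `human-gl-po-225` (human, pk): GL 225 mg single oral dose (pure compound) — Ploeger et al. licorice comparison
- `human-gl-po-225-licorice` (human, pk): licorice containing 225 mg GL (4-fold gut hydrolysis) — Ploeger et al. licorice comparison
- `ga-510-tid-2d` (human, pd): GA 170 mg 3x/day for 2 days: urinary cortisol:cortisone ratio (baseline 0.65, estimated day-2 ratio 2.0) — Palermo et al. urinary steroid study
- `ga-500-bid-7d` (human, cascade): GA 250 mg 2x/day for 7 days: full biomarker cascade (baselines: aldosterone 13.1 ng/dl, K 3.7, Na 141) — MacKenzie et al. volunteer study
- `gl-0.7g-7d` (human, cascade): GL 0.7 g/day for one week: RAAS suppression (baselines: aldosterone 21.5 ng/dl, angiotensin II 54.4 pg/ml) — Epstein et al. licorice consumption study
- `gl-1.4g-7d` (human, cascade): GL 1.4 g/day for one week: RAAS suppression — Epstein et al. licorice consumption study
- `gl-200-7d-sensitivity` (human, cascade): GL 200 mg/day for one week (sensitivity sweep base case) — one-at-a-time sensitivity analysis
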