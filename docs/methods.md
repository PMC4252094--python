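# Model and methods

`pseudoaldo` predicts the adverse mineralocorticoid effects of glycyrrhizin
(GL), the sweet triterpene glycoside of licorice. GL itself is pharmacologically
bland; its aglycone glycyrrhetic acid (GA), produced by gut-microbial
hydrolysis, inhibits renal 11β-hydroxysteroid dehydrogenase type 2 (11β-HSD2).
That enzyme normally protects the mineralocorticoid receptor (MR) from
cortisol; when it is inhibited, kidney cortisol rises, the MR is
over-activated, potassium is wasted, sodium and water are retained, and the
renin–angiotensin–aldosterone system (RAAS) is compensatorily suppressed —
pseudoaldosteronism. The package chains a rat and a human semi-physiological
pharmacokinetic (PBPK) model of GL/GA and their phase-II conjugates (GAM,
pooling 3-monoglucuronyl-GA with the GA glucuronides/sulfates), an 11β-HSD2
pharmacodynamic module, a reduced RAAS/electrolyte system, and a Monte Carlo
virtual-elderly-population engine that estimates the daily GL dose limit
producing hypokalemia (serum K 3.5 mmol/l on day 28).

## Pharmacokinetic structure

Both species share the topology: a vascular compartment (drug confined to
plasma; perfusion terms use plasma flows, `Q·(1−Hct)`), perfusion-limited
kidney and gut tissue with tissue:plasma partition coefficients `P_k`, `P_g`,
a lumped remaining tissue (distribution clearance `K_12_r` in, rate `K_21_r`
out), and a liver split into a sinusoidal (venous) and a tissue compartment.
Sinusoidal uptake is carrier-mediated: Michaelis–Menten on the unbound
sinusoidal concentration in rat (`V_max`, `K_m`), linearized to `CL_up` in
human. From liver tissue, drug leaves by sinusoidal efflux (`PS_eff`),
metabolism (`CL_met`; GL→GAM, GA→GAM, 1:1 molar) or biliary excretion
(saturable `V_max_B`/`K_m_B` in rat, linear `CL_b` in human; GL and GAM
only), each driven by the unbound tissue concentration (`f_ut`, obtained from
the plasma unbound fraction by the protein-dilution relation
`fu_t = 1/(1 + R(1−fu_p)/fu_p)`, R = 0.5 for lean tissue). Renal clearance is
negligible for all three species and is omitted.

The gut lumen is a transit chain — six segments in rat (stomach, duodenum,
jejunum, ileum, cecum, colon), three in human (stomach, small intestine,
colon). GL is hydrolyzed to GA by the microbiota (rat: cecum + colon; human:
colon; 4-fold faster from a whole-licorice matrix), GAM likewise. GA is
absorbed (rat small-intestinal segments and cecum/colon; human small
intestine and colon) into the portal stream; oral GL is not absorbed in rat,
while in human recycled GL is absorbed slowly from the small intestine. In
rat, bile reaches the duodenum through a first-order duct delay (1 h⁻¹); a
bile fistula diverts it to an external sink. In human, biliary output is
stored in the gallbladder and discharged completely into the small intestine
at meal times (default 0, 5 and 10 h of each day) — enterohepatic
recirculation is therefore meal-gated.

**Flow-equilibrium central pool.** The kidney, gut-tissue and sinusoidal
compartments have residence times of seconds (`P·V/Q` ≈ 1–4 ms·h⁻¹ scale),
thousands of times faster than any other process in the model. They are kept
at flow equilibrium with plasma and lumped with the vascular space into one
central amount; the sinusoidal concentration follows from its algebraic flux
balance (a quadratic closed form under Michaelis–Menten uptake, inverted by
a three-step damped fixed point; exact closed form in the linear human
model). All lumped amounts are reported in the output and enter the molar
mass balance, which holds to machine precision. This is what makes a
fixed-step fourth-order Runge–Kutta scheme at 0.01 h stable: the fastest
remaining mode is aldosterone turnover (18.67 h⁻¹).

Units: rat ml/µmol/h, human l/µmol/h. The published human table mixes units
(`CL_up`, `CL_b` in l/h; `K_12_r`, `CL_met`, `PS_eff` in ml/h, as they were
scaled from the rat ml/h values); configs store the published numbers and the
loader converts.

## Integration

Fixed-step classical RK4 with discrete events (doses, gallbladder emptying)
applied exactly on the grid; default step 0.01 h. The same kernel integrates
a whole batch of parameter sets at once (the Monte Carlo cohort is bisected
in one batched run per iteration). States are clamped at zero when a step
undershoots by less than 10⁻⁹ of the running peak; larger undershoot is an
error. A scipy adaptive solver (LSODA) over the same event segmentation is
the independent cross-check; fixed and adaptive solutions agree to <0.5% on
the validation scenarios, and halving the step changes outputs by <0.1%.
Long virtual-population runs use 0.05–0.1 h steps: the day-28 potassium and
the resulting dose limits are unchanged to <0.01 mg between 0.02 and 0.1 h
because the states that matter evolve on multi-hour scales.

## 11β-HSD2 module

Kidney cortisol `F_k` obeys `V_k·dF_k/dt = k_0 − (k_ox + k_ur_F)·F_k` with a
constant formation rate `k_0`; plasma cortisone `E` obeys
`V_app·dE/dt = k_ox·F_k − k_ur_E·E`. GA in kidney tissue (P_k × plasma)
reduces the oxidation clearance by the saturable law
`k_ox = k_ox0·(1 − C/(IC50 + C))`, IC50 = 0.000234 µmol/ml. Urinary cortisol
and cortisone are the integrals of `k_ur_F·F_k` and `k_ur_E·E`; their daily
ratio R is the standard biomarker (baseline 0.65).

Baselines are literature-sourced required inputs (defaults: plasma cortisol
100 µg/l, plasma cortisone 17 µg/l, kidney:plasma cortisol ratio 1.5, 24 h
urinary cortisol 84.5 µg and cortisone 130 µg). The clearances are derived so
that the drug-free system is an exact fixed point; this yields a normal-adult
`k_ox0` of 0.036 l/h, 1.8-fold the elderly value 0.02 l/h. A subject with a
different `k_ox0` keeps the population values of cortisol production and
urinary clearances, so a low-HSD2 (elderly) subject has a *higher* baseline
kidney cortisol and a higher plasma cortisol:cortisone ratio — the trait the
population model samples.

## MR activation and the reduced RAAS/electrolyte system

Aldosterone is released at `K_gen·(1 + S_max·s_K·s_AngII)` and eliminated
first order (`K_deg`), where `s_K` is a steep Hill function of serum
potassium (coefficient 9.97, SC50 4.577 mmol/l) and `s_AngII` a hyperbolic
function of angiotensin II (SC50 94.129 pg/ml); the two secretagogues
combine multiplicatively. At (K 3.7 mmol/l, AngII 54.4 pg/ml) the closed-form
steady state is 15.6 ng/dl, bracketing observed baselines; at (3.3, 32.4) it
is ≈6 ng/dl.

The MR signal combines aldosterone and kidney cortisol:

    ALD = [Aldo/Aldo0 + β·c(F_k)] / (1 + β),
    c(F) = (F/F_ref)^γ − (F_k0/F_ref)^γ + 1,

with β = 3 (cortisol carries three quarters of the baseline signal — in
pseudoaldosteronism hypokalemia develops *despite* suppressed aldosterone,
so the cortisol arm must dominate) and a convex transduction γ ≈ 3 referenced
to the normal-adult baseline `F_ref`. Convexity is what reproduces the
observed elderly susceptibility: a linear form (γ = 1) makes the fractional
cortisol rise — and hence the response — *smaller* in low-HSD2 subjects, in
conflict with the sensitivity analysis, and leaves the elderly population
without any finite hypokalemia dose limit. Each subject's own baseline is
subtracted inside `c`, so the drug-free state remains an exact fixed point
for every subject. With β = 1 (equal contribution) the same failure reappears
for the elderly; the acceptance-facing outputs (one-week biomarkers) move by
only a few percent between β = 2 and β = 5 once the gains are recalibrated,
because the calibration absorbs the scale of the signal.

The body-fluid/electrolyte reduction keeps one state per arrow of the causal
diagram: extracellular K and Na pools and volume, an intracellular K pool
(first-order exchange against its equilibrium share), renin activity and
angiotensin II. Volume expansion raises an arterial-pressure surrogate
(gain 2 per relative blood-volume change), which raises GFR and suppresses
renin (AngII tracks renin). Urinary potassium excretion scales as
`GFR·(K/K0)^b_k·(1 + g_K(ALD−1))`, urinary sodium as
`GFR·(Na/Na0)^b_Na·(1 − g_Na(ALD−1))`; intakes are constant (70 mmol K and
150 mmol Na per day). With no perturbation every state is constant by
construction (drift <0.1% over 28 days).

All reduction gains live in `data/electrolyte.yaml` and were calibrated
jointly — as the module's one calibration step — so that the model reproduces
the published one-week clinical deltas (GA 500 mg/day: K 3.7→3.3 mmol/l,
Na 141→142 mmol/l, aldosterone →5.8 ng/dl; GL 0.7/1.4 g/day: mean
angiotensin II 54.4→40 pg/ml) and so that the reference elderly subject's
28-day hypokalemia dose limit sits at the published population median
(≈280 mg/day). The calibrated model then predicts the *four-week* potassium
levels of the GL study (3.77 and 3.47 mmol/l at 0.7 and 1.4 g/day) within a
few percent of the published model predictions (3.7 and 3.3) without having
been fitted to them. The small serum-K exponent found by calibration
(b_k ≈ 0.35) encodes the clinical observation that mineralocorticoid-driven
kaliuresis persists in hypokalemia.

## Virtual elderly population

Three sensitivity factors per subject: a hepatic-uptake (OATP expression)
multiplier on `CL_up` of GL and GA, lognormal with median 1 and a 4.9-fold
95% range (σ = ln 4.9/3.92 = 0.406); the elderly colonic transit constant
`K_co`, bootstrap-resampled from a 16-value sample vector (synthetic,
centred on 0.0217 h⁻¹ — the cited transit-time sample is not published);
and the elderly `k_ox0`, truncated normal (0.02 ± 0.004 l/h, bounds at the
sample extremes, likewise synthetic stand-ins). Baseline serum potassium is
4.18 mmol/l (median of the 3.5–5.0 normal range).

Each subject's dose limit is found by bisection (geometric midpoints,
bracket 10–2000 mg/day, tolerance 1 mg) on the day-28 serum potassium under
daily oral GL; subjects whose potassium never crosses 3.5 mmol/l inside the
bracket are reported as censored rather than extrapolated. Dose limits are
summarized by the maximum-likelihood lognormal fit (μ, σ), the critical dose
at the maximum of the second derivative of the cumulative distribution
(closed form `exp(μ − uσ²)`, `u = (3 + √(1+4/σ²))/2`, cross-checked by grid
argmax), and exceedance probabilities `Φ((ln d − μ)/σ)`. With the published
fit (μ = 5.6348, σ = 0.5449) these give 3.07% at 101 mg, 3% at 100 mg, 27%
at 200 mg and a critical dose of ≈102 mg. A seeded n = 1000 cohort run takes
about a minute at a 0.1 h step and yields μ ≈ 5.63, σ ≈ 0.44, with the
critical dose stable to <5% across seeds; reproducing the published μ and σ
exactly is not possible from the published information because the
distribution hyperparameters derive from unpublished literature samples.

## What the synthetic fixtures do and do not show

The calibration datasets behind the PK parameters exist only as published
figures, so the fitting harness is exercised on synthetic fixtures:
simulate, sample at stated times, multiply by lognormal noise (CV 15%),
refit. Passing recovery tests (V_max, K_12_r, K_21_r within 20%) shows the
estimation machinery is unbiased and identifiable under the model's own
error structure — it does not validate the model against real plasma curves,
which is covered only qualitatively (topology, saturation direction,
recirculation effects, accumulation) here.

## Numerical and design choices

- Gut transit constants, bile-duct delay, i.p. depot rate and meal schedule
  are not published; defaults (rat K_st 2, K_sa=K_sb=K_sc 1.5, K_ce 0.25,
  K_co 0.15 h⁻¹; human K_st 2, K_s 0.25, K_co 0.04 h⁻¹ normal / 0.0217
  elderly; bile 1 h⁻¹; i.p. 2 h⁻¹; meals 0/5/10 h) are literature-informed,
  flagged in the configs and overridable.
- GAM has no published systemic parameters; it exists in liver, bile/
  gallbladder and gut lumen only, and dosing it directly is rejected.
- Molecular weights (GL 822.93, GA 470.68, GAM 646.81 g/mol) are
  formula-derived and stored in config.
- Gallbladder emptying is instantaneous and complete at each meal; meal
  times are recorded in every run manifest since they gate recirculation.
- Scenario outputs use 9-significant-digit fixed formatting so repeated runs
  are byte-identical.

## Known limitations

- No circadian cortisol rhythm and no adrenal feedback on cortisol
  production (`k_0` constant); urinary ratios therefore lack the observed
  day-to-day variability.
- The RAAS/electrolyte block is a deliberate minimal reduction: blood
  pressure is an internal surrogate, not a validated output; respiratory
  and anion balance are out of scope.
- The human hepatic handling is linear, so very high GL doses extrapolate
  without saturation.
- Population variability covers the three published sensitivity factors
  only; the bootstrap vector and truncation bounds are synthetic stand-ins
  for unpublished samples, so the fitted population σ is informative only
  about this configuration, not about the elderly population itself.
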