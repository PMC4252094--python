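"""Shipped simulation scenarios.

Each scenario reproduces one of the clinical or animal dosing situations the
model was built against, anchored to the original experimental datasets
(Ishida, Ichikawa, Takeda, Yamamura, Ploeger, MacKenzie, Palermo, Epstein).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import DoseRegimen


@dataclass(frozen=True)
class Scenario:
    """A named, runnable simulation setup."""

    name: str
    species: str
    regimen: DoseRegimen
    description: str
    reference: str
    kind: str = "pk"                 # pk | pd | cascade
    t_end: float | None = None
    baselines: dict = field(default_factory=dict)
    hsd2_kwargs: dict = field(default_factory=dict)


def _rat(name, desc, ref, **kw):
    return Scenario(name=name, species="rat", regimen=DoseRegimen(**kw),
                    description=desc, reference=ref)


def _human(name, desc, ref, kind="pk", t_end=None, baselines=None, hsd2_kwargs=None, **kw):
    return Scenario(name=name, species="human", regimen=DoseRegimen(**kw),
                    description=desc, reference=ref, kind=kind, t_end=t_end,
                    baselines=baselines or {}, hsd2_kwargs=hsd2_kwargs or {})


SCENARIOS: dict[str, Scenario] = {s.name: s for s in [
    # --- rat pharmacokinetics -------------------------------------------
    _rat("rat-gl-iv-10", "GL 10 mg/kg i.v., bile fistula",
         "Shimamura et al. biliary excretion study",
         compound="GL", route="iv", dose_amount=10.0, per_kg=True, bile_fistula=True),
    _rat("rat-gl-iv-25", "GL 25 mg/kg i.v.", "Ichikawa et al. disposition study",
         compound="GL", route="iv", dose_amount=25.0, per_kg=True),
    _rat("rat-gl-iv-100", "GL 100 mg/kg i.v.", "Ishida et al. kinetic study",
         compound="GL", route="iv", dose_amount=100.0, per_kg=True),
    _rat("rat-gl-po-100", "GL 100 mg/kg p.o. (GA appears via gut hydrolysis)",
         "oral GL pharmacokinetic study",
         compound="GL", route="po", dose_amount=100.0, per_kg=True),
    _rat("rat-ga-iv-5.7", "GA 5.7 mg/kg i.v., intact recirculation",
         "Takeda et al. recirculation study",
         compound="GA", route="iv", dose_amount=5.7, per_kg=True),
    _rat("rat-ga-ip-25", "GA 25 mg/kg i.p., biliary conjugate excretion",
         "Parke et al. biliary excretion study",
         compound="GA", route="ip", dose_amount=25.0, per_kg=True),
    # --- human pharmacokinetics -----------------------------------------
    _human("human-gl-iv-40", "GL 40 mg i.v.", "Yamamura et al. i.v. study",
           compound="GL", route="iv", dose_amount=40.0),
    _human("human-gl-iv-80", "GL 80 mg i.v.", "Yamamura et al. i.v. study",
           compound="GL", route="iv", dose_amount=80.0),
    _human("human-gl-iv-120", "GL 120 mg i.v.", "Yamamura et al. i.v. study",
           compound="GL", route="iv", dose_amount=120.0, t_end=48.0),
    _human("human-ga-po-130", "GA 130 mg single oral dose",
           "Ploeger et al. volunteer study",
           compound="GA", route="po", dose_amount=130.0, t_end=48.0),
    _human("human-ga-po-130x5", "GA 130 mg/day for 5 days (accumulation)",
           "Ploeger et al. multiple-dose study",
           compound="GA", route="po", dose_amount=130.0, n_days=5, t_end=144.0),
    _human("human-gl-po-225", "GL 225 mg single oral dose (pure compound)",
           "Ploeger et al. licorice comparison",
           compound="GL", route="po", dose_amount=225.0, t_end=72.0),
    _human("human-gl-po-225-licorice",
           "licorice containing 225 mg GL (4-fold gut hydrolysis)",
           "Ploeger et al. licorice comparison",
           compound="GL", route="po", dose_amount=225.0, licorice_matrix=True, t_end=72.0),
    # --- pharmacodynamic scenarios --------------------------------------
    _human("ga-510-tid-2d", "GA 170 mg 3x/day for 2 days: urinary "
           "cortisol:cortisone ratio (baseline 0.65, estimated day-2 ratio 2.0)",
           "Palermo et al. urinary steroid study", kind="pd",
           compound="GA", route="po", dose_amount=170.0,
           dose_times=(0.0, 5.0, 10.0), n_days=2, t_end=48.0),
    _human("ga-500-bid-7d", "GA 250 mg 2x/day for 7 days: full biomarker "
           "cascade (baselines: aldosterone 13.1 ng/dl, K 3.7, Na 141)",
           "MacKenzie et al. volunteer study", kind="cascade",
           compound="GA", route="po", dose_amount=250.0,
           dose_times=(0.0, 10.0), n_days=7, t_end=168.0,
           baselines={"K_serum0": 3.7, "Na_serum0": 141.0, "AngII0": 54.4,
                      "Aldo_init": 13.1}),
    _human("gl-0.7g-7d", "GL 0.7 g/day for one week: RAAS suppression "
           "(baselines: aldosterone 21.5 ng/dl, angiotensin II 54.4 pg/ml)",
           "Epstein et al. licorice consumption study", kind="cascade",
           compound="GL", route="po", dose_amount=700.0, n_days=7, t_end=168.0,
           baselines={"K_serum0": 4.1, "Na_serum0": 141.0, "AngII0": 54.4,
                      "Aldo_init": 21.5}),
    _human("gl-1.4g-7d", "GL 1.4 g/day for one week: RAAS suppression",
           "Epstein et al. licorice consumption study", kind="cascade",
           compound="GL", route="po", dose_amount=1400.0, n_days=7, t_end=168.0,
           baselines={"K_serum0": 4.0, "Na_serum0": 141.0, "AngII0": 54.4,
                      "Aldo_init": 21.5}),
    _human("gl-200-7d-sensitivity", "GL 200 mg/day for one week (sensitivity "
           "sweep base case)", "one-at-a-time sensitivity analysis", kind="cascade",
           compound="GL", route="po", dose_amount=200.0, n_days=7, t_end=168.0,
           baselines={"K_serum0": 4.18}),
]}


def list_scenarios() -> list[dict]:
    """Catalogue of shipped scenarios (name, species, kind, description,
    reference)."""
    return [{"name": s.name, "species": s.species, "kind": s.kind,
             "description": s.description, "reference": s.reference}
            for s in SCENARIOS.values()]
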