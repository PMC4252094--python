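"""Typed, validated parameter configuration for the glycyrrhizin PBPK/PD model.

Every published parameter (compound kinetics per species, physiology,
pharmacodynamic constants, population-variability hyperparameters) lives in
YAML files under :mod:`pseudoaldo.data` and is loaded into frozen dataclasses
here. Configs store values in their published units; unit conversion to the
internal model units (rat: ml/umol/h, human: l/umol/h) happens in the model
builders via :meth:`CompoundParams.model_values`.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

COMPOUNDS = ("GL", "GA", "GAM")
SPECIES = ("rat", "human")
ROUTES = ("iv", "po", "ip")

#: Human compound-table fields printed in ml/h (scaled from the rat ml/h
#: values); converted to l/h for the litre-based human model.
HUMAN_ML_PER_H_FIELDS = ("K_12_r", "CL_met", "PS_eff")

#: Numeric CompoundParams fields by category, used for validation.
_FRACTION_FIELDS = ("f_u", "f_ut", "hematocrit")
_NONNEG_FIELDS = (
    "K_12_r", "K_21_r", "V_max", "K_m", "V_max_B", "K_m_B", "CL_met",
    "CL_up", "CL_b", "PS_eff", "P_k", "P_g", "K_abs_si", "K_abs_co",
    "KH_ce", "KH_co", "molecular_weight",
)


class ParameterError(ValueError):
    """A configuration value violates the schema; the message names the field."""


def fu_tissue(fu_p: float, R: float = 0.5) -> float:
    """Unbound tissue fraction from the unbound plasma fraction.

    Uses the plasma-protein dilution relation

        fu_t = 1 / (1 + R * (1 - fu_p) / fu_p)

    where ``R`` is the tissue interstitial-fluid to plasma ratio of albumin
    and lipoproteins (0.5 for lean tissues, 0.15 for adipose). Reproduces the
    published (f_u, f_ut) pairs for GL and GA in both species.
    """
    if not 0.0 < fu_p <= 1.0:
        raise ParameterError(f"fu_p must be in (0, 1], got {fu_p}")
    if R <= 0:
        raise ParameterError(f"R must be positive, got {R}")
    return 1.0 / (1.0 + R * (1.0 - fu_p) / fu_p)


@dataclass(frozen=True)
class CompoundParams:
    """Per-compound, per-species kinetic constants.

    Values are stored in published units: rat clearances ml/h, human CL_up
    and CL_b l/h, human K_12_r/CL_met/PS_eff ml/h (see module docstring),
    Michaelis constants umol/ml of unbound concentration, all first-order
    constants 1/h.
    """

    compound: str
    species: str
    f_ut: float
    hematocrit: float
    molecular_weight: float
    f_u: float | None = None
    K_12_r: float | None = None
    K_21_r: float | None = None
    V_max: float | None = None
    K_m: float | None = None
    V_max_B: float | None = None
    K_m_B: float | None = None
    CL_met: float | None = None
    CL_up: float | None = None
    CL_b: float | None = None
    PS_eff: float | None = None
    P_k: float | None = None
    P_g: float | None = None
    K_abs_si: float | None = None
    K_abs_co: float | None = None
    KH_ce: float | None = None
    KH_co: float | None = None

    def __post_init__(self) -> None:
        if self.compound not in COMPOUNDS:
            raise ParameterError(f"compound must be one of {COMPOUNDS}, got {self.compound!r}")
        if self.species not in SPECIES:
            raise ParameterError(f"species must be one of {SPECIES}, got {self.species!r}")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if v is not None and not 0.0 < v <= 1.0:
                raise ParameterError(f"{self.compound}.{name} must be in (0, 1], got {v}")
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ParameterError(f"{self.compound}.{name} must be >= 0, got {v}")
        if self.f_u is not None:
            expected = fu_tissue(self.f_u, 0.5)
            if abs(expected - self.f_ut) > 0.05 * expected:
                raise ParameterError(
                    f"{self.compound}.f_ut={self.f_ut} inconsistent with binding "
                    f"relation from f_u={self.f_u} (expected ~{expected:.4g})"
                )

    def model_values(self) -> dict[str, float]:
        """Parameters in internal model units (0.0 for absent processes).

        Rat: ml, umol, h as published. Human: l, umol, h — the ml/h-published
        fields are divided by 1000.
        """
        out: dict[str, float] = {}
        for name in _NONNEG_FIELDS + _FRACTION_FIELDS:
            v = getattr(self, name)
            if v is None:
                v = 0.0
            elif self.species == "human" and name in HUMAN_ML_PER_H_FIELDS:
                v = v / 1000.0
            out[name] = float(v)
        return out


@dataclass(frozen=True)
class Physiology:
    """Organ volumes, blood flows and gut transit constants for one species.

    Volumes/flows in ml and ml/h (rat) or l and l/h (human). ``transit`` maps
    segment constants (1/h): rat ``K_st, K_sa, K_sb, K_sc, K_ce, K_co``;
    human ``K_st, K_s, K_co``.
    """

    species: str
    body_weight: float
    volumes: Mapping[str, float]
    flows: Mapping[str, float]
    transit: Mapping[str, float]
    meal_times: tuple[float, ...] = ()
    bile_transit: float = 1.0
    ip_absorption: float = 2.0

    _RAT_TRANSIT = ("K_st", "K_sa", "K_sb", "K_sc", "K_ce", "K_co")
    _HUMAN_TRANSIT = ("K_st", "K_s", "K_co")

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ParameterError(f"species must be one of {SPECIES}")
        for group, vals in (("volumes", self.volumes), ("flows", self.flows)):
            for k, v in vals.items():
                if v <= 0:
                    raise ParameterError(f"physiology.{group}.{k} must be > 0, got {v}")
        for k in ("liver", "guts", "kidneys", "liver_venous", "vascular"):
            if k not in self.volumes:
                raise ParameterError(f"physiology.volumes missing required key {k!r}")
        for k in ("hepatic_artery", "portal_vein", "kidney"):
            if k not in self.flows:
                raise ParameterError(f"physiology.flows missing required key {k!r}")
        required = self._RAT_TRANSIT if self.species == "rat" else self._HUMAN_TRANSIT
        for k in required:
            if k not in self.transit:
                raise ParameterError(
                    f"physiology.transit missing required constant {k!r} "
                    "(gut transit constants are a required config input)"
                )
            if self.transit[k] <= 0:
                raise ParameterError(f"physiology.transit.{k} must be > 0")

    @property
    def liver_blood_flow(self) -> float:
        """Total liver inflow: hepatic artery plus portal vein."""
        return self.flows["hepatic_artery"] + self.flows["portal_vein"]


@dataclass(frozen=True)
class DoseRegimen:
    """A dosing schedule for one compound.

    ``dose_amount`` is mg (human) or mg/kg (rat, ``per_kg=True``);
    ``dose_times`` are hours within each simulated day, repeated for
    ``n_days``. ``meal_times`` trigger human gallbladder emptying (``None``
    means use the physiology default). ``bile_fistula`` diverts biliary
    output to an external sink (disables recirculation); ``licorice_matrix``
    multiplies the GL gut hydrolysis constant by 4 (whole-licorice dosing).
    """

    compound: str
    route: str
    dose_amount: float
    dose_times: tuple[float, ...] = (0.0,)
    n_days: int = 1
    per_kg: bool = False
    meal_times: tuple[float, ...] | None = None
    bile_fistula: bool = False
    licorice_matrix: bool = False

    def __post_init__(self) -> None:
        if self.compound not in COMPOUNDS:
            raise ParameterError(f"regimen.compound must be one of {COMPOUNDS}")
        if self.route not in ROUTES:
            raise ParameterError(f"regimen.route must be one of {ROUTES}")
        if self.dose_amount < 0:
            raise ParameterError(f"regimen.dose_amount must be >= 0, got {self.dose_amount}")
        if self.n_days < 1:
            raise ParameterError("regimen.n_days must be >= 1")
        for t in self.dose_times:
            if not 0.0 <= t < 24.0:
                raise ParameterError(f"regimen.dose_times must lie within a day, got {t}")
        if self.meal_times is not None:
            for t in self.meal_times:
                if not 0.0 <= t < 24.0:
                    raise ParameterError(f"regimen.meal_times must lie within a day, got {t}")
        if self.licorice_matrix and not (self.compound == "GL" and self.route == "po"):
            raise ParameterError("licorice_matrix applies only to oral GL regimens")

    def dose_umol(self, molecular_weight: float, body_weight_kg: float = 1.0) -> float:
        """Single-administration dose in umol."""
        mg = self.dose_amount * (body_weight_kg if self.per_kg else 1.0)
        return mg / molecular_weight * 1000.0


@dataclass(frozen=True)
class ModelConfig:
    """A full per-species parameter set: physiology plus compound kinetics."""

    species: str
    physiology: Physiology
    compounds: Mapping[str, CompoundParams]
    raw: dict = field(repr=False, default_factory=dict)

    def compound(self, name: str) -> CompoundParams:
        try:
            return self.compounds[name]
        except KeyError:
            raise ParameterError(f"no parameters for compound {name!r} in {self.species} config")


_COMPOUND_FIELDS = set(_NONNEG_FIELDS) | set(_FRACTION_FIELDS)


def _build_config(doc: dict, origin: str) -> ModelConfig:
    try:
        species = doc["species"]
        phys_doc = doc["physiology"]
        comp_doc = doc["compounds"]
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"{origin}: missing required section {exc}") from None
    extras = doc.get("extras", {})
    phys = Physiology(
        species=species,
        body_weight=float(phys_doc["body_weight"]),
        volumes={k: float(v) for k, v in phys_doc["volumes"].items()},
        flows={k: float(v) for k, v in phys_doc["flows"].items()},
        transit={k: float(v) for k, v in phys_doc["transit"].items()},
        meal_times=tuple(phys_doc.get("meal_times", ())),
        bile_transit=float(extras.get("bile_transit", 1.0)),
        ip_absorption=float(extras.get("ip_absorption", 2.0)),
    )
    compounds = {}
    for name, values in comp_doc.items():
        unknown = set(values) - _COMPOUND_FIELDS
        if unknown:
            raise ParameterError(f"{origin}: unknown field(s) {sorted(unknown)} for compound {name}")
        compounds[name] = CompoundParams(compound=name, species=species, **values)
    return ModelConfig(species=species, physiology=phys, compounds=compounds, raw=doc)


def default_config_path(name: str) -> Path:
    """Path of a shipped default config (``rat``, ``human``, ``pd``, ...)."""
    return Path(str(resources.files("pseudoaldo").joinpath(f"data/{name}.yaml")))


def load_parameters(path: str | Path | None = None, species: str | None = None) -> ModelConfig:
    """Load and validate a species parameter file.

    With no ``path``, loads the shipped default for ``species``. Raises
    :class:`ParameterError` naming the offending field on any schema
    violation.
    """
    if path is None:
        if species is None:
            raise ParameterError("either path or species is required")
        path = default_config_path(species)
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _build_config(doc, origin=str(path))


def save_parameters(config: ModelConfig, path: str | Path) -> None:
    """Write a parameter set back to YAML (lossless round-trip of the raw doc)."""
    doc = config.raw
    if not doc:
        doc = {
            "species": config.species,
            "physiology": {
                "body_weight": config.physiology.body_weight,
                "volumes": dict(config.physiology.volumes),
                "flows": dict(config.physiology.flows),
                "transit": dict(config.physiology.transit),
                "meal_times": list(config.physiology.meal_times),
            },
            "compounds": {
                n: {k: v for k, v in asdict(c).items()
                    if k in _COMPOUND_FIELDS and v is not None}
                for n, c in config.compounds.items()
            },
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_yaml(name_or_path: str | Path) -> dict:
    """Load one of the shipped auxiliary configs (``pd``, ``electrolyte``,
    ``vpop``) by name, or any YAML file by path."""
    p = Path(name_or_path)
    if not p.exists():
        p = default_config_path(str(name_or_path))
    if not p.exists():
        raise ParameterError(f"config not found: {name_or_path}")
    with open(p) as fh:
        return yaml.safe_load(fh)
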