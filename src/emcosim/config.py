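"""Run configuration: schema-validated YAML/JSON documents.

A RunConfig names a population (bundled fixture or inline layer table),
simulation length and mode, coupling constants, stimulus-calibration
settings, metabolic parameter overrides and ageing profiles.  Unknown keys
are rejected; the resolved configuration hash is recorded in every results
container for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from .ageing import AGED_DEFAULT, YOUNG, AgeingProfile
from .circuit import LayerSpec, PopulationSpec, fixture_population
from .coupling import CouplingConstants
from .metabolism import MetabolicParams

__all__ = ["RunConfig", "ConfigError", "load_config", "resolved_params_doc"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class CalibrationConfig:
    enabled: bool = True
    band: Tuple[float, float] = (1.0, 10.0)  # Hz
    budget: int = 6

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ConfigError("calibration budget must be >= 1")
        if not self.band[0] < self.band[1]:
            raise ConfigError("calibration band must be (low, high)")


@dataclass(frozen=True)
class RunConfig:
    population: str = "medium"  # fixture name
    population_spec: Optional[PopulationSpec] = None  # overrides `population`
    T: float = 3000.0  # ms
    mode: str = "coupled"  # coupled | fixed_atp
    seed: int = 0
    t_coupling: float = 100.0  # ms
    dt_ephys: float = 0.025  # ms
    record_stride: float = 0.5  # ms
    workers: int = 1
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    metabolic_overrides: Dict[str, float] = field(default_factory=dict)
    ageing_profile: str = "aged"
    profiles: Dict[str, AgeingProfile] = field(default_factory=dict)
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("coupled", "fixed_atp"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.T <= 0 or self.T % self.t_coupling:
            raise ConfigError("T must be a positive multiple of t_coupling")
        bad = [k for k in self.metabolic_overrides
               if k not in {f.name for f in dataclasses.fields(MetabolicParams)}]
        if bad:
            raise ConfigError(f"unknown metabolic parameter(s): {bad}")

    # -- resolution helpers --------------------------------------------------

    def resolve_population_spec(self) -> PopulationSpec:
        if self.population_spec is not None:
            return self.population_spec
        return fixture_population(self.population)

    def resolve_met_params(self) -> MetabolicParams:
        return dataclasses.replace(MetabolicParams(), **self.metabolic_overrides)

    def resolve_coupling(self) -> CouplingConstants:
        return CouplingConstants(t_coupling=self.t_coupling,
                                 dt_ephys=self.dt_ephys, dt_met=self.t_coupling)

    def resolve_profile(self, name: Optional[str] = None) -> AgeingProfile:
        name = name or self.ageing_profile
        if name in self.profiles:
            return self.profiles[name]
        if name == "young":
            return YOUNG
        if name == "aged":
            return AGED_DEFAULT
        raise ConfigError(f"unknown ageing profile {name!r}")

    def to_dict(self) -> dict:
        d = {
            "population": self.population,
            "T": self.T, "mode": self.mode, "seed": self.seed,
            "t_coupling": self.t_coupling, "dt_ephys": self.dt_ephys,
            "record_stride": self.record_stride, "workers": self.workers,
            "calibration": {"enabled": self.calibration.enabled,
                            "band": list(self.calibration.band),
                            "budget": self.calibration.budget},
            "metabolic_overrides": dict(sorted(self.metabolic_overrides.items())),
            "ageing_profile": self.ageing_profile,
            "profiles": {k: dataclasses.asdict(v)
                         for k, v in sorted(self.profiles.items())},
            "output": self.output,
        }
        if self.population_spec is not None:
            d["population_spec"] = json.loads(json.dumps(
                dataclasses.asdict(self.population_spec)))
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


_TOP_KEYS = {"population", "population_spec", "T", "mode", "seed", "t_coupling",
             "dt_ephys", "record_stride", "workers", "calibration",
             "metabolic_overrides", "ageing_profile", "profiles", "output"}


def _parse_population_spec(doc: dict) -> PopulationSpec:
    keys = set(doc) - {"total", "layers", "seed", "name", "area_sigma"}
    if keys:
        raise ConfigError(f"unknown population_spec keys: {sorted(keys)}")
    layers = tuple(LayerSpec(**ld) for ld in doc["layers"])
    return PopulationSpec(total=doc["total"], layers=layers,
                          seed=doc.get("seed", 0), name=doc.get("name", "custom"),
                          area_sigma=doc.get("area_sigma", 0.25))


def load_config(path_or_doc) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Accepts a file path or an already-parsed mapping.  Unknown keys raise
    :class:`ConfigError`.
    """
    if isinstance(path_or_doc, dict):
        doc = dict(path_or_doc)
    else:
        with open(path_or_doc) as fh:
            doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")

    kwargs = {k: doc[k] for k in doc
              if k in _TOP_KEYS - {"calibration", "profiles", "population_spec"}}
    if "calibration" in doc:
        cal = dict(doc["calibration"])
        extra = set(cal) - {"enabled", "band", "budget"}
        if extra:
            raise ConfigError(f"unknown calibration key(s): {sorted(extra)}")
        if "band" in cal:
            cal["band"] = tuple(float(x) for x in cal["band"])
        kwargs["calibration"] = CalibrationConfig(**cal)
    if "profiles" in doc:
        profs = {}
        for name, pd_ in doc["profiles"].items():
            profs[name] = AgeingProfile(name=name, **pd_)
        kwargs["profiles"] = profs
    if "population_spec" in doc:
        kwargs["population_spec"] = _parse_population_spec(doc["population_spec"])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def resolved_params_doc(cfg: RunConfig) -> dict:
    """Fully resolved parameter document for provenance (``--dump-params``).

    Includes the printed vascular constants as stated by the source model
    ("blood volume of 0.023 ml/min") together with the interpretation used
    here (a fixed volume in ml).
    """
    met = cfg.resolve_met_params()
    return {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "metabolic_params": dataclasses.asdict(met),
        "coupling_constants": {
            "a_tot": cfg.resolve_coupling().a_tot,
            "q_ak": cfg.resolve_coupling().q_ak,
            "t_coupling": cfg.t_coupling,
            "dt_ephys": cfg.dt_ephys,
        },
        "vascular_provenance": {
            "blood_flow_printed": "0.0001 ml/min",
            "blood_volume_printed": "0.023 ml/min",
            "blood_volume_interpreted_as": "0.023 ml (fixed volume)",
        },
    }
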