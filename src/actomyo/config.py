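"""Scenario configuration: named presets and YAML round-tripping.

A Scenario bundles everything needed to reproduce a run: parameter
overrides on top of the reference ParameterSet, the domain, the initial
orientation bias, the schedule, and the seed.  Presets cover the studied
conditions at full scale and at a reduced "mini" scale (domain and budgets
shrunk proportionally, densities unchanged).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .integrator import StepSchedule
from .kinetics import MotorRateModel
from .params import Domain, ParameterSet


@dataclasses.dataclass
class Scenario:
    name: str = "custom"
    domain: tuple = (4000.0, 8000.0, 500.0)
    overrides: dict = dataclasses.field(default_factory=dict)
    orientation: str = "isotropic"
    duration: float = 50.0
    record_dt: float = 0.5
    kinetics_interval: int = 40
    seed: int = 0
    assembly_time: float = 0.5
    motor_variant: str = "reference"   # "reference" | "modified"

    def params(self) -> ParameterSet:
        return ParameterSet(**self.overrides)

    def domain_obj(self) -> Domain:
        return Domain(*[float(v) for v in self.domain])

    def motor_model(self, params: ParameterSet) -> MotorRateModel:
        if self.motor_variant == "modified":
            return MotorRateModel.modified(params)
        return MotorRateModel.from_params(params)

    def schedule(self) -> StepSchedule:
        p = self.params()
        return StepSchedule(dt=p.dt, duration=self.duration,
                            kinetics_interval=self.kinetics_interval,
                            record_interval=max(1, int(round(self.record_dt / p.dt))))

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["domain"] = list(self.domain)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        d = dict(d)
        if "domain" in d:
            d["domain"] = tuple(float(v) for v in d["domain"])
        sc = cls(**d)
        sc.params()          # validate overrides eagerly
        sc.domain_obj()
        return sc

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "Scenario":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("scenario YAML must map keys to values")
        return cls.from_dict(data)


_MINI_DOMAIN = (1000.0, 2000.0, 150.0)

PRESETS = {
    # full-scale reference condition: C_A = 40 uM, R_M = 0.08, R_ACP = 0.02
    "reference": dict(domain=(4000.0, 8000.0, 500.0),
                      overrides=dict(r_motor=0.08, r_acp=0.02), duration=50.0),
    # reduced-scale variants (same densities, smaller domain, shorter runs)
    "reference-mini": dict(domain=_MINI_DOMAIN,
                           overrides=dict(r_motor=0.08, r_acp=0.02),
                           duration=3.0, record_dt=0.1),
    "low-acp-mini": dict(domain=_MINI_DOMAIN,
                         overrides=dict(r_motor=0.08, r_acp=0.01),
                         duration=6.0, record_dt=0.1),
    "high-acp-mini": dict(domain=_MINI_DOMAIN,
                          overrides=dict(r_motor=0.08, r_acp=0.1),
                          duration=6.0, record_dt=0.1),
    "low-motor-mini": dict(domain=_MINI_DOMAIN,
                           overrides=dict(r_motor=0.02, r_acp=0.01),
                           duration=6.0, record_dt=0.1),
    # buckling suppressed via 100x bending stiffness
    "stiff-filament-mini": dict(domain=_MINI_DOMAIN,
                                overrides=dict(r_motor=0.08, r_acp=0.1,
                                               kb_actin=100 * ParameterSet().kb_actin),
                                duration=3.0, record_dt=0.1),
    # orientation-biased networks
    "plus-y-mini": dict(domain=_MINI_DOMAIN, orientation="+y",
                        overrides=dict(r_motor=0.08, r_acp=0.01),
                        duration=3.0, record_dt=0.1),
    # actin turnover at k_t = 60 1/s with different depolymerization inhibition
    "turnover-xi00-mini": dict(domain=_MINI_DOMAIN,
                               overrides=dict(r_motor=0.08, r_acp=0.01,
                                              k_turnover=60.0, xi_depoly=0.0),
                               # window covers a full filament turnover (~10 s)
                               duration=12.0, record_dt=0.2),
    "turnover-xi06-mini": dict(domain=_MINI_DOMAIN,
                               overrides=dict(r_motor=0.08, r_acp=0.01,
                                              k_turnover=60.0, xi_depoly=0.6),
                               # window covers a full filament turnover (~10 s)
                               duration=12.0, record_dt=0.2),
    "turnover-xi10-mini": dict(domain=_MINI_DOMAIN,
                               overrides=dict(r_motor=0.08, r_acp=0.01,
                                              k_turnover=60.0, xi_depoly=1.0),
                               # window covers a full filament turnover (~10 s)
                               duration=12.0, record_dt=0.2),
    # lower-duty-ratio motor variant (stall 5.3 pN, unbinding 0.49 1/s)
    "modified-motor-mini": dict(domain=_MINI_DOMAIN,
                                overrides=dict(r_motor=0.08, r_acp=0.02),
                                motor_variant="modified",
                                duration=3.0, record_dt=0.1),
}


def get_scenario(name: str, **changes) -> Scenario:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(changes)
    return Scenario(name=name, **kwargs)
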