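"""Run configuration: YAML schema, validation and unit normalisation.

A configuration file fully determines a pipeline run; the parameter echo
written next to the results is itself a valid configuration, so any run
can be reproduced bit-for-bit from its own output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import IdealizedBrainSpec
from .parameters import (
    OedemaParameters,
    PerfusionParameters,
    NumericalControls,
    Schedule,
    MMHG,
)

PRESETS = ("single", "abp_sweep", "lp_sweep", "oedema_types")

#: physical-quantity unit tables: target SI value = value * factor
_UNIT_FACTORS = {
    "pressure": {"Pa": 1.0, "kPa": 1000.0, "mmHg": MMHG},
    "hydraulic_permeability": {
        "m/(s*Pa)": 1.0,
        "m/s/Pa": 1.0,
        "cm/(s*mmHg)": 1e-2 / MMHG,
    },
    "permeability": {"mm^3*s/kg": 1.0, "mm3*s/kg": 1.0},  # table unit, kept as-is
}

_PRESSURE_KEYS = {"p_a_cortex", "p_v_cortex", "p_w_boundary", "Pi_c"}
_LP_KEYS = {"L_p"}
_PERM_KEYS = {"K_a", "K_c", "K_v", "K_w"}


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


@dataclass
class RunConfig:
    geometry: IdealizedBrainSpec = field(default_factory=IdealizedBrainSpec)
    geometry_path: str | None = None
    params: OedemaParameters = field(default_factory=OedemaParameters)
    occlusion: tuple = ("right_hemispheric",)
    schedule: Schedule = field(default_factory=Schedule)
    controls: NumericalControls = field(default_factory=NumericalControls)
    preset: str = "single"
    contact: bool = True
    core_threshold: float = 0.7
    mls_mode: str = "signed"
    outdir: str = "poroedema_out"
    seed: int = 0

    def echo(self) -> dict:
        d = {
            "geometry": dataclasses.asdict(self.geometry) if self.geometry_path is None
            else {"load": self.geometry_path},
            "parameters": _params_echo(self.params),
            "occlusion": list(self.occlusion),
            "schedule": dataclasses.asdict(self.schedule),
            "controls": dataclasses.asdict(self.controls),
            "preset": self.preset,
            "contact": self.contact,
            "core_threshold": self.core_threshold,
            "mls_mode": self.mls_mode,
            "outdir": self.outdir,
            "seed": self.seed,
        }
        return d


def _params_echo(p: OedemaParameters) -> dict:
    d = dataclasses.asdict(p)
    pf = d.pop("perfusion")
    d.update({f"perfusion.{k}": v for k, v in pf.items()})
    return d


def _convert(key: str, raw, errors) -> float | None:
    """Normalise a scalar that may carry an explicit unit."""
    if isinstance(raw, dict):
        if set(raw) != {"value", "unit"}:
            errors.append(f"parameter {key}: expected {{value, unit}}, got {sorted(raw)}")
            return None
        value, unit = raw["value"], str(raw["unit"])
        if key in _PRESSURE_KEYS:
            table = _UNIT_FACTORS["pressure"]
        elif key in _LP_KEYS:
            table = _UNIT_FACTORS["hydraulic_permeability"]
        elif key in _PERM_KEYS:
            table = _UNIT_FACTORS["permeability"]
        else:
            errors.append(f"parameter {key} does not accept a unit field")
            return None
        if unit not in table:
            errors.append(f"parameter {key}: unknown unit {unit!r} (known: {sorted(table)})")
            return None
        return float(value) * table[unit]
    try:
        return float(raw)
    except (TypeError, ValueError):
        errors.append(f"parameter {key}: not a number: {raw!r}")
        return None


def parse_config(data: dict) -> RunConfig:
    """Build a validated RunConfig from a plain dict (already-parsed YAML)."""
    errors = []
    data = dict(data or {})
    cfg = RunConfig()

    known_top = {"geometry", "parameters", "occlusion", "schedule", "controls",
                 "preset", "contact", "core_threshold", "mls_mode", "outdir", "seed"}
    for k in data:
        if k not in known_top:
            errors.append(f"unknown top-level key {k!r}")

    geo = dict(data.get("geometry") or {})
    if "load" in geo:
        cfg.geometry_path = str(geo.pop("load"))
        if geo:
            errors.append("geometry: 'load' cannot be combined with spec fields")
    else:
        spec_fields = {f.name for f in dataclasses.fields(IdealizedBrainSpec)}
        for k in list(geo):
            if k not in spec_fields:
                errors.append(f"geometry: unknown key {k!r}")
                geo.pop(k)
        if "sectors" in geo:
            geo["sectors"] = tuple(tuple(s) for s in geo["sectors"])
        try:
            cfg.geometry = IdealizedBrainSpec(**geo)
            cfg.geometry.validate()
        except Exception as e:
            errors.append(f"geometry: {e}")

    par = dict(data.get("parameters") or {})
    oed_fields = {f.name for f in dataclasses.fields(OedemaParameters)} - {"perfusion"}
    pf_fields = {f.name for f in dataclasses.fields(PerfusionParameters)}
    oed_kw, pf_kw = {}, {}
    for k, v in par.items():
        base = k.split(".", 1)[1] if k.startswith("perfusion.") else k
        if base in pf_fields:
            tgt, name = pf_kw, base
        elif base in oed_fields:
            tgt, name = oed_kw, base
        else:
            errors.append(f"parameters: unknown key {k!r}")
            continue
        if isinstance(v, bool) or name in ("anisotropic", "clamp_starling"):
            tgt[name] = bool(v)
        else:
            c = _convert(name, v, errors)
            if c is not None:
                tgt[name] = c
    try:
        cfg.params = OedemaParameters(**oed_kw, perfusion=PerfusionParameters(**pf_kw))
        cfg.params.validate()
    except Exception as e:
        errors.append(f"parameters: {e}")

    if "occlusion" in data:
        occ = data["occlusion"] or []
        if not isinstance(occ, (list, tuple)):
            errors.append("occlusion must be a list of territory names")
        else:
            cfg.occlusion = tuple(str(t) for t in occ)

    sch = dict(data.get("schedule") or {})
    sch_fields = {f.name for f in dataclasses.fields(Schedule)}
    for k in list(sch):
        if k not in sch_fields:
            errors.append(f"schedule: unknown key {k!r}")
            sch.pop(k)
    if "abp_mmhg" in sch:
        sch["abp_mmhg"] = tuple(float(v) for v in sch["abp_mmhg"])
    try:
        cfg.schedule = Schedule(**sch)
        cfg.schedule.validate()
    except Exception as e:
        errors.append(f"schedule: {e}")

    ctl = dict(data.get("controls") or {})
    ctl_fields = {f.name for f in dataclasses.fields(NumericalControls)}
    for k in list(ctl):
        if k not in ctl_fields:
            errors.append(f"controls: unknown key {k!r}")
            ctl.pop(k)
    try:
        cfg.controls = NumericalControls(**ctl)
    except Exception as e:
        errors.append(f"controls: {e}")

    cfg.preset = str(data.get("preset", cfg.preset))
    if cfg.preset not in PRESETS:
        errors.append(f"preset must be one of {PRESETS}, got {cfg.preset!r}")
    cfg.contact = bool(data.get("contact", True))
    cfg.core_threshold = float(data.get("core_threshold", 0.7))
    if not (0 < cfg.core_threshold < 1):
        errors.append("core_threshold must be in (0, 1)")
    cfg.mls_mode = str(data.get("mls_mode", "signed"))
    if cfg.mls_mode not in ("signed", "magnitude"):
        errors.append("mls_mode must be 'signed' or 'magnitude'")
    cfg.outdir = str(data.get("outdir", cfg.outdir))
    cfg.seed = int(data.get("seed", 0))

    if errors:
        raise ConfigError(errors)
    return cfg


def validate_config(path) -> RunConfig:
    """Parse + schema-check a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return parse_config(data)
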