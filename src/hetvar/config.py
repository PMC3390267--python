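"""Run configuration: plain-text (YAML) parsing with collected validation errors.

The scenario grid and engine options are too wide for command-line flags, so
every subcommand accepts a config file; flags override single keys.  Unknown
keys are rejected (typo safety) and all validation errors are reported at
once, never one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .montecarlo import ScenarioGrid
from .reml import REMLOptions
from .simulate import GeneticParameters, SimulationDesign
from .step1 import EditRules, Step1ModelSpec

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]

_SECTIONS = {"seed", "out_dir", "design", "genetic", "edit", "step1", "step2", "engine", "paths", "mc"}


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "hetvar_out"
    design: SimulationDesign = field(default_factory=SimulationDesign)
    genetic: GeneticParameters = field(default_factory=GeneticParameters)
    edit: EditRules = field(default_factory=EditRules)
    step1: Step1ModelSpec = field(default_factory=Step1ModelSpec)
    step2_transform: str = "log"
    step2_maternal: bool = False
    engine: REMLOptions = field(default_factory=REMLOptions)
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    mc: ScenarioGrid = field(default_factory=ScenarioGrid)


def _build(cls, raw: dict, section: str, errors: list, **renames):
    import dataclasses

    known = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        name = renames.get(key, key)
        if name not in known:
            errors.append(f"{section}: unknown key {key!r}")
            continue
        kwargs[name] = tuple(value) if isinstance(value, list) else value
    try:
        obj = cls(**kwargs)
        if hasattr(obj, "validate"):
            obj.validate()
        return obj
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return cls()


def validate_config(raw: dict | str | None) -> RunConfig:
    """Validate raw config (dict or YAML text); raises ConfigError listing
    every problem found."""
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    errors: list[str] = []
    for key in raw:
        if key not in _SECTIONS:
            errors.append(f"unknown top-level key {key!r}")

    cfg = RunConfig()
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            errors.append("seed: must be an integer")
        else:
            cfg.seed = raw["seed"]
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])

    design_raw = dict(raw.get("design") or {})
    preset = design_raw.pop("preset", None)
    if preset not in (None, "full", "small"):
        errors.append(f"design: unknown preset {preset!r}")
    base = SimulationDesign.small() if preset == "small" else SimulationDesign()
    if design_raw:
        merged = {**base.__dict__, **design_raw}
        cfg.design = _build(SimulationDesign, merged, "design", errors)
    else:
        cfg.design = base
    cfg.genetic = _build(GeneticParameters, raw.get("genetic") or {}, "genetic", errors)
    cfg.edit = _build(EditRules, raw.get("edit") or {}, "edit", errors)
    cfg.step1 = _build(
        Step1ModelSpec, raw.get("step1") or {}, "step1", errors, residual="residual_structure"
    )
    step2 = dict(raw.get("step2") or {})
    cfg.step2_transform = step2.pop("transform", "log")
    cfg.step2_maternal = bool(step2.pop("maternal", False))
    if cfg.step2_transform not in ("log", "cuberoot"):
        errors.append(f"step2: unknown transform {cfg.step2_transform!r}")
    for key in step2:
        errors.append(f"step2: unknown key {key!r}")
    cfg.engine = _build(REMLOptions, raw.get("engine") or {}, "engine", errors)
    paths = dict(raw.get("paths") or {})
    cfg.pedigree_path = paths.pop("pedigree", None)
    cfg.phenotype_path = paths.pop("phenotype", None)
    for key in paths:
        errors.append(f"paths: unknown key {key!r}")
    cfg.mc = _build(ScenarioGrid, raw.get("mc") or {}, "mc", errors)

    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(fh.read())
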