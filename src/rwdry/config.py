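"""Run configuration: a single YAML/JSON document validated into nested
dataclasses, with every schema violation enumerated (not just the first)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ann import TrainConfig
from .diffusion import DiffusionSettings
from .energy import EmissionSettings
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Carries the full list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass
class RunConfig:
    mode: str = "synthetic"                 # "synthetic" | "csv"
    seed: int = 0
    outdir: str = "rwdry_out"
    log_level: str = "INFO"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    diffusion: DiffusionSettings = field(default_factory=DiffusionSettings)
    emissions: EmissionSettings = field(default_factory=EmissionSettings)
    train: TrainConfig = field(default_factory=TrainConfig)
    csv_paths: dict = field(default_factory=dict)   # csv mode: {"drying_runs": path}
    run_topology_search: bool = False


_SECTIONS = {
    "synthetic": SyntheticConfig,
    "diffusion": DiffusionSettings,
    "emissions": EmissionSettings,
    "train": TrainConfig,
}
_TOP_KEYS = {"mode", "seed", "outdir", "log_level", "csv_paths",
             "run_topology_search", *_SECTIONS}


def _build_section(cls, raw: dict, name: str, errors: list[str]):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(raw) - allowed
    for k in sorted(unknown):
        errors.append(f"{name}.{k}: unknown key")
    kwargs = {k: v for k, v in raw.items() if k in allowed}
    # tuple-typed fields arrive as YAML lists
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{name}: {exc}")
        return None


def validate_config(raw: dict | None) -> RunConfig:
    """Check all invariants, inject defaults, reject unknown keys loudly."""
    raw = dict(raw or {})
    errors: list[str] = []
    for k in sorted(set(raw) - _TOP_KEYS):
        errors.append(f"{k}: unknown top-level key")

    mode = raw.get("mode", "synthetic")
    if mode not in ("synthetic", "csv"):
        errors.append(f"mode: must be 'synthetic' or 'csv', got {mode!r}")
    csv_paths = raw.get("csv_paths", {})
    if mode == "csv" and "drying_runs" not in csv_paths:
        errors.append("csv_paths.drying_runs: required in csv mode")
    if mode == "synthetic" and csv_paths:
        errors.append("csv_paths: only valid in csv mode")

    sections = {}
    for name, cls in _SECTIONS.items():
        sec_raw = raw.get(name, {})
        if not isinstance(sec_raw, dict):
            errors.append(f"{name}: must be a mapping")
            sec_raw = {}
        sections[name] = _build_section(cls, sec_raw, name, errors)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        mode=mode,
        seed=seed,
        outdir=str(raw.get("outdir", "rwdry_out")),
        log_level=str(raw.get("log_level", "INFO")),
        synthetic=sections["synthetic"],
        diffusion=sections["diffusion"],
        emissions=sections["emissions"],
        train=sections["train"],
        csv_paths=dict(csv_paths),
        run_topology_search=bool(raw.get("run_topology_search", False)),
    )


def load_config(path) -> RunConfig:
    """Parse a YAML (or JSON, a YAML subset) config file and validate it."""
    doc = yaml.safe_load(Path(path).read_text())
    if doc is not None and not isinstance(doc, dict):
        raise ConfigError(["document root must be a mapping"])
    return validate_config(doc)
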