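"""Pipeline configuration: schema, validation and defaults.

The config file is flat YAML with one section per stage. Unknown keys and
out-of-range values are collected (not fail-fast) and reported with their
key paths; omitted keys receive the documented defaults, which mirror the
analysis parameters (beta 12, min module size 30, merge cut 0.25,
detection percentile 95, tissue fraction 0.65, r_min 0.7, alpha 0.05,
q cap 0.2).
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

STAGES = ("simulate", "annotate", "assemble", "network", "enrich", "hubs")


@dataclass
class SimulateConfig:
    n_genes: int = 30
    n_probes_per_class: dict = field(
        default_factory=lambda: {"mRNA": 60, "intronic": 15, "antisense": 15, "lincRNA": 30}
    )
    annotation_disagreement_rate: float = 0.0
    tissues: list = field(default_factory=lambda: [
        ["oocyte", 10, 2], ["two_cell", 6, 1], ["blastocyst", 12, 2],
        ["cumulus", 8, 1], ["granulosa", 10, 2],
    ])
    module_sizes: list = field(default_factory=lambda: [20, 20, 20])
    within_module_cor: float = 0.8
    noise_sd: float = 1.0
    n_negative_controls: int = 100
    signal_over_background: float = 4.0
    tissue_specific_sets: dict = field(default_factory=lambda: {"oocyte": 5})
    n_never_expressed: int = 2


@dataclass
class AssembleConfig:
    detection_percentile: float = 95.0
    tissue_fraction: float = 0.65
    outlier_floor: float = 0.5
    pooled_controls: bool = False


@dataclass
class NetworkConfig:
    beta: int = 12
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    cut_height_quantile: float = 0.99
    pick_beta: bool = False


@dataclass
class EnrichConfig:
    alpha: float = 0.05
    q_cap: float = 0.2


@dataclass
class HubsConfig:
    r_min: float = 0.7
    alpha: float = 0.05
    use_absolute: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    outdir: str = "lncomp_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    assemble: AssembleConfig = field(default_factory=AssembleConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    hubs: HubsConfig = field(default_factory=HubsConfig)


_RANGES: dict[str, tuple[float, float]] = {
    "simulate.annotation_disagreement_rate": (0.0, 1.0),
    "simulate.within_module_cor": (0.0, 0.999),
    "assemble.detection_percentile": (0.0, 100.0),
    "assemble.tissue_fraction": (0.0, 1.0),
    "assemble.outlier_floor": (-1.0, 1.0),
    "network.beta": (1, 50),
    "network.min_module_size": (1, 10_000),
    "network.merge_cut_height": (0.0, 1.0),
    "network.cut_height_quantile": (0.0, 1.0),
    "enrich.alpha": (0.0, 1.0),
    "enrich.q_cap": (0.0, 1.0),
    "hubs.r_min": (-1.0, 1.0),
    "hubs.alpha": (0.0, 1.0),
}

_SECTIONS = {
    "simulate": SimulateConfig,
    "assemble": AssembleConfig,
    "network": NetworkConfig,
    "enrich": EnrichConfig,
    "hubs": HubsConfig,
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


def _check_range(path: str, value: Any, errors: list[str]) -> None:
    bounds = _RANGES.get(path)
    if bounds is None:
        return
    lo, hi = bounds
    try:
        ok = lo <= value <= hi
    except TypeError:
        ok = False
    if not ok:
        errors.append(f"{path}: value {value!r} outside [{lo}, {hi}]")


def _apply_section(section_name: str, raw: dict, target: Any, errors: list[str]) -> None:
    known = {f.name for f in fields(target)}
    for key, value in raw.items():
        path = f"{section_name}.{key}"
        if key not in known:
            errors.append(f"{path}: unknown key")
            continue
        _check_range(path, value, errors)
        setattr(target, key, value)


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse + validate config text (or pre-parsed mapping).

    All violations are collected and raised together as :class:`ConfigError`
    with their key paths; omitted keys keep their defaults. An empty file
    yields the full default configuration.
    """
    if isinstance(raw, str):
        parsed = yaml.safe_load(raw)
    else:
        parsed = raw
    parsed = parsed or {}
    if not isinstance(parsed, dict):
        raise ConfigError(["top level must be a mapping"])
    config = PipelineConfig()
    errors: list[str] = []
    for key, value in parsed.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                errors.append(f"{key}: section must be a mapping")
                continue
            _apply_section(key, value, getattr(config, key), errors)
        elif key == "seed":
            if not isinstance(value, int):
                errors.append("seed: must be an integer")
            else:
                config.seed = value
        elif key == "stages":
            if not isinstance(value, list) or any(s not in STAGES for s in value):
                errors.append(f"stages: must be a subset of {STAGES}")
            else:
                config.stages = value
        elif key == "outdir":
            config.outdir = str(value)
        else:
            errors.append(f"{key}: unknown key")
    if errors:
        raise ConfigError(errors)
    return config


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    return validate_config(Path(path).read_text())
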