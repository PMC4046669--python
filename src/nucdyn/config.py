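"""Run configuration: a single YAML file echoing every tunable threshold."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple

import yaml

from .simulate import SimConfig


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; unknown keys are rejected."""

    seed: int = 0
    conditions: List[str] = field(default_factory=lambda: ["cond1", "cond2"])
    # input paths (all optional when simulating)
    reads: Dict[str, str] = field(default_factory=dict)     # condition -> SAM/BED path
    genome: Optional[str] = None
    annotations: Optional[str] = None
    expression: Optional[str] = None
    sites: Optional[str] = None
    motif_file: Optional[str] = None
    # simulation block (None disables simulation)
    simulate: Optional[SimConfig] = None
    # stage parameters
    wavelet: str = "bior3.5"
    level: int = 5
    shift_window: Tuple[int, int] = (100, 250)
    min_height: float = 1.0
    min_separation: int = 100
    ndr_min_length: int = 150
    ndr_max_occupancy: float = 0.4
    min_overlap_fraction: float = 0.5
    anchor: str = "+1N"
    flank: int = 1000
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.level < 1 or self.flank < 1 or self.ndr_min_length < 1:
            raise ValueError("level, flank and ndr_min_length must be positive")
        if not 0 < self.ndr_max_occupancy:
            raise ValueError("ndr_max_occupancy must be positive")
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")

    def echo(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = {k: v for k, v in dataclasses.asdict(self.simulate).items()
                             if not k.startswith("_")}
        d["shift_window"] = list(self.shift_window)
        return d


def load_config(path, seed: Optional[int] = None) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, seed=seed)


def config_from_dict(raw: Dict[str, Any], seed: Optional[int] = None) -> RunConfig:
    raw = dict(raw)
    sim = raw.pop("simulate", None)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if seed is not None:
        cfg.seed = seed
    if sim is not None:
        sim = dict(sim)
        sim_known = {f.name for f in dataclasses.fields(SimConfig) if f.init}
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulate keys: {sorted(sim_unknown)}")
        sim.setdefault("seed", cfg.seed)
        if seed is not None:
            sim["seed"] = seed
        cfg.simulate = SimConfig(**sim)
    if "shift_window" in raw:
        cfg.shift_window = tuple(raw["shift_window"])
    return cfg
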