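"""Run configuration: YAML parsing, validation, seed derivation and hashing."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "stage_seed"]

_DEFAULT_STAGES = ("metrics", "surface", "water_dynamics", "landscape", "mep")


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    With ``topology``/``trajectory`` unset the pipeline runs in synthetic
    demo mode, generating its own fixtures from the seed.
    """

    topology: str | None = None
    trajectory: str | None = None
    selections: dict = field(default_factory=lambda: {"metrics": "backbone"})
    temperature_K: float = 313.0
    catalytic_residues: tuple[int, ...] = ()
    hydropathy_overrides: dict = field(default_factory=dict)
    solvent_role_map: dict = field(default_factory=dict)
    stages: tuple[str, ...] = _DEFAULT_STAGES
    params: dict = field(default_factory=dict)
    outdir: str = "maostraj_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        for path in (self.topology, self.trajectory):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input file does not exist: {path}")
        unknown = set(self.stages) - set(_DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "catalytic_residues" in data:
            data["catalytic_residues"] = tuple(int(r) for r in data["catalytic_residues"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def canonical_json(self) -> str:
        d = {
            "topology": self.topology,
            "trajectory": self.trajectory,
            "selections": self.selections,
            "temperature_K": self.temperature_K,
            "catalytic_residues": list(self.catalytic_residues),
            "hydropathy_overrides": self.hydropathy_overrides,
            "solvent_role_map": self.solvent_role_map,
            "stages": list(self.stages),
            "params": self.params,
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed (kept below 2³¹)."""
    return (base_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)
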