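"""Run configuration: every numeric constant of the planning pipeline.

The defaults are the working values of the method: 9 Å / 5 contacts / 20%
for SSE contact determination, the 19 Å cross-linkable window, the
0.95/0.5/0.05 link-probability tiers, agreement weight q = 0.8, the 0.01
bit mRMR stop threshold, 10-link plans with k0 = 3, and the ±2-residue
misalignment / 5-sample elastic-mode noise model.  Configs round-trip
losslessly through YAML with a flat key namespace.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # SSE contact determination
    contact_distance: float = 9.0
    min_contacts: int = 5
    min_residue_fraction: float = 0.20
    # ensemble assembly
    presence_fraction: float = 0.5
    overlap_fraction: float = 0.5
    # stage-1 probability model and mRMR
    q: float = 0.8
    stop_threshold: float = 0.01
    max_pairs: int | None = None
    # cross-link planning
    xlink_max_distance: float = 19.0
    plan_size: int = 10
    k0: int = 3
    p_near: float = 0.95
    p_mid: float = 0.50
    p_far: float = 0.05
    # noise model
    delta_max: int = 2
    decay: float = 1.0
    enm_samples: int = 5
    enm_amplitude: float = 3.0
    enm_cutoff: float = 10.0
    enm_kT: float | None = None
    # simulation
    sim_distance: float = 9.0
    r_values: list[float] = field(default_factory=lambda: [0.05, 0.10, 0.15, 0.20])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
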