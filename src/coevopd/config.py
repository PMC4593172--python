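"""Run configuration: validation, JSON/YAML round-trip, seed splitting."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .model import GameParams, LatticeSpec, WeightParams


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation campaign.

    ``measure_window`` is the number of trailing MCS averaged for the
    stationary cooperation fraction; the reference protocol is a window of
    1000 over 61000 total MCS on a 100 x 100 lattice with up to 10
    realizations.
    """

    lattice: LatticeSpec
    game: GameParams
    weight: WeightParams
    init_mode: str = "random"
    total_mcs: int = 5000
    measure_window: int = 500
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.init_mode not in ("random", "half_plane"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode == "half_plane" and self.lattice.L % 2 != 0:
            raise ValueError("half_plane initialization requires even L")
        if self.total_mcs < 0:
            raise ValueError("total_mcs must be >= 0")
        if self.measure_window > self.total_mcs:
            raise ValueError("measure_window must not exceed total_mcs")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def to_dict(self) -> dict:
        return {
            "lattice": {"L": self.lattice.L},
            "game": {"b": self.game.b},
            "weight": {"delta": self.weight.delta, "Delta": self.weight.Delta},
            "init_mode": self.init_mode,
            "total_mcs": self.total_mcs,
            "measure_window": self.measure_window,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            lattice=LatticeSpec(L=int(d["lattice"]["L"])),
            game=GameParams(b=float(d["game"]["b"])),
            weight=WeightParams(
                delta=float(d["weight"]["delta"]), Delta=float(d["weight"]["Delta"])
            ),
            init_mode=d.get("init_mode", "random"),
            total_mcs=int(d.get("total_mcs", 5000)),
            measure_window=int(d.get("measure_window", 500)),
            replicates=int(d.get("replicates", 1)),
            seed=int(d.get("seed", 0)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load from a JSON or YAML file (YAML is a JSON superset here)."""
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix in (".yml", ".yaml"):
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            p.write_text(self.to_json())

    def replicate_seeds(self, n: int | None = None) -> list[np.random.SeedSequence]:
        """Per-replicate seed sequences via ``SeedSequence.spawn``.

        Spawning is prefix-stable: the first k children are identical no
        matter how many replicates are requested, so adding replicates never
        perturbs existing ones.
        """
        return np.random.SeedSequence(self.seed).spawn(self.replicates if n is None else n)
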