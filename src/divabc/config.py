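"""Run configuration: one serializable object that pins an analysis.

Every pipeline stage accepts a :class:`RunConfig` and writes it (as JSON)
next to its outputs, so any result directory documents the exact
settings, seed and scale that produced it.  Two scale presets are
provided: ``desk`` (1e4 simulations per model, 100 PODs per true model)
for workstation runs, and ``paper`` (5e6 simulations per model) matching
the full-scale analysis; the latter is documented but not exercised by
the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .abc import ABCSettings
from .demography import MODELS, PriorSet

PRESETS = {
    "desk": {"n_sims_per_model": 10_000, "n_pods": 100,
             "acceptance_rate": 0.05, "n_accept_est": 500},
    "paper": {"n_sims_per_model": 5_000_000, "n_pods": 100,
              "acceptance_rate": 0.001, "n_accept_est": 2000},
}


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs besides its input files."""

    seed: int = 1
    preset: str = "desk"
    models: tuple[str, ...] = MODELS
    n_sims_per_model: int = 10_000
    n_pods: int = 100
    gen_years: float = 2.0
    T_out_years: float = 5e6
    priors: PriorSet = dataclasses.field(default_factory=PriorSet)
    abc: ABCSettings = dataclasses.field(default_factory=ABCSettings)

    @classmethod
    def from_preset(cls, preset: str, seed: int = 1, **overrides
                    ) -> "RunConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        p = PRESETS[preset]
        abc = ABCSettings(acceptance_rate=p["acceptance_rate"],
                          n_accept_est=p["n_accept_est"], seed=seed)
        cfg = cls(seed=seed, preset=preset,
                  n_sims_per_model=p["n_sims_per_model"],
                  n_pods=p["n_pods"], abc=abc)
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         default=str))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "priors" in raw:
            raw["priors"] = PriorSet(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["priors"].items()})
        if "abc" in raw:
            raw["abc"] = ABCSettings(**raw["abc"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)
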