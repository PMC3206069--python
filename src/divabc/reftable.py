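"""Reference tables: (parameter draw, summary statistics) matrices.

One table per demographic model is the ABC "training set": each row holds
one prior draw and the 22 summary statistics of a multilocus dataset
simulated under it.  Tables serialize to TSV with a JSON header line
carrying the model, priors, seed and column order, so any run can be
reproduced or resumed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalescent, popgen
from .demography import LocusSpec, PriorSet, check_model, draw_parameters

__all__ = ["ReferenceTable", "build_reference_table"]


@dataclasses.dataclass
class ReferenceTable:
    model: str
    param_names: list[str]
    params: np.ndarray          # (n_reps, n_params), natural units
    stat_names: list[str]
    stats: np.ndarray           # (n_reps, 22)
    seed: int
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return self.params.shape[0]

    def subsample(self, n: int, rng: np.random.Generator) -> "ReferenceTable":
        idx = rng.choice(self.n_reps, size=n, replace=False)
        return dataclasses.replace(self, params=self.params[idx],
                                   stats=self.stats[idx])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {"model": self.model, "seed": self.seed,
                  "param_names": self.param_names,
                  "stat_names": self.stat_names, "meta": self.meta}
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            df = pd.DataFrame(
                np.hstack([self.params, self.stats]),
                columns=self.param_names + self.stat_names)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceTable":
        path = Path(path)
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            df = pd.read_csv(fh, sep="\t")
        p = df[header["param_names"]].to_numpy(float)
        s = df[header["stat_names"]].to_numpy(float)
        return cls(header["model"], header["param_names"], p,
                   header["stat_names"], s, header["seed"],
                   header.get("meta", {}))


def build_reference_table(model: str, priors: PriorSet,
                          loci: list[LocusSpec], n_reps: int, seed: int,
                          workspace: coalescent.Workspace | None = None,
                          ) -> ReferenceTable:
    """Simulate ``n_reps`` (parameters, 22 statistics) rows under one model.

    Replicate ``r`` is driven by the deterministic child seed sequence
    ``SeedSequence([seed, r])``, so tables are bit-reproducible and can be
    rebuilt row-by-row.  Per-locus statistics that are undefined for every
    locus of a replicate (e.g. Tajima's D with no segregating sites) enter
    the summary vector as 0 (the popgen exclusion rule).
    """
    check_model(model)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_max = max(s.n_A + s.n_B for s in loci)
    ws = workspace or coalescent.Workspace(n_max)
    param_names = list(priors.bounds_for(model))
    params = np.empty((n_reps, len(param_names)))
    stats = np.empty((n_reps, len(popgen.STAT_NAMES)))
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        draw = draw_parameters(model, priors, rng)
        sim_seed = int(rng.integers(0, 2 ** 31))
        per_locus, _ = coalescent.simulate_dataset(draw, loci, sim_seed, ws)
        values, _excl = popgen.summarize_matrix(per_locus[:, :12])
        free = draw.free_values()
        params[r] = [free[k] for k in param_names]
        stats[r] = values
    meta = {"n_loci": len(loci),
            "n_A": loci[0].n_A, "n_B": loci[0].n_B,
            "priors": dataclasses.asdict(priors)}
    return ReferenceTable(model, param_names, params,
                          list(popgen.STAT_NAMES), stats, seed, meta)
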