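"""Posterior-predictive goodness-of-fit for a fitted divergence model.

After parameter estimation, datasets are re-simulated under parameter
vectors drawn from the weighted posterior and compared with the
observation on *held-out* statistics -- the composition of the polarized
site classes (proportions of shared, fixed and exclusive polymorphisms),
which enter the inference only through count means/SDs, never as
proportions.  Each statistic gets a two-sided posterior-predictive
p-value with the (r+1)/(n+1) small-sample correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import coalescent
from .abc import ParameterPosterior
from .demography import LocusSpec, ParameterVector

__all__ = ["HELDOUT_NAMES", "heldout_stats", "goodness_of_fit"]

HELDOUT_NAMES = ["prop_ss", "prop_sf", "prop_sx_A", "prop_sx_B",
                 "prop_sxA_fB", "prop_sxB_fA"]

# columns of the per-locus 14-vector (coalescent.LOCUS_VEC_COLUMNS)
_CLS_COLS = {"prop_ss": 8, "prop_sf": 9, "prop_sx_A": 10, "prop_sx_B": 11,
             "prop_sxA_fB": 12, "prop_sxB_fA": 13}


def heldout_stats(per_locus: np.ndarray) -> np.ndarray:
    """Site-class composition across loci: each class's share of all
    classified polarized sites (zeros when no site is classified)."""
    per_locus = np.atleast_2d(per_locus)
    totals = np.array([per_locus[:, c].sum() for c in _CLS_COLS.values()])
    grand = totals.sum()
    if grand <= 0:
        return np.zeros(len(HELDOUT_NAMES))
    return totals / grand


def goodness_of_fit(obs_per_locus: np.ndarray,
                    posterior: ParameterPosterior,
                    loci: list[LocusSpec], n_pp: int, seed: int,
                    gen_years: float = 2.0) -> pd.DataFrame:
    """Posterior-predictive p-values for the held-out statistics.

    ``obs_per_locus`` is the observed (n_loci, 14) per-locus matrix;
    ``n_pp`` parameter vectors are resampled from the weighted posterior
    and one dataset simulated under each.
    """
    if n_pp < 1:
        raise ValueError("n_pp must be >= 1")
    obs = heldout_stats(obs_per_locus)
    rng = np.random.default_rng(seed)
    w = posterior.weights / posterior.weights.sum()
    picks = rng.choice(len(w), size=n_pp, replace=True, p=w)
    ws = coalescent.Workspace(max(s.n_A + s.n_B for s in loci))
    sims = np.empty((n_pp, len(HELDOUT_NAMES)))
    for i, k in enumerate(picks):
        kwargs = dict(zip(posterior.param_names, posterior.adjusted[k]))
        pv = ParameterVector(model=posterior.model, gen_years=gen_years,
                             **kwargs)
        per_locus, _ = coalescent.simulate_dataset(
            pv, loci, int(rng.integers(2 ** 31)), ws)
        sims[i] = heldout_stats(per_locus)
    rows = []
    for j, name in enumerate(HELDOUT_NAMES):
        lo = (np.sum(sims[:, j] <= obs[j]) + 1) / (n_pp + 1)
        hi = (np.sum(sims[:, j] >= obs[j]) + 1) / (n_pp + 1)
        rows.append({"stat": name, "observed": obs[j],
                     "pp_mean": sims[:, j].mean(),
                     "p_value": min(1.0, 2.0 * min(lo, hi))})
    return pd.DataFrame(rows)
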