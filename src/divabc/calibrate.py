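"""Model-choice calibration with pseudo-observed datasets (PODs).

A POD is a simulated dataset whose generating model is known.  Running
every POD through the model-choice machinery yields, for each true model,
the empirical distribution of the estimated posterior probability of each
candidate.  Two quantities follow: the *recovery rate* (fraction of PODs
whose true model receives relative probability > 0.5) and, via a density
ratio, the probability that the winning model is correct given the
posterior value observed on real data.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import coalescent
from .abc import ABCSettings, model_choice
from .demography import LocusSpec, PriorSet, draw_parameters
from .popgen import summarize_matrix
from .reftable import ReferenceTable

__all__ = ["CalibrationResult", "run_pods", "p_correct_given_posterior",
           "reflected_kde"]


@dataclasses.dataclass
class CalibrationResult:
    """POD calibration of a candidate-model set.

    ``posteriors[m]`` is the (n_pods, k) matrix of estimated posterior
    probabilities of every candidate (columns ordered as ``models``) when
    ``m`` is the true model; ``recovery[m]`` the fraction of those PODs
    in which m's posterior exceeds 0.5.
    """

    models: list[str]
    posteriors: dict[str, np.ndarray]
    recovery: dict[str, float]
    n_pods: int

    def winner_column(self, winner: str) -> dict[str, np.ndarray]:
        j = self.models.index(winner)
        return {m: P[:, j] for m, P in self.posteriors.items()}


def _drop_row(table: ReferenceTable, row: int) -> ReferenceTable:
    keep = np.arange(table.n_reps) != row
    return dataclasses.replace(table, params=table.params[keep],
                               stats=table.stats[keep])


def run_pods(tables: dict[str, ReferenceTable], priors: PriorSet,
             loci: list[LocusSpec], n_pods: int, seed: int,
             settings: ABCSettings | None = None,
             pods_from_tables: bool = True) -> CalibrationResult:
    """Calibrate model choice with ``n_pods`` PODs per candidate model.

    By default PODs are drawn from each model's own reference table (its
    rows are exactly prior-predictive simulations); the POD's own row is
    removed from its table before inference so a POD never matches
    itself.  With ``pods_from_tables=False`` fresh datasets are simulated
    instead.
    """
    st = settings or ABCSettings()
    if n_pods < 20:
        warnings.warn(f"n_pods={n_pods} is small; recovery rates and "
                      "density estimates will be unstable", stacklevel=2)
    models = sorted(tables)
    rng = np.random.default_rng(seed)
    ws = None
    if not pods_from_tables:
        ws = coalescent.Workspace(max(s.n_A + s.n_B for s in loci))
    posteriors = {}
    recovery = {}
    for m in models:
        P = np.empty((n_pods, len(models)))
        if pods_from_tables:
            rows = rng.choice(tables[m].n_reps, size=n_pods, replace=False)
        for i in range(n_pods):
            if pods_from_tables:
                row = int(rows[i])
                obs = tables[m].stats[row]
                use = dict(tables)
                use[m] = _drop_row(tables[m], row)
            else:
                draw = draw_parameters(m, priors, rng)
                per_locus, _ = coalescent.simulate_dataset(
                    draw, loci, int(rng.integers(2 ** 31)), ws)
                obs, _ = summarize_matrix(per_locus[:, :12])
                use = tables
            pod_settings = dataclasses.replace(
                st, seed=int(rng.integers(2 ** 31)))
            mp = model_choice(obs, use, pod_settings)
            P[i] = [mp.probs[c] for c in models]
        posteriors[m] = P
        recovery[m] = float((P[:, models.index(m)] > 0.5).mean())
    return CalibrationResult(models, posteriors, recovery, n_pods)


def reflected_kde(sample: np.ndarray, x: np.ndarray | float,
                  bw: float | None = None) -> np.ndarray:
    """Gaussian KDE on [0, 1] with boundary reflection.

    Posterior probabilities live on the unit interval; reflecting mass at
    both boundaries removes the usual edge bias of a plain Gaussian
    kernel.  Degenerate (zero-variance) samples get a narrow Gaussian
    around the common value.
    """
    s = np.asarray(sample, dtype=float)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    sd = s.std()
    if bw is None:
        # Scott's rule on the raw sample, floored for degenerate cases
        bw = max(sd * len(s) ** (-1 / 5), 1e-3)

    def gauss(u):
        return np.exp(-0.5 * (u / bw) ** 2) / (bw * np.sqrt(2 * np.pi))

    dens = np.zeros_like(xs)
    for si in s:
        dens += gauss(xs - si) + gauss(xs + si) + gauss(2.0 - xs - si)
    dens /= len(s)
    return dens if np.ndim(x) else float(dens[0])


def p_correct_given_posterior(calib: CalibrationResult, winner: str,
                              observed_p: float) -> float:
    """Probability the winning model is correct given its observed
    posterior probability, by density ratio under equal model priors:
    d_winner(observed) / sum_m d_m(observed), where d_m is the density of
    the winner's estimated posterior when m is the true model."""
    cols = calib.winner_column(winner)
    dens = {m: reflected_kde(v, observed_p) for m, v in cols.items()}
    total = sum(dens.values())
    if total <= 0 or not np.isfinite(total):
        raise ValueError(
            f"all calibration densities vanish at p={observed_p}; the "
            "observed posterior lies outside the calibrated range")
    return dens[winner] / total
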