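"""Rejection + regression ABC for model choice and parameter estimation.

Model choice pools the candidate models' reference tables, keeps the
fraction of simulations nearest to the observed summary vector in
standardized Euclidean distance, weights them with an Epanechnikov kernel,
and regresses the model indicator on the summary statistics within the
accepted set -- either by weighted multinomial logistic regression
(``method="mnlogistic"``, deterministic and fast) or by an ensemble of
single-hidden-layer neural networks (``method="neuralnet"``, the weighting
realized as weighted bootstrap resampling per ensemble member).  A plain
rejection (weighted-frequency) posterior is always reported alongside.

Parameter estimation keeps the ``n_accept`` nearest simulations, maps each
parameter to the real line by a log-tangent transform of its prior
interval, regresses the transformed parameters on the statistics with an
ensemble of neural networks, shifts the accepted draws by the fitted
conditional mean towards the observation, back-transforms, and reports
kernel-density modes and highest-posterior-density intervals.

Distances standardize every statistic by its median absolute deviation
over the pooled reference table (robust scale; columns with zero MAD fall
back to the standard deviation, then to 1).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .demography import PriorSet, check_model
from .reftable import ReferenceTable

__all__ = ["ABCSettings", "ModelPosterior", "ParameterPosterior",
           "robust_scale", "standardize_and_distance", "reject",
           "model_choice", "hierarchical_model_choice",
           "transform_params", "inverse_transform_params",
           "estimate_parameters", "hpd", "weighted_mode"]


@dataclasses.dataclass
class ABCSettings:
    """Tunable knobs of the ABC procedures.

    ``acceptance_rate`` is the fraction of pooled simulations kept for
    model choice (0.001 at full scale); ``n_accept_est`` the count kept
    for parameter estimation (2000 at full scale).  ``method`` selects the
    model-choice regression backend.  Ensemble sizes and hidden-unit
    counts default to the full-scale analysis (50 nets x 10 units for
    choice, 100 nets x 15 units for estimation); reduced presets shrink
    them for desk-scale runs.
    """

    acceptance_rate: float = 0.001
    min_accept: int = 50
    n_accept_est: int = 2000
    method: str = "mnlogistic"          # mnlogistic | neuralnet | rejection
    n_nets_choice: int = 50
    hidden_choice: int = 10
    n_nets_est: int = 10
    hidden_est: int = 15
    max_iter: int = 300
    seed: int = 0
    hpd_level: float = 0.95
    grid_size: int = 512


@dataclasses.dataclass
class ModelPosterior:
    """Posterior model probabilities (regression-adjusted and
    rejection-only), plus accepted counts and ensemble spread."""

    probs: dict[str, float]
    rejection_probs: dict[str, float]
    n_accepted: dict[str, int]
    method: str
    ensemble_sd: dict[str, float] | None = None

    @property
    def best(self) -> str:
        return max(self.probs, key=self.probs.get)


@dataclasses.dataclass
class ParameterPosterior:
    """Accepted-and-adjusted parameter sample with weights and summaries."""

    model: str
    param_names: list[str]
    raw: np.ndarray         # accepted draws, natural units
    adjusted: np.ndarray    # regression-adjusted draws, natural units
    weights: np.ndarray
    bounds: dict[str, tuple[float, float]]
    mode: dict[str, float]
    hpd: dict[str, tuple[float, float]]
    level: float
    adjusted_by_regression: bool


# ---------------------------------------------------------------------------
# distances and rejection


def robust_scale(stats: np.ndarray) -> np.ndarray:
    """Per-column MAD of a reference-statistic matrix, with std and unit
    fallbacks for degenerate columns."""
    X = np.asarray(stats, dtype=float)
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    sd = X.std(axis=0)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return scale


def standardize_and_distance(obs: np.ndarray, stats: np.ndarray,
                             scale: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distance of every reference row to the observation after
    per-statistic standardization."""
    obs = np.asarray(obs, dtype=float)
    X = np.asarray(stats, dtype=float)
    if obs.shape[0] != X.shape[1]:
        raise ValueError("observation length does not match table width")
    if scale is None:
        scale = robust_scale(X)
    Z = (X - obs) / scale
    return np.sqrt((Z ** 2).sum(axis=1))


def reject(distances: np.ndarray, acceptance_rate: float | None = None,
           n_accept: int | None = None
           ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-fraction rejection step with Epanechnikov weights.

    Keeps the ``ceil(acceptance_rate * n)`` (or ``n_accept``) rows with
    smallest distance; weight ``w_i = 1 - (d_i/d_max)^2`` vanishes at the
    acceptance boundary and is 1 at distance zero.
    """
    d = np.asarray(distances, dtype=float)
    if n_accept is None:
        if acceptance_rate is None:
            raise ValueError("give acceptance_rate or n_accept")
        n_accept = math.ceil(acceptance_rate * len(d))
    n_accept = min(n_accept, len(d))
    if n_accept < 2:
        raise ValueError(f"acceptance yields {n_accept} rows (< 2); "
                         "increase the rate or the table size")
    idx = np.argpartition(d, n_accept - 1)[:n_accept]
    idx = idx[np.argsort(d[idx], kind="stable")]
    dmax = d[idx[-1]]
    if dmax == 0:
        w = np.ones(n_accept)
    else:
        w = 1.0 - (d[idx] / dmax) ** 2
        w = np.maximum(w, 0.0)
    return idx, w


# ---------------------------------------------------------------------------
# model choice


def _weighted_bootstrap(rng, weights, n):
    p = weights / weights.sum()
    return rng.choice(len(weights), size=n, replace=True, p=p)


def model_choice(obs: np.ndarray, tables: dict[str, ReferenceTable],
                 settings: ABCSettings | None = None) -> ModelPosterior:
    """Posterior model probabilities among >=2 candidate models.

    Tables are subsampled to equal replicate counts, pooled, and the
    nearest fraction retained; the model indicator is then regressed on
    the summary statistics within the accepted set.  Models absent from
    the accepted set receive probability 0.
    """
    st = settings or ABCSettings()
    if len(tables) < 2:
        raise ValueError("need >= 2 candidate models")
    models = sorted(tables)
    rng = np.random.default_rng(st.seed)
    n_common = min(t.n_reps for t in tables.values())
    stats_list, labels = [], []
    for m_i, m in enumerate(models):
        t = tables[m]
        t = t.subsample(n_common, rng) if t.n_reps > n_common else t
        stats_list.append(t.stats)
        labels.append(np.full(t.stats.shape[0], m_i))
    X = np.vstack(stats_list)
    y = np.concatenate(labels)

    d = standardize_and_distance(obs, X)
    n_acc = max(math.ceil(st.acceptance_rate * len(d)), st.min_accept)
    idx, w = reject(d, n_accept=n_acc)
    ya, Xa = y[idx], X[idx]

    # rejection-only posterior: Epanechnikov-weighted class frequencies
    wsum = w.sum() if w.sum() > 0 else 1.0
    rej = {m: float(w[ya == m_i].sum() / wsum)
           for m_i, m in enumerate(models)}
    n_accepted = {m: int((ya == m_i).sum()) for m_i, m in enumerate(models)}

    present = np.unique(ya)
    ensemble_sd = None
    if st.method == "rejection" or len(present) < 2:
        probs = dict(rej)
    else:
        mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
        sd[sd == 0] = 1.0
        Za = (Xa - mu) / sd
        zobs = ((obs - mu) / sd).reshape(1, -1)
        if st.method == "mnlogistic":
            clf = LogisticRegression(max_iter=2000, C=1.0)
            clf.fit(Za, ya, sample_weight=np.maximum(w, 1e-8))
            p_present = clf.predict_proba(zobs)[0]
            probs = {m: 0.0 for m in models}
            for cls, p in zip(clf.classes_, p_present):
                probs[models[int(cls)]] = float(p)
        elif st.method == "neuralnet":
            preds = []
            for f in range(st.n_nets_choice):
                boot = _weighted_bootstrap(rng, np.maximum(w, 1e-8), len(w))
                yb = ya[boot]
                if len(np.unique(yb)) < 2:
                    continue
                clf = MLPClassifier(hidden_layer_sizes=(st.hidden_choice,),
                                    max_iter=st.max_iter,
                                    random_state=int(rng.integers(2 ** 31)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(Za[boot], yb)
                row = np.zeros(len(models))
                for cls, p in zip(clf.classes_, clf.predict_proba(zobs)[0]):
                    row[int(cls)] = p
                preds.append(row)
            P = np.array(preds)
            mean_p = P.mean(axis=0)
            ensemble_sd = {m: float(P[:, i].std())
                           for i, m in enumerate(models)}
            probs = {m: float(mean_p[i]) for i, m in enumerate(models)}
        else:
            raise ValueError(f"unknown method {st.method!r}")
    total = sum(max(p, 0.0) for p in probs.values())
    probs = {m: max(p, 0.0) / total for m, p in probs.items()} if total > 0 \
        else dict(rej)
    return ModelPosterior(probs, rej, n_accepted, st.method, ensemble_sd)


def hierarchical_model_choice(obs: np.ndarray,
                              tables: dict[str, ReferenceTable],
                              settings: ABCSettings | None = None) -> dict:
    """Two-step hierarchical choice over the 12-model grid.

    Stage 1, per migration scenario: the constant-size model is compared
    pairwise against the growth and the bottleneck variants; the class's
    best-supported model advances.  Stage 2 is a four-way choice among the
    advanced models.  Returns the stage-wise posteriors and the winner.
    """
    st = settings or ABCSettings()
    scenarios = sorted({m[:2] for m in tables})
    stage1: dict[str, dict] = {}
    finalists: dict[str, str] = {}
    for scen in scenarios:
        comp = {}
        scores = {}
        const = scen + "C"
        for mode, label in (("E", "growth"), ("B", "bottleneck")):
            alt = scen + mode
            if const not in tables or alt not in tables:
                continue
            mp = model_choice(obs, {const: tables[const], alt: tables[alt]},
                              st)
            comp[label] = mp
            scores[alt] = mp.probs[alt]
        # the constant model advances unless an alternative beats it in
        # its own pairwise comparison; the strongest winner advances
        best, best_score = const, 0.5
        for alt, s in scores.items():
            if s > best_score:
                best, best_score = alt, s
        stage1[scen] = {"comparisons": comp, "best": best}
        finalists[scen] = best
    stage2 = model_choice(obs, {m: tables[m] for m in finalists.values()},
                          st)
    return {"stage1": stage1, "finalists": finalists, "stage2": stage2,
            "winner": stage2.best}


# ---------------------------------------------------------------------------
# parameter transforms


_EPS = 1e-12


def transform_params(x: np.ndarray, bounds: list[tuple[float, float]]
                     ) -> np.ndarray:
    """Log-tangent map of each bounded parameter to the real line:
    y = log(tan(pi/2 * (x-lo)/(hi-lo)))."""
    X = np.atleast_2d(np.asarray(x, dtype=float)).copy()
    for j, (lo, hi) in enumerate(bounds):
        u = np.clip((X[:, j] - lo) / (hi - lo), _EPS, 1.0 - _EPS)
        X[:, j] = np.log(np.tan(0.5 * np.pi * u))
    return X.reshape(np.shape(x))


def inverse_transform_params(y: np.ndarray,
                             bounds: list[tuple[float, float]]) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(y, dtype=float)).copy()
    with np.errstate(over="ignore"):
        for j, (lo, hi) in enumerate(bounds):
            u = (2.0 / np.pi) * np.arctan(np.exp(Y[:, j]))
            Y[:, j] = lo + np.clip(u, 0.0, 1.0) * (hi - lo)
    return Y.reshape(np.shape(y))


# ---------------------------------------------------------------------------
# weighted density summaries


def _weighted_kde(sample: np.ndarray, weights: np.ndarray, grid: np.ndarray):
    try:
        kde = gaussian_kde(sample, weights=weights)
        return kde(grid)
    except (np.linalg.LinAlgError, ValueError):
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - np.average(sample, weights=weights)))] = 1.0
        return dens


def _density_grid(sample, weights, grid_size):
    lo, hi = float(np.min(sample)), float(np.max(sample))
    if hi <= lo:
        return np.array([lo]), np.array([1.0])
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    return grid, _weighted_kde(sample, weights, grid)


def weighted_mode(sample: np.ndarray, weights: np.ndarray | None = None,
                  grid_size: int = 512) -> float:
    """Argmax of the weighted kernel density estimate."""
    sample = np.asarray(sample, dtype=float)
    weights = np.ones_like(sample) if weights is None else weights
    grid, dens = _density_grid(sample, weights, grid_size)
    return float(grid[np.argmax(dens)])


def hpd(sample: np.ndarray, weights: np.ndarray | None = None,
        level: float = 0.95, grid_size: int = 512) -> tuple[float, float]:
    """Smallest interval holding >= ``level`` of the weighted kernel
    density mass (grid construction); degenerate samples give zero-width
    intervals."""
    sample = np.asarray(sample, dtype=float)
    weights = np.ones_like(sample) if weights is None else weights
    grid, dens = _density_grid(sample, weights, grid_size)
    if len(grid) == 1:
        return float(grid[0]), float(grid[0])
    dx = grid[1] - grid[0]
    cum = np.concatenate([[0.0], np.cumsum(dens) * dx])
    total = cum[-1]
    target = level * total
    best = (grid[0], grid[-1])
    best_w = grid[-1] - grid[0]
    j = 0
    for i in range(len(grid)):
        j = max(j, i)
        while j < len(grid) and cum[j + 1] - cum[i] < target:
            j += 1
        if j >= len(grid):
            break
        width = grid[j] - grid[i]
        if width < best_w:
            best_w = width
            best = (float(grid[i]), float(grid[j]))
    return best


# ---------------------------------------------------------------------------
# parameter estimation


def estimate_parameters(obs: np.ndarray, table: ReferenceTable,
                        priors: PriorSet | None = None,
                        settings: ABCSettings | None = None
                        ) -> ParameterPosterior:
    """Regression-adjusted ABC posterior for one model's parameters.

    Keeps the ``n_accept_est`` nearest simulations, adjusts the
    (log-tangent transformed) accepted draws by an ensemble of
    single-hidden-layer neural-network regressions of parameters on
    statistics, and reports weighted KDE modes and HPD intervals.  With a
    degenerate accepted set the adjustment is skipped (rejection-only
    posterior, flagged on the result).
    """
    st = settings or ABCSettings()
    priors = priors or PriorSet()
    check_model(table.model)
    bounds_map = priors.bounds_for(table.model)
    bounds = [bounds_map[p] for p in table.param_names]

    d = standardize_and_distance(obs, table.stats)
    idx, w = reject(d, n_accept=min(st.n_accept_est, table.n_reps))
    raw = table.params[idx]
    Xa = table.stats[idx]

    Y = transform_params(raw, bounds)
    mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
    sd[sd == 0] = 1.0
    Za = (Xa - mu) / sd
    zobs = ((np.asarray(obs, dtype=float) - mu) / sd).reshape(1, -1)

    degenerate = (np.allclose(Za.std(axis=0), 0.0) or np.allclose(w.sum(), 0)
                  or np.allclose(Y.std(axis=0), 0.0))
    adjusted_by_regression = False
    if degenerate or st.method == "rejection":
        Yadj = Y
        if degenerate:
            warnings.warn("degenerate accepted set: rejection-only "
                          "posterior reported", stacklevel=2)
    else:
        rng = np.random.default_rng(st.seed + 1)
        shift = np.zeros_like(Y)
        n_fit = 0
        for f in range(st.n_nets_est):
            boot = _weighted_bootstrap(rng, np.maximum(w, 1e-8), len(w))
            reg = MLPRegressor(hidden_layer_sizes=(st.hidden_est,),
                               max_iter=st.max_iter,
                               random_state=int(rng.integers(2 ** 31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reg.fit(Za[boot], Y[boot])
            pred_obs = reg.predict(zobs)
            pred_sims = reg.predict(Za)
            if Y.shape[1] == 1:
                pred_obs = pred_obs.reshape(1, 1)
                pred_sims = pred_sims.reshape(-1, 1)
            shift += pred_obs - pred_sims
            n_fit += 1
        Yadj = Y + shift / max(n_fit, 1)
        adjusted_by_regression = n_fit > 0

    adj = inverse_transform_params(Yadj, bounds)
    # respect hierarchical support (times nested below T_split)
    if "T_split" in table.param_names:
        ts = adj[:, table.param_names.index("T_split")]
        for nested in ("T_iso", "T_SC", "T_b"):
            if nested in table.param_names:
                j = table.param_names.index(nested)
                adj[:, j] = np.minimum(adj[:, j], ts)

    mode = {}
    hpd_iv = {}
    for j, name in enumerate(table.param_names):
        mode[name] = weighted_mode(adj[:, j], w, st.grid_size)
        hpd_iv[name] = hpd(adj[:, j], w, st.hpd_level, st.grid_size)
    return ParameterPosterior(table.model, list(table.param_names), raw,
                              adj, w, bounds_map, mode, hpd_iv,
                              st.hpd_level, adjusted_by_regression)
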