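"""Two-population divergence scenarios and their priors.

Twelve models: four migration scenarios -- strict isolation (SI), constant
migration (CM), ancient migration (AM, gene flow only between T_iso and
T_split), secondary contact (SC, gene flow only more recently than T_SC) --
crossed with three population-size modes: constant (C), exponential growth
in both daughter species (E), and a bottleneck in species A followed by
exponential regrowth (B).  Model codes are the concatenation, e.g. ``SIC``,
``AMB``.

Public parameters are in natural units (individuals, years, 4Nm migration
units).  ``compile_epochs`` converts a parameter vector into the piecewise
epoch arrays consumed by the coalescent kernel, scaled by a reference size
N_ref = N_A-species size of the draw (time in units of 4*N_ref generations,
deme sizes relative to N_ref).

Size-mode shapes (the scenario grid names the shapes but not their
parameters; these are declared, configurable defaults):

* E -- exponential growth in both species starting, forwards in time, at
  T_split/2 from a founding size of N_A/2 each, reaching the current size
  at present.
* B -- species A is instantaneously reduced to a fraction ``bottleneck_f``
  of its current size at time ``T_b`` (drawn U(0, T_split), strength drawn
  U(0.01, 0.5)), then regrows exponentially to N_hal at present; before
  T_b it is at N_hal.  Species B stays constant.
"""

from __future__ import annotations

import dataclasses

import numpy as np

SCENARIOS = ("SI", "CM", "AM", "SC")
SIZE_MODES = ("C", "E", "B")
MODELS = tuple(s + m for s in SCENARIOS for m in SIZE_MODES)

_TINY_N = 1.0  # floor on drawn sizes (individuals); U(0, x) priors touch 0


@dataclasses.dataclass
class PriorSet:
    """Independent uniform prior bounds, natural units."""

    N_hal: tuple[float, float] = (0.0, 300_000.0)
    N_lyr: tuple[float, float] = (0.0, 300_000.0)
    N_anc: tuple[float, float] = (0.0, 1_000_000.0)
    M: tuple[float, float] = (0.0, 20.0)            # both directions, 4Nm
    T_split: tuple[float, float] = (0.0, 3_200_000.0)  # years
    bottleneck_f: tuple[float, float] = (0.01, 0.5)
    gen_years: float = 2.0

    def bounds_for(self, model: str) -> dict[str, tuple[float, float]]:
        """Prior support of every parameter free under ``model``."""
        b = {"N_hal": self.N_hal, "N_lyr": self.N_lyr, "N_anc": self.N_anc,
             "T_split": self.T_split}
        scen, mode = model[:2], model[2]
        if scen in ("CM", "AM", "SC"):
            b["M_AB"] = self.M
            b["M_BA"] = self.M
        if scen == "AM":
            b["T_iso"] = self.T_split
        if scen == "SC":
            b["T_SC"] = self.T_split
        if mode == "B":
            b["T_b"] = self.T_split
            b["bottleneck_f"] = self.bottleneck_f
        return b


@dataclasses.dataclass
class ParameterVector:
    """One draw of a divergence model, natural units.

    Unused parameters are inert (0).  Times are years before present;
    sizes are numbers of (diploid) individuals; migration rates are 4Nm.
    """

    model: str
    N_hal: float
    N_lyr: float
    N_anc: float
    T_split: float
    M_AB: float = 0.0        # lineages in A trace back to B at this rate
    M_BA: float = 0.0
    T_iso: float = 0.0       # AM: migration only older than T_iso
    T_SC: float = 0.0        # SC: migration only younger than T_SC
    T_b: float = 0.0         # B: bottleneck time in species A
    bottleneck_f: float = 0.0
    gen_years: float = 2.0

    def free_values(self) -> dict[str, float]:
        return {k: getattr(self, k)
                for k in PriorSet().bounds_for(self.model)}


def check_model(model: str) -> str:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return model


def draw_parameters(model: str, priors: PriorSet,
                    rng: np.random.Generator) -> ParameterVector:
    """Draw one parameter vector; hierarchical times (T_iso, T_SC, T_b)
    are drawn uniform on (0, T_split) conditional on the drawn T_split."""
    check_model(model)
    scen, mode = model[:2], model[2]
    u = lambda lo_hi: rng.uniform(*lo_hi)
    p = ParameterVector(
        model=model,
        N_hal=max(u(priors.N_hal), _TINY_N),
        N_lyr=max(u(priors.N_lyr), _TINY_N),
        N_anc=max(u(priors.N_anc), _TINY_N),
        T_split=u(priors.T_split),
        gen_years=priors.gen_years,
    )
    if scen in ("CM", "AM", "SC"):
        p.M_AB = u(priors.M)
        p.M_BA = u(priors.M)
    if scen == "AM":
        p.T_iso = rng.uniform(0.0, p.T_split)
    if scen == "SC":
        p.T_SC = rng.uniform(0.0, p.T_split)
    if mode == "B":
        p.T_b = rng.uniform(0.0, p.T_split)
        p.bottleneck_f = u(priors.bottleneck_f)
    return p


# ---------------------------------------------------------------------------
# epoch compilation


@dataclasses.dataclass
class EpochModel:
    """Piecewise demography in coalescent units (time in 4*N_ref
    generations, sizes relative to N_ref).

    Within epoch ``e`` (``times[e] <= t < times[e+1]``, backwards from the
    present) deme ``d`` has size ``x[e, d] * exp(-beta[e, d]*(t -
    times[e]))`` and its lineages migrate to the other deme at rate
    ``mig[e, d]``.  ``ndemes[e] == 1`` marks epochs after the split, where
    every lineage sits in deme 0.
    """

    N_ref: float
    times: np.ndarray      # (nE+1,), times[0]=0, times[-1]=inf
    x: np.ndarray          # (nE, 2)
    beta: np.ndarray       # (nE, 2)
    mig: np.ndarray        # (nE, 2)
    ndemes: np.ndarray     # (nE,), int8

    def size_at(self, deme: int, t: float) -> float:
        e = int(np.searchsorted(self.times, t, side="right") - 1)
        e = min(e, len(self.ndemes) - 1)
        if self.ndemes[e] == 1:
            deme = 0
        return self.x[e, deme] * np.exp(-self.beta[e, deme]
                                        * (t - self.times[e]))


def compile_epochs(p: ParameterVector, N_ref: float | None = None
                   ) -> EpochModel:
    """Translate a natural-unit parameter vector into epoch arrays.

    The reference size defaults to the drawn N_hal (ms convention of
    scaling by a focal deme).
    """
    check_model(p.model)
    scen, mode = p.model[:2], p.model[2]
    N_ref = float(N_ref if N_ref is not None else p.N_hal)
    if N_ref <= 0:
        raise ValueError("N_ref must be positive")
    scale_t = 1.0 / (p.gen_years * 4.0 * N_ref)   # years -> coalescent units
    T_split = max(p.T_split * scale_t, 1e-12)
    x_hal, x_lyr, x_anc = (p.N_hal / N_ref, p.N_lyr / N_ref, p.N_anc / N_ref)

    # interior breakpoints (coalescent units), all within (0, T_split)
    breaks: set[float] = set()
    if mode == "E":
        breaks.add(T_split / 2.0)
    if mode == "B":
        breaks.add(min(max(p.T_b * scale_t, 0.0), T_split))
    if scen == "AM":
        breaks.add(min(max(p.T_iso * scale_t, 0.0), T_split))
    if scen == "SC":
        breaks.add(min(max(p.T_SC * scale_t, 0.0), T_split))
    interior = sorted(b for b in breaks if 0.0 < b < T_split)
    times = np.array([0.0, *interior, T_split, np.inf])
    nE = len(times) - 1

    x = np.zeros((nE, 2))
    beta = np.zeros((nE, 2))
    mig = np.zeros((nE, 2))
    ndemes = np.full(nE, 2, dtype=np.int8)
    ndemes[-1] = 1
    x[-1, :] = x_anc

    def _fill_sizes(deme: int, profile):
        """profile(t) -> (size, local decline rate) at time t (recent edge)."""
        for e in range(nE - 1):
            x[e, deme], beta[e, deme] = profile(times[e])

    def _const(size):
        return lambda t: (size, 0.0)

    def _expo(x_now, x_old, t_old):
        """Exponential from x_now at t=0 back to x_old at t_old, constant
        x_old beyond."""
        g = np.log(x_now / x_old) / t_old if t_old > 0 else 0.0

        def prof(t):
            if t >= t_old:
                return x_old, 0.0
            return x_now * np.exp(-g * t), g
        return prof

    if mode == "C":
        _fill_sizes(0, _const(x_hal))
        _fill_sizes(1, _const(x_lyr))
    elif mode == "E":
        t_on = T_split / 2.0
        _fill_sizes(0, _expo(x_hal, x_anc / 2.0, t_on))
        _fill_sizes(1, _expo(x_lyr, x_anc / 2.0, t_on))
    else:  # B
        t_b = min(max(p.T_b * scale_t, 1e-12), T_split)
        x_bot = max(p.bottleneck_f, 1e-6) * x_hal

        def prof_hal(t):
            if t >= t_b:
                return x_hal, 0.0
            g = np.log(x_hal / x_bot) / t_b
            return x_hal * np.exp(-g * t), g
        _fill_sizes(0, prof_hal)
        _fill_sizes(1, _const(x_lyr))

    # migration windows (rates in 4*N_ref*m units = per-lineage rates)
    if scen != "SI":
        if scen == "CM":
            lo, hi = 0.0, T_split
        elif scen == "AM":
            lo, hi = min(max(p.T_iso * scale_t, 0.0), T_split), T_split
        else:  # SC
            lo, hi = 0.0, min(max(p.T_SC * scale_t, 0.0), T_split)
        for e in range(nE - 1):
            mid = 0.5 * (times[e] + times[e + 1])
            if lo <= mid < hi:
                mig[e, 0] = p.M_AB
                mig[e, 1] = p.M_BA

    # guard against zero sizes
    x = np.maximum(x, 1e-9)
    return EpochModel(N_ref, times, x, beta, mig, ndemes)


@dataclasses.dataclass
class LocusSpec:
    """Per-locus simulation layout: haploid sample sizes, number of
    analyzed (synonymous) sites, per-site per-generation mutation rate,
    and the recombination-to-mutation ratio (rho = theta by default)."""

    locus_id: str
    n_A: int
    n_B: int
    L: int
    mu: float
    rho_over_theta: float = 1.0

    def __post_init__(self) -> None:
        if self.n_A < 2 or self.n_B < 2:
            raise ValueError("need >=2 haploid samples per species")
        if self.L < 1:
            raise ValueError("L must be >=1")
        if self.mu < 0:
            raise ValueError("mu must be >=0")

    def theta(self, N_ref: float) -> float:
        return 4.0 * N_ref * self.mu * self.L

    def rho(self, N_ref: float) -> float:
        return self.rho_over_theta * self.theta(N_ref)
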