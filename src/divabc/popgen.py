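"""Multilocus summary statistics for two-species polymorphism panels.

Implements the per-locus diversity and differentiation estimators
(nucleotide diversity pi, Watterson's theta_W, Tajima's D, F_ST as
1 - pi_s/pi_T), between-species and outgroup divergence, the seven
outgroup-polarized site classes of Ramos-Onsins (exclusive, fixed, shared
and exclusive-but-fixed-in-the-other-species polymorphisms) with the joint
derived site-frequency spectrum, and the fixed-order 22-statistic summary
vector consumed by the ABC machinery.

Site filtering convention: a masked site is *usable* when no ingroup
sequence is missing (N/-) there and the pooled ingroup sample carries at
most two alleles.  All denominators are counts of usable sites.
Statistics that are undefined (no segregating sites for Tajima's D, zero
total diversity for F_ST, no usable sites at all) are reported as NaN and
excluded from cross-locus moments, with exclusion counts recorded.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .alignments import MISSING, LocusAlignment

__all__ = [
    "SiteClassTable", "LocusStats", "SummaryStats", "STAT_NAMES",
    "classify_sites", "compute_locus_stats", "stats_from_counts",
    "pi", "theta_w", "tajima_d", "fst", "divergence", "summarize_dataset",
    "mutation_rate_from_outgroup", "tdiv_from_divergence",
]

#: Fixed ordering of the 22 dataset-level summary statistics: mean and SD
#: across loci of the eight per-locus statistics, plus means of the four
#: site-class counts and SDs of the shared/fixed counts.
STAT_NAMES = [
    "pi_A_mean", "pi_A_sd", "pi_B_mean", "pi_B_sd",
    "thetaW_A_mean", "thetaW_A_sd", "thetaW_B_mean", "thetaW_B_sd",
    "D_A_mean", "D_A_sd", "D_B_mean", "D_B_sd",
    "K_AB_mean", "K_AB_sd", "fst_mean", "fst_sd",
    "ss_mean", "ss_sd", "sf_mean", "sf_sd",
    "sx_A_mean", "sx_B_mean",
]

PER_LOCUS_COLUMNS = ["pi_A", "pi_B", "thetaW_A", "thetaW_B", "D_A", "D_B",
                     "K_AB", "fst", "ss", "sf", "sx_A", "sx_B"]


@dataclasses.dataclass
class SiteClassTable:
    """Counts of the seven polarized site classes plus the joint SFS.

    ``joint_sfs[i, j]`` counts retained sites whose derived allele appears
    on ``i`` of the species-A and ``j`` of the species-B haplotypes; cells
    (0,0) and (n_A,n_B) are structurally empty.  ``skipped`` tallies masked
    variable sites that could not be polarized or classified.
    """

    sx_A: int = 0
    sx_B: int = 0
    sf_A: int = 0
    sf_B: int = 0
    ss: int = 0
    sxA_fB: int = 0
    sxB_fA: int = 0
    joint_sfs: np.ndarray | None = None
    skipped: dict[str, int] = dataclasses.field(default_factory=dict)

    @property
    def total(self) -> int:
        return (self.sx_A + self.sx_B + self.sf_A + self.sf_B + self.ss
                + self.sxA_fB + self.sxB_fA)

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in
                ("sx_A", "sx_B", "sf_A", "sf_B", "ss", "sxA_fB", "sxB_fA")}


@dataclasses.dataclass
class LocusStats:
    """Per-locus statistics; undefined values are NaN (never silent 0)."""

    locus_id: str
    n_A: int
    n_B: int
    L_use: int           # usable masked sites (all within-ingroup stats)
    L_out: int           # usable sites with a callable outgroup allele
    S_A: int
    S_B: int
    pi_A: float
    pi_B: float
    thetaW_A: float
    thetaW_B: float
    D_A: float
    D_B: float
    fst: float
    K_AB: float
    K_out: float
    net_K_out: float


@dataclasses.dataclass
class SummaryStats:
    """Dataset-level 22-statistic vector plus the per-locus table."""

    values: np.ndarray
    names: list[str]
    per_locus: pd.DataFrame
    n_loci: int
    n_excluded: dict[str, int]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


# ---------------------------------------------------------------------------
# site decomposition


def _site_arrays(aln: LocusAlignment):
    """Decompose an alignment into per-masked-site allele counts.

    Returns (usable, cA, cB, allele1, allele2, out_code) over masked sites:
    ``usable`` flags complete-case, at-most-biallelic sites; ``cA``/``cB``
    count ``allele2`` (the non-reference of the two pooled-ingroup alleles,
    arbitrary for monomorphic sites where cA=cB=0).
    """
    A, B, out = aln.matrices()
    mask = aln.syn_mask
    A, B, out = A[:, mask], B[:, mask], out[mask]
    nA, nB = A.shape[0], B.shape[0]
    pooled = np.vstack([A, B])
    complete = ~(pooled == MISSING).any(axis=0)

    counts = np.zeros((4, pooled.shape[1]), dtype=np.int64)
    for c in range(4):
        counts[c] = (pooled == c).sum(axis=0)
    n_alleles = (counts > 0).sum(axis=0)
    usable = complete & (n_alleles <= 2)

    # allele1 = most frequent, allele2 = the other (or == allele1 if mono)
    order = np.argsort(counts, axis=0)
    allele1 = order[-1]
    allele2 = np.where(n_alleles >= 2, order[-2], order[-1])
    cA = (A == allele2[None, :]).sum(axis=0)
    cB = (B == allele2[None, :]).sum(axis=0)
    mono = n_alleles < 2
    cA = np.where(mono, 0, cA)
    cB = np.where(mono, 0, cB)
    return usable, cA, cB, allele1, allele2, out, nA, nB, complete, n_alleles


def classify_sites(aln: LocusAlignment) -> SiteClassTable:
    """Polarize masked variable sites by the outgroup and classify them.

    A site enters exactly one of the seven classes when it is usable,
    biallelic in the pooled ingroup, and the outgroup carries one of the
    two ingroup alleles (which is then the ancestral state).  Sites fixed
    for the derived allele in both species are not polymorphic and not
    between-ingroup fixed differences, and are excluded (tallied under
    ``skipped['fixed_both']``).
    """
    (usable, cA, cB, a1, a2, out, nA, nB,
     complete, n_alleles) = _site_arrays(aln)
    tab = SiteClassTable(joint_sfs=np.zeros((nA + 1, nB + 1), dtype=np.int64))
    skip = {"missing_ingroup": int((~complete).sum()),
            "multiallelic": int((complete & (n_alleles > 2)).sum()),
            "monomorphic_match_out": 0, "fixed_both": 0,
            "outgroup_missing": 0, "outgroup_third_allele": 0}
    for j in np.nonzero(usable)[0]:
        if cA[j] == 0 and cB[j] == 0:          # pooled ingroup monomorphic
            if out[j] == MISSING:
                skip["outgroup_missing"] += 1
            elif out[j] == a1[j]:
                skip["monomorphic_match_out"] += 1
            else:                               # fixed derived in A and B
                skip["fixed_both"] += 1
            continue
        if out[j] == MISSING:
            skip["outgroup_missing"] += 1
            continue
        if out[j] == a1[j]:
            dA, dB = int(cA[j]), int(cB[j])
        elif out[j] == a2[j]:
            dA, dB = nA - int(cA[j]), nB - int(cB[j])
        else:
            skip["outgroup_third_allele"] += 1
            continue
        _tally(tab, dA, dB, nA, nB)
    tab.skipped = skip
    return tab


def _tally(tab: SiteClassTable, dA: int, dB: int, nA: int, nB: int) -> None:
    polyA, polyB = 0 < dA < nA, 0 < dB < nB
    if polyA and polyB:
        tab.ss += 1
    elif polyA and dB == 0:
        tab.sx_A += 1
    elif polyB and dA == 0:
        tab.sx_B += 1
    elif polyA and dB == nB:
        tab.sxA_fB += 1
    elif polyB and dA == nA:
        tab.sxB_fA += 1
    elif dA == nA and dB == 0:
        tab.sf_A += 1
    elif dB == nB and dA == 0:
        tab.sf_B += 1
    else:
        return  # dA==dB==0 or fixed derived in both: not classified
    tab.joint_sfs[dA, dB] += 1


# ---------------------------------------------------------------------------
# per-locus estimators


def _pi_sum(c: np.ndarray, n: int) -> float:
    """Sum over sites of unbiased pairwise diversity, counts ``c`` of one
    allele in a sample of ``n``."""
    c = np.asarray(c, dtype=float)
    return float((2.0 * c * (n - c) / (n * (n - 1))).sum())


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i ** power for i in range(1, n)))


def tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) of Tajima's (1989) variance normalization."""
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return a1, c1 / a1, c2 / (a1 ** 2 + a2)


def tajima_d_from(S: int, pi_total: float, n: int) -> float:
    """Tajima's (1989) D from segregating sites and summed pairwise
    diversity (per locus, not per site); NaN when S == 0."""
    if S == 0:
        return math.nan
    a1, e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_total - S / a1) / math.sqrt(var)


def stats_from_counts(locus_id: str, cA: np.ndarray, cB: np.ndarray,
                      nA: int, nB: int, L: int,
                      d_out: np.ndarray | None = None,
                      L_out: int | None = None,
                      polarized: bool = True,
                      ) -> tuple[LocusStats, SiteClassTable]:
    """Per-locus statistics from per-site allele counts.

    ``cA``/``cB`` give, for every usable variable site, the count of one
    designated allele (the *derived* allele when ``polarized``) in each
    species; ``L`` is the number of usable sites.  ``d_out``, when given,
    is the per-site count of ingroup sequences differing from the outgroup
    over ``L_out`` outgroup-callable sites.  This is the common kernel
    behind both the alignment reader and the coalescent simulator.
    """
    cA = np.asarray(cA, dtype=np.int64)
    cB = np.asarray(cB, dtype=np.int64)
    n = nA + nB
    if L <= 0:
        nanstats = LocusStats(locus_id, nA, nB, 0, 0, 0, 0, *([math.nan] * 10))
        return nanstats, SiteClassTable(
            joint_sfs=np.zeros((nA + 1, nB + 1), dtype=np.int64))

    segA = (0 < cA) & (cA < nA)
    segB = (0 < cB) & (cB < nB)
    S_A, S_B = int(segA.sum()), int(segB.sum())
    piA_sum = _pi_sum(cA, nA)
    piB_sum = _pi_sum(cB, nB)
    pi_A, pi_B = piA_sum / L, piB_sum / L
    thetaW_A = S_A / _harmonic(nA) / L
    thetaW_B = S_B / _harmonic(nB) / L
    D_A = tajima_d_from(S_A, piA_sum, nA)
    D_B = tajima_d_from(S_B, piB_sum, nB)

    piT_sum = _pi_sum(cA + cB, n)
    pi_T = piT_sum / L
    pi_s = 0.5 * (pi_A + pi_B)
    fst_val = 1.0 - pi_s / pi_T if pi_T > 0 else math.nan

    cAf, cBf = cA.astype(float), cB.astype(float)
    K_AB = float((cAf * (nB - cBf) + (nA - cAf) * cBf).sum()) / (nA * nB) / L

    if d_out is not None and L_out:
        K_out = float(np.asarray(d_out, dtype=float).sum()) / n / L_out
        net_K_out = K_out - 0.5 * (pi_A + pi_B)
    else:
        K_out, L_out = math.nan, 0
        net_K_out = math.nan

    tab = SiteClassTable(joint_sfs=np.zeros((nA + 1, nB + 1), dtype=np.int64))
    if polarized:
        for dA, dB in zip(cA, cB):
            _tally(tab, int(dA), int(dB), nA, nB)

    stats = LocusStats(locus_id, nA, nB, L, L_out or 0, S_A, S_B,
                       pi_A, pi_B, thetaW_A, thetaW_B, D_A, D_B,
                       fst_val, K_AB, K_out, net_K_out)
    return stats, tab


def compute_locus_stats(aln: LocusAlignment) -> tuple[LocusStats, SiteClassTable]:
    """All per-locus statistics plus the polarized site-class table."""
    (usable, cA, cB, a1, a2, out, nA, nB, _c, _na) = _site_arrays(aln)
    L_use = int(usable.sum())
    var = usable & ((cA > 0) | (cB > 0))

    # ingroup-vs-outgroup mismatch counts at outgroup-callable usable sites
    out_ok = usable & (out != MISSING)
    L_out = int(out_ok.sum())
    d_out = np.zeros(L_out, dtype=np.int64)
    if L_out:
        idx = np.nonzero(out_ok)[0]
        cA_o, cB_o = cA[idx], cB[idx]
        tot2 = cA_o + cB_o                     # copies of allele2
        n = nA + nB
        d_out = np.where(out[idx] == a1[idx], tot2,
                         np.where(out[idx] == a2[idx], n - tot2, n))

    stats, _ = stats_from_counts(aln.locus_id, cA[var], cB[var], nA, nB,
                                 L_use, d_out=d_out, L_out=L_out,
                                 polarized=False)
    tab = classify_sites(aln)
    return stats, tab


# thin named wrappers ------------------------------------------------------

def _species_counts(aln: LocusAlignment, species: str):
    usable, cA, cB, _a1, _a2, _out, nA, nB, _c, _na = _site_arrays(aln)
    if species == "A":
        return cA[usable], nA, int(usable.sum())
    if species == "B":
        return cB[usable], nB, int(usable.sum())
    raise ValueError("species must be 'A' or 'B'")


def pi(aln: LocusAlignment, species: str) -> float:
    """Per-site nucleotide diversity (unbiased pairwise); NaN if no usable
    sites."""
    c, n, L = _species_counts(aln, species)
    return _pi_sum(c, n) / L if L else math.nan


def theta_w(aln: LocusAlignment, species: str) -> float:
    """Watterson's estimator per usable site: S / a_1 / L."""
    c, n, L = _species_counts(aln, species)
    if not L:
        return math.nan
    S = int(((0 < c) & (c < n)).sum())
    return S / _harmonic(n) / L


def tajima_d(aln: LocusAlignment, species: str) -> float:
    c, n, L = _species_counts(aln, species)
    if not L:
        return math.nan
    S = int(((0 < c) & (c < n)).sum())
    return tajima_d_from(S, _pi_sum(c, n), n)


def fst(aln: LocusAlignment) -> float:
    """1 - pi_s/pi_T with pi_s the unweighted mean of the two species' pi."""
    return compute_locus_stats(aln)[0].fst


def divergence(aln: LocusAlignment) -> tuple[float, float, float]:
    """(K_AB, K_out, net_K_out) per usable site; net subtracts the mean
    within-ingroup diversity (Nei net-distance convention, no multiple-hit
    correction)."""
    s = compute_locus_stats(aln)[0]
    return s.K_AB, s.K_out, s.net_K_out


# ---------------------------------------------------------------------------
# dataset-level summary


def per_locus_frame(results: list[tuple[LocusStats, SiteClassTable]]
                    ) -> pd.DataFrame:
    rows = []
    for stats, tab in results:
        rows.append({
            "locus_id": stats.locus_id, "n_A": stats.n_A, "n_B": stats.n_B,
            "pi_A": stats.pi_A, "pi_B": stats.pi_B,
            "thetaW_A": stats.thetaW_A, "thetaW_B": stats.thetaW_B,
            "D_A": stats.D_A, "D_B": stats.D_B, "K_AB": stats.K_AB,
            "fst": stats.fst, "ss": tab.ss, "sf": tab.sf_A + tab.sf_B,
            "sx_A": tab.sx_A, "sx_B": tab.sx_B,
            "sxA_fB": tab.sxA_fB, "sxB_fA": tab.sxB_fA,
            "K_out": stats.K_out, "net_K_out": stats.net_K_out,
            "L_use": stats.L_use, "S_A": stats.S_A, "S_B": stats.S_B,
        })
    return pd.DataFrame(rows)


def summarize_dataset(results: list[tuple[LocusStats, SiteClassTable]]
                      ) -> SummaryStats:
    """Collapse per-locus statistics into the fixed-order 22-vector.

    Cross-locus means and SDs (population SD, ddof=0) of the eight real
    statistics; loci where a statistic is undefined (NaN) are excluded
    from that statistic's moments only, with the exclusion count recorded.
    If no locus contributes, the moment is reported as 0 (count logged).
    """
    df = per_locus_frame(results)
    X = df[PER_LOCUS_COLUMNS].to_numpy(float)
    values, excluded = summarize_matrix(X)
    return SummaryStats(values, list(STAT_NAMES), df, len(results), excluded)


def summarize_matrix(X: np.ndarray) -> tuple[np.ndarray, dict[str, int]]:
    """Collapse a (n_loci, 12) per-locus matrix (columns in
    PER_LOCUS_COLUMNS order) into the 22-vector; NaN entries are excluded
    per column, an all-NaN column yields 0 moments."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    values: list[float] = []
    excluded: dict[str, int] = {}

    def _moments(col, want_sd=True):
        x = X[:, PER_LOCUS_COLUMNS.index(col)]
        ok = np.isfinite(x)
        excluded[col] = int((~ok).sum())
        if not ok.any():
            return (0.0, 0.0) if want_sd else (0.0,)
        m = float(x[ok].mean())
        return (m, float(x[ok].std(ddof=0))) if want_sd else (m,)

    for col in ("pi_A", "pi_B", "thetaW_A", "thetaW_B",
                "D_A", "D_B", "K_AB", "fst"):
        values.extend(_moments(col))
    for col in ("ss", "sf"):
        values.extend(_moments(col))
    for col in ("sx_A", "sx_B"):
        values.extend(_moments(col, want_sd=False))
    return np.array(values, dtype=float), excluded


# ---------------------------------------------------------------------------
# molecular-clock conversions


def mutation_rate_from_outgroup(net_K_out: float, T_div_years: float = 5e6,
                                gen_years: float = 2.0) -> float:
    """Per-site per-generation mutation rate from net outgroup divergence,
    mu = net_K / (2 * T_div_years / gen_years)."""
    if T_div_years <= 0 or gen_years <= 0:
        raise ValueError("divergence and generation times must be positive")
    return net_K_out / (2.0 * T_div_years / gen_years)


def tdiv_from_divergence(K_AB: float, mu: float,
                         gen_years: float | None = None) -> float:
    """Divergence time T = K / (2 mu) in generations (or years when
    ``gen_years`` is given)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    t = K_AB / (2.0 * mu)
    return t * gen_years if gen_years else t
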