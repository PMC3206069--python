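"""Shared fixtures and the independent brute-force statistics oracle.

The oracle functions here re-derive every per-locus statistic by explicit
enumeration over haplotype pairs and per-site rule application -- they
share no code with the package's vectorized implementations and serve as
the reference in equivalence tests.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from divabc.alignments import LocusAlignment
from divabc.coalescent import Workspace


@pytest.fixture(scope="session")
def workspace():
    return Workspace(256)


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    from divabc.synth import worked_example_fixture
    d = tmp_path_factory.mktemp("worked")
    return worked_example_fixture(d)


def random_alignment(rng: np.random.Generator, max_n: int = 10,
                     max_L: int = 50) -> LocusAlignment:
    """Random small alignment with missing data, gaps and a mask."""
    nA = int(rng.integers(2, max_n // 2 + 1))
    nB = int(rng.integers(2, max_n // 2 + 1))
    L = int(rng.integers(1, max_L + 1))
    alphabet = np.array(list("ACGTN-"))
    # skew towards low diversity so many sites are mono/bi-allelic
    probs = np.array([0.55, 0.25, 0.08, 0.04, 0.05, 0.03])
    mat = rng.choice(alphabet, size=(nA + nB + 1, L), p=probs)
    # make a fraction of columns monomorphic
    mono = rng.random(L) < 0.4
    mat[:, mono] = rng.choice(alphabet[:4], size=mono.sum())
    seqs = ["".join(row) for row in mat]
    mask = rng.random(L) < 0.8
    return LocusAlignment("rand", seqs[:nA], seqs[nA:nA + nB], seqs[-1],
                          mask)


# ---------------------------------------------------------------------------
# brute-force oracle


def _usable_columns(aln: LocusAlignment):
    """Masked columns with no ingroup N/- and at most two ingroup alleles."""
    cols = []
    ingroup = aln.seqs_A + aln.seqs_B
    for j in range(aln.L):
        if not aln.syn_mask[j]:
            continue
        chars = [s[j] for s in ingroup]
        if any(c in "N-" for c in chars):
            continue
        if len(set(chars)) > 2:
            continue
        cols.append(j)
    return cols


def brute_pi(aln: LocusAlignment, species: str) -> float:
    seqs = aln.seqs_A if species == "A" else aln.seqs_B
    cols = _usable_columns(aln)
    if not cols:
        return math.nan
    total = 0
    npairs = 0
    for a, b in itertools.combinations(seqs, 2):
        npairs += 1
        total += sum(1 for j in cols if a[j] != b[j])
    return total / npairs / len(cols)


def brute_pi_total(aln: LocusAlignment) -> float:
    cols = _usable_columns(aln)
    if not cols:
        return math.nan
    seqs = aln.seqs_A + aln.seqs_B
    total = 0
    npairs = 0
    for a, b in itertools.combinations(seqs, 2):
        npairs += 1
        total += sum(1 for j in cols if a[j] != b[j])
    return total / npairs / len(cols)


def brute_S(aln: LocusAlignment, species: str) -> int:
    seqs = aln.seqs_A if species == "A" else aln.seqs_B
    cols = _usable_columns(aln)
    return sum(1 for j in cols if len({s[j] for s in seqs}) == 2)


def brute_theta_w(aln: LocusAlignment, species: str) -> float:
    seqs = aln.seqs_A if species == "A" else aln.seqs_B
    cols = _usable_columns(aln)
    if not cols:
        return math.nan
    n = len(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    return brute_S(aln, species) / a1 / len(cols)


def brute_tajima_d(aln: LocusAlignment, species: str) -> float:
    """Textbook Tajima (1989) formula coded independently."""
    seqs = aln.seqs_A if species == "A" else aln.seqs_B
    cols = _usable_columns(aln)
    if not cols:
        return math.nan
    n = len(seqs)
    S = brute_S(aln, species)
    if S == 0:
        return math.nan
    k_hat = brute_pi(aln, species) * len(cols)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0:
        return math.nan
    return (k_hat - S / a1) / denom


def brute_fst(aln: LocusAlignment) -> float:
    pi_T = brute_pi_total(aln)
    if not pi_T or math.isnan(pi_T):
        return math.nan
    pi_s = (brute_pi(aln, "A") + brute_pi(aln, "B")) / 2
    return 1 - pi_s / pi_T


def brute_K_AB(aln: LocusAlignment) -> float:
    cols = _usable_columns(aln)
    if not cols:
        return math.nan
    total = sum(sum(1 for j in cols if a[j] != b[j])
                for a in aln.seqs_A for b in aln.seqs_B)
    return total / (len(aln.seqs_A) * len(aln.seqs_B)) / len(cols)


def brute_classify(aln: LocusAlignment) -> dict:
    """Per-site application of the seven polarized class rules."""
    counts = dict(sx_A=0, sx_B=0, sf_A=0, sf_B=0, ss=0, sxA_fB=0,
                  sxB_fA=0)
    cols = _usable_columns(aln)
    for j in cols:
        charsA = [s[j] for s in aln.seqs_A]
        charsB = [s[j] for s in aln.seqs_B]
        pooled = set(charsA + charsB)
        out = aln.outgroup[j]
        if len(pooled) == 1:
            continue  # monomorphic ingroup (fixed_both handled elsewhere)
        if out in "N-" or out not in pooled:
            continue
        derived = (pooled - {out}).pop()
        fA = charsA.count(derived) / len(charsA)
        fB = charsB.count(derived) / len(charsB)
        if 0 < fA < 1 and 0 < fB < 1:
            counts["ss"] += 1
        elif 0 < fA < 1 and fB == 0:
            counts["sx_A"] += 1
        elif 0 < fB < 1 and fA == 0:
            counts["sx_B"] += 1
        elif 0 < fA < 1 and fB == 1:
            counts["sxA_fB"] += 1
        elif 0 < fB < 1 and fA == 1:
            counts["sxB_fA"] += 1
        elif fA == 1 and fB == 0:
            counts["sf_A"] += 1
        elif fB == 1 and fA == 0:
            counts["sf_B"] += 1
    return counts
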