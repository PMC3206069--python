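"""Hudson-style two-deme coalescent simulator with recombination.

Simulates the ancestral recombination graph (ARG) of a two-population
sample backwards in time under the piecewise demographies of
:mod:`divabc.demography`, drops infinite-sites mutations on ancestral
material at rate theta (= 4*N_ref*mu*L) per unit branch length, and
returns segregating sites as (position, derived-carrier bitset) records
from which haplotype matrices, per-locus summary statistics and ms-style
text output are derived.

Scaling conventions (ms-compatible): time in units of 4*N_ref
generations; a pair of lineages in a deme of relative size ``x`` coalesces
at rate ``2/x``; each lineage accumulates mutations at rate ``theta`` per
unit of carried ancestral sequence length, recombines at rate ``rho`` per
unit of carried breadth (rightmost minus leftmost ancestral coordinate),
and migrates at its deme's per-lineage rate ``M = 4*N_ref*m``.

Each lineage carries a linked list of genomic segments, each tagged with
the bitset of sampled haplotypes descending from it.  Segments whose
bitset reaches the full sample have found their MRCA and are discarded;
the simulation ends when no ancestral material remains.  Because the
ancestral state of every mutation is known, polarization of simulated
sites is exact and no outgroup sequence is simulated.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from . import popgen
from .demography import EpochModel, LocusSpec, ParameterVector, compile_epochs

__all__ = ["SimulatedLocus", "Workspace", "simulate_locus",
           "simulate_dataset", "locus_stats_vector", "haplotype_matrix",
           "ms_block", "LOCUS_VEC_COLUMNS"]

#: order of the per-locus statistic vector produced by the fast kernel;
#: the first 12 entries match popgen.PER_LOCUS_COLUMNS.
LOCUS_VEC_COLUMNS = popgen.PER_LOCUS_COLUMNS + ["sxA_fB", "sxB_fA"]

_SEG_CAP = 1 << 15
_LIN_CAP = 1 << 12
_TMP_CAP = 1 << 13
_SITE_CAP = 1 << 15
_MRCA_CAP = 1 << 14
_MAX_EVENTS = 4_000_000

_STATUS_MSG = {
    1: "segregating-site buffer overflow",
    2: "segment pool exhausted",
    3: "lineage buffer exhausted",
    4: "MRCA-interval buffer exhausted",
    5: "event guard tripped (runaway recombination?)",
    6: "merge scratch buffer exhausted",
}


class Workspace:
    """Reusable scratch buffers for the ARG kernel (one per thread)."""

    def __init__(self, n_max: int = 256):
        nw = (n_max + 63) // 64
        self.nw = nw
        self.seg_l = np.empty(_SEG_CAP)
        self.seg_r = np.empty(_SEG_CAP)
        self.seg_bits = np.empty((_SEG_CAP, nw), dtype=np.uint64)
        self.seg_next = np.empty(_SEG_CAP, dtype=np.int64)
        self.lin_head = np.empty(_LIN_CAP, dtype=np.int64)
        self.lin_deme = np.empty(_LIN_CAP, dtype=np.int64)
        self.lin_len = np.empty(_LIN_CAP)
        self.lin_lmin = np.empty(_LIN_CAP)
        self.lin_rmax = np.empty(_LIN_CAP)
        self.tmp_l = np.empty(_TMP_CAP)
        self.tmp_r = np.empty(_TMP_CAP)
        self.tmp_bits = np.empty((_TMP_CAP, nw), dtype=np.uint64)
        self.pos = np.empty(_SITE_CAP)
        self.bits = np.empty((_SITE_CAP, nw), dtype=np.uint64)
        self.dA = np.empty(_SITE_CAP, dtype=np.int64)
        self.dB = np.empty(_SITE_CAP, dtype=np.int64)
        self.mrca = np.empty((_MRCA_CAP, 3))


@dataclasses.dataclass
class SimulatedLocus:
    """Segregating sites of one simulated locus.

    ``positions`` are continuous coordinates on (0, 1); ``dA``/``dB`` are
    derived-allele counts per site in each species; ``bits`` holds the
    derived-carrier bitsets (haplotypes 0..n_A-1 are species A);
    ``mrca`` rows are (left, right, time) marginal-MRCA intervals.
    """

    spec: LocusSpec
    positions: np.ndarray
    dA: np.ndarray
    dB: np.ndarray
    bits: np.ndarray
    mrca: np.ndarray
    theta: float
    rho: float

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def site_indices(self) -> np.ndarray:
        """Map continuous positions to discrete site columns 0..L-1."""
        return np.minimum((self.positions * self.spec.L).astype(np.int64),
                          self.spec.L - 1)


@njit(cache=True)
def _pc64(x):
    x = np.uint64(x)
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + \
        ((x >> np.uint64(2)) & np.uint64(0x3333333333333333))
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return np.int64((x * np.uint64(0x0101010101010101)) >> np.uint64(56))


@njit(cache=True)
def _coal_tau(k, x0, beta, dt):
    """Waiting time to next coalescence among k lineages in a deme of size
    x0*exp(-beta*(dt+tau)) (dt = elapsed time in epoch)."""
    if k < 2:
        return np.inf
    c = k * (k - 1.0) * np.exp(beta * dt) / x0
    E = -np.log(np.random.random())
    if beta == 0.0:
        return E / c
    arg = 1.0 + beta * E / c
    if arg <= 0.0:
        return np.inf
    return np.log(arg) / beta


@njit(cache=True)
def _arg_kernel(nA, nB, theta, rho, times, ex, ebeta, emig, endemes, seed,
                seg_l, seg_r, seg_bits, seg_next,
                lin_head, lin_deme, lin_len, lin_lmin, lin_rmax,
                tmp_l, tmp_r, tmp_bits,
                out_pos, out_bits, out_dA, out_dB, out_mrca,
                full, maskA):
    np.random.seed(seed)
    n = nA + nB
    NW = seg_bits.shape[1]
    SEG_CAP = seg_l.shape[0]
    LIN_CAP = lin_head.shape[0]
    TMP_CAP = tmp_l.shape[0]
    SITE_CAP = out_pos.shape[0]
    MRCA_CAP = out_mrca.shape[0]

    # segment free list (stack)
    free_stack = np.empty(SEG_CAP, dtype=np.int64)
    for i in range(SEG_CAP):
        free_stack[i] = SEG_CAP - 1 - i
    free_top = SEG_CAP

    # initial lineages: one full-locus segment each
    nlin = n
    for i in range(n):
        free_top -= 1
        s = free_stack[free_top]
        seg_l[s] = 0.0
        seg_r[s] = 1.0
        for w in range(NW):
            seg_bits[s, w] = np.uint64(0)
        seg_bits[s, i // 64] = np.uint64(1) << np.uint64(i % 64)
        seg_next[s] = -1
        lin_head[i] = s
        lin_deme[i] = 0 if i < nA else 1
        lin_len[i] = 1.0
        lin_lmin[i] = 0.0
        lin_rmax[i] = 1.0

    t = 0.0
    e = 0
    nE = endemes.shape[0]
    nsites = 0
    nmrca = 0
    events = 0

    while nlin > 0:
        events += 1
        if events > _MAX_EVENTS:
            return 5, nsites, nmrca, t

        k0 = 0
        k1 = 0
        tot_len = 0.0
        tot_span = 0.0
        for i in range(nlin):
            if lin_deme[i] == 0:
                k0 += 1
            else:
                k1 += 1
            tot_len += lin_len[i]
            tot_span += lin_rmax[i] - lin_lmin[i]

        M0 = emig[e, 0]
        M1 = emig[e, 1]
        R_mig = k0 * M0 + k1 * M1
        R_rec = rho * tot_span
        R_mut = theta * tot_len
        R_const = R_mig + R_rec + R_mut
        if R_const > 0.0:
            tau_const = -np.log(np.random.random()) / R_const
        else:
            tau_const = np.inf

        dt = t - times[e]
        tau0 = _coal_tau(k0, ex[e, 0], ebeta[e, 0], dt)
        if endemes[e] == 2:
            tau1 = _coal_tau(k1, ex[e, 1], ebeta[e, 1], dt)
        else:
            tau1 = np.inf

        tau = tau_const
        ev = 0  # 0 const-bundle, 1 coal deme0, 2 coal deme1
        if tau0 < tau:
            tau = tau0
            ev = 1
        if tau1 < tau:
            tau = tau1
            ev = 2

        if e < nE - 1 and t + tau >= times[e + 1]:
            t = times[e + 1]
            e += 1
            if endemes[e] == 1:
                for i in range(nlin):
                    lin_deme[i] = 0
            continue
        t += tau

        if ev == 0:
            u = np.random.random() * R_const
            if u < R_mut:
                # ---- mutation: lineage weighted by carried length
                target = np.random.random() * tot_len
                li = 0
                acc = 0.0
                for i in range(nlin):
                    acc += lin_len[i]
                    if target < acc or i == nlin - 1:
                        li = i
                        break
                rem = target - (acc - lin_len[li])
                if rem < 0.0:
                    rem = 0.0
                s = lin_head[li]
                while s != -1:
                    seg_len = seg_r[s] - seg_l[s]
                    if rem < seg_len or seg_next[s] == -1:
                        if nsites >= SITE_CAP:
                            return 1, nsites, nmrca, t
                        p = seg_l[s] + rem
                        if p >= seg_r[s]:
                            p = seg_r[s] - 1e-15
                        out_pos[nsites] = p
                        da = 0
                        db = 0
                        for w in range(NW):
                            b = seg_bits[s, w]
                            out_bits[nsites, w] = b
                            ca = _pc64(b & maskA[w])
                            da += ca
                            db += _pc64(b) - ca
                        out_dA[nsites] = da
                        out_dB[nsites] = db
                        nsites += 1
                        break
                    rem -= seg_len
                    s = seg_next[s]
            elif u < R_mut + R_rec:
                # ---- recombination: lineage weighted by breadth
                target = (np.random.random() * R_rec) / rho
                li = 0
                acc = 0.0
                for i in range(nlin):
                    acc += lin_rmax[i] - lin_lmin[i]
                    if target < acc or i == nlin - 1:
                        li = i
                        break
                span = lin_rmax[li] - lin_lmin[li]
                bp = lin_lmin[li] + np.random.random() * span
                if bp > lin_lmin[li] and bp < lin_rmax[li]:
                    if nlin >= LIN_CAP:
                        return 3, nsites, nmrca, t
                    # split the segment list of li at bp
                    s = lin_head[li]
                    prev = -1
                    rhead = -1
                    while s != -1:
                        if seg_r[s] > bp:
                            if seg_l[s] >= bp:
                                rhead = s
                                if prev == -1:
                                    lin_head[li] = -1
                                else:
                                    seg_next[prev] = -1
                            else:
                                if free_top <= 0:
                                    return 2, nsites, nmrca, t
                                free_top -= 1
                                ns = free_stack[free_top]
                                seg_l[ns] = bp
                                seg_r[ns] = seg_r[s]
                                for w in range(NW):
                                    seg_bits[ns, w] = seg_bits[s, w]
                                seg_next[ns] = seg_next[s]
                                seg_r[s] = bp
                                seg_next[s] = -1
                                rhead = ns
                            break
                        prev = s
                        s = seg_next[s]
                    if rhead != -1 and lin_head[li] != -1:
                        nj = nlin
                        lin_head[nj] = rhead
                        lin_deme[nj] = lin_deme[li]
                        # recompute metadata for both halves
                        for idx in range(2):
                            lid = li if idx == 0 else nj
                            s2 = lin_head[lid]
                            tl = 0.0
                            lmin = 2.0
                            rmax = -1.0
                            while s2 != -1:
                                tl += seg_r[s2] - seg_l[s2]
                                if seg_l[s2] < lmin:
                                    lmin = seg_l[s2]
                                if seg_r[s2] > rmax:
                                    rmax = seg_r[s2]
                                s2 = seg_next[s2]
                            lin_len[lid] = tl
                            lin_lmin[lid] = lmin
                            lin_rmax[lid] = rmax
                        nlin += 1
                    elif rhead != -1 and lin_head[li] == -1:
                        # all material right of bp: undo (no-op split)
                        lin_head[li] = rhead
            else:
                # ---- migration
                u2 = np.random.random() * R_mig
                d = 0 if u2 < k0 * M0 else 1
                kd = k0 if d == 0 else k1
                target = np.int64(np.random.random() * kd)
                if target >= kd:
                    target = kd - 1
                cnt = -1
                for i in range(nlin):
                    if lin_deme[i] == d:
                        cnt += 1
                        if cnt == target:
                            lin_deme[i] = 1 - d
                            break
        else:
            # ---- coalescence in deme d
            d = 0 if ev == 1 else 1
            kd = k0 if d == 0 else k1
            r1 = np.int64(np.random.random() * kd)
            if r1 >= kd:
                r1 = kd - 1
            r2 = np.int64(np.random.random() * (kd - 1))
            if r2 >= kd - 1:
                r2 = kd - 2
            if r2 >= r1:
                r2 += 1
            ia = -1
            ib = -1
            cnt = -1
            for i in range(nlin):
                if lin_deme[i] == d:
                    cnt += 1
                    if cnt == r1:
                        ia = i
                    if cnt == r2:
                        ib = i
            # merge segment lists of ia and ib into tmp arrays
            pa = lin_head[ia]
            pb = lin_head[ib]
            la = seg_l[pa] if pa != -1 else 0.0
            ra = seg_r[pa] if pa != -1 else 0.0
            lb = seg_l[pb] if pb != -1 else 0.0
            rb = seg_r[pb] if pb != -1 else 0.0
            tc = 0
            while pa != -1 or pb != -1:
                if pb == -1 or (pa != -1 and ra <= lb):
                    cl = la
                    cr = ra
                    src = pa
                    src2 = -1
                    pa = seg_next[pa]
                    if pa != -1:
                        la = seg_l[pa]
                        ra = seg_r[pa]
                elif pa == -1 or rb <= la:
                    cl = lb
                    cr = rb
                    src = pb
                    src2 = -1
                    pb = seg_next[pb]
                    if pb != -1:
                        lb = seg_l[pb]
                        rb = seg_r[pb]
                else:
                    # overlapping heads
                    if la < lb:
                        cl = la
                        cr = lb
                        src = pa
                        src2 = -1
                        la = lb
                    elif lb < la:
                        cl = lb
                        cr = la
                        src = pb
                        src2 = -1
                        lb = la
                    else:
                        cl = la
                        cr = ra if ra < rb else rb
                        src = pa
                        src2 = pb
                        la = cr
                        lb = cr
                        if la >= ra:
                            pa = seg_next[pa]
                            if pa != -1:
                                la = seg_l[pa]
                                ra = seg_r[pa]
                        if lb >= rb:
                            pb = seg_next[pb]
                            if pb != -1:
                                lb = seg_l[pb]
                                rb = seg_r[pb]
                # emit chunk (cl, cr) with bits from src (| src2)
                is_full = True
                for w in range(NW):
                    bw = seg_bits[src, w]
                    if src2 != -1:
                        bw |= seg_bits[src2, w]
                    tmp_bits_w = bw
                    if tmp_bits_w != full[w]:
                        is_full = False
                    if tc < TMP_CAP:
                        tmp_bits[tc, w] = bw
                if tc >= TMP_CAP:
                    return 6, nsites, nmrca, t
                if src2 != -1 and is_full:
                    if nmrca >= MRCA_CAP:
                        return 4, nsites, nmrca, t
                    out_mrca[nmrca, 0] = cl
                    out_mrca[nmrca, 1] = cr
                    out_mrca[nmrca, 2] = t
                    nmrca += 1
                else:
                    # try to extend previous chunk
                    if tc > 0 and tmp_r[tc - 1] == cl:
                        same = True
                        for w in range(NW):
                            if tmp_bits[tc - 1, w] != tmp_bits[tc, w]:
                                same = False
                                break
                        if same:
                            tmp_r[tc - 1] = cr
                            continue
                    tmp_l[tc] = cl
                    tmp_r[tc] = cr
                    tc += 1
            # free old nodes
            for old in (lin_head[ia], lin_head[ib]):
                s2 = old
                while s2 != -1:
                    nxt = seg_next[s2]
                    free_stack[free_top] = s2
                    free_top += 1
                    s2 = nxt
            # build merged lineage in slot ia; drop ib (swap with last)
            if tc == 0:
                lin_head[ia] = -1
            else:
                prev = -1
                tl = 0.0
                for c in range(tc):
                    if free_top <= 0:
                        return 2, nsites, nmrca, t
                    free_top -= 1
                    s2 = free_stack[free_top]
                    seg_l[s2] = tmp_l[c]
                    seg_r[s2] = tmp_r[c]
                    for w in range(NW):
                        seg_bits[s2, w] = tmp_bits[c, w]
                    seg_next[s2] = -1
                    if prev == -1:
                        lin_head[ia] = s2
                    else:
                        seg_next[prev] = s2
                    prev = s2
                    tl += tmp_r[c] - tmp_l[c]
                lin_len[ia] = tl
                lin_lmin[ia] = tmp_l[0]
                lin_rmax[ia] = tmp_r[tc - 1]
            # remove ib (and ia too if empty)
            rm1 = ib
            rm2 = ia if tc == 0 else -1
            if rm2 > rm1:
                rm1, rm2 = rm2, rm1
            for rm in (rm1, rm2):
                if rm == -1:
                    continue
                last = nlin - 1
                if rm != last:
                    lin_head[rm] = lin_head[last]
                    lin_deme[rm] = lin_deme[last]
                    lin_len[rm] = lin_len[last]
                    lin_lmin[rm] = lin_lmin[last]
                    lin_rmax[rm] = lin_rmax[last]
                nlin -= 1

    return 0, nsites, nmrca, t


@njit(cache=True)
def _locus_stats_kernel(dA, dB, nsites, nA, nB, L,
                        a1A, e1A, e2A, a1B, e1B, e2B, a1T):
    """Per-locus 14-vector from per-site derived counts (see
    LOCUS_VEC_COLUMNS for the ordering)."""
    out = np.empty(14)
    piA = 0.0
    piB = 0.0
    piT = 0.0
    kab = 0.0
    SA = 0
    SB = 0
    ss = 0
    sfA = 0
    sfB = 0
    sxA = 0
    sxB = 0
    sxAfB = 0
    sxBfA = 0
    n = nA + nB
    for s in range(nsites):
        a = dA[s]
        b = dB[s]
        piA += 2.0 * a * (nA - a) / (nA * (nA - 1.0))
        piB += 2.0 * b * (nB - b) / (nB * (nB - 1.0))
        c = a + b
        piT += 2.0 * c * (n - c) / (n * (n - 1.0))
        kab += (a * (nB - b) + (nA - a) * b) / (nA * 1.0 * nB)
        pA = 0 < a < nA
        pB = 0 < b < nB
        if pA:
            SA += 1
        if pB:
            SB += 1
        if pA and pB:
            ss += 1
        elif pA and b == 0:
            sxA += 1
        elif pB and a == 0:
            sxB += 1
        elif pA and b == nB:
            sxAfB += 1
        elif pB and a == nA:
            sxBfA += 1
        elif a == nA and b == 0:
            sfA += 1
        elif b == nB and a == 0:
            sfB += 1
    out[0] = piA / L
    out[1] = piB / L
    out[2] = SA / a1A / L
    out[3] = SB / a1B / L
    for idx in range(2):
        S = SA if idx == 0 else SB
        pisum = piA if idx == 0 else piB
        a1 = a1A if idx == 0 else a1B
        e1 = e1A if idx == 0 else e1B
        e2 = e2A if idx == 0 else e2B
        if S == 0:
            out[4 + idx] = np.nan
        else:
            var = e1 * S + e2 * S * (S - 1.0)
            out[4 + idx] = ((pisum - S / a1) / np.sqrt(var)
                            if var > 0 else np.nan)
    out[6] = kab / L
    pis = 0.5 * (out[0] + out[1])
    out[7] = 1.0 - pis / (piT / L) if piT > 0 else np.nan
    out[8] = ss
    out[9] = sfA + sfB
    out[10] = sxA
    out[11] = sxB
    out[12] = sxAfB
    out[13] = sxBfA
    return out


# ---------------------------------------------------------------------------
# python-facing wrappers


def _full_and_maskA(n: int, nA: int, nw: int):
    full = np.zeros(nw, dtype=np.uint64)
    maskA = np.zeros(nw, dtype=np.uint64)
    for i in range(n):
        full[i // 64] |= np.uint64(1) << np.uint64(i % 64)
    for i in range(nA):
        maskA[i // 64] |= np.uint64(1) << np.uint64(i % 64)
    return full, maskA


def _run_kernel(epochs: EpochModel, spec: LocusSpec, seed: int,
                ws: Workspace):
    theta = spec.theta(epochs.N_ref)
    rho = spec.rho(epochs.N_ref)
    n = spec.n_A + spec.n_B
    nw = ws.nw
    if n > nw * 64:
        raise ValueError(f"sample size {n} exceeds workspace capacity")
    full, maskA = _full_and_maskA(n, spec.n_A, nw)
    status, nsites, nmrca, t_end = _arg_kernel(
        spec.n_A, spec.n_B, theta, rho,
        epochs.times, epochs.x, epochs.beta, epochs.mig, epochs.ndemes,
        np.int64(seed % (2 ** 31)),
        ws.seg_l, ws.seg_r, ws.seg_bits, ws.seg_next,
        ws.lin_head, ws.lin_deme, ws.lin_len, ws.lin_lmin, ws.lin_rmax,
        ws.tmp_l, ws.tmp_r, ws.tmp_bits,
        ws.pos, ws.bits, ws.dA, ws.dB, ws.mrca,
        full, maskA)
    if status != 0:
        raise RuntimeError(
            f"coalescent simulation failed for locus {spec.locus_id!r}: "
            f"{_STATUS_MSG.get(status, status)} "
            f"(theta={theta:.3g}, rho={rho:.3g})")
    return nsites, nmrca, t_end, theta, rho


_tajima_cache: dict[int, tuple[float, float, float]] = {}


def _tc(n: int):
    if n not in _tajima_cache:
        _tajima_cache[n] = popgen.tajima_constants(n)
    return _tajima_cache[n]


def simulate_locus(epochs: EpochModel, spec: LocusSpec, seed: int,
                   workspace: Workspace | None = None) -> SimulatedLocus:
    """Simulate one locus; returns sites, carrier bitsets and marginal-MRCA
    intervals."""
    ws = workspace or Workspace(spec.n_A + spec.n_B)
    nsites, nmrca, _t, theta, rho = _run_kernel(epochs, spec, seed, ws)
    order = np.argsort(ws.pos[:nsites], kind="stable")
    return SimulatedLocus(
        spec=spec,
        positions=ws.pos[:nsites][order].copy(),
        dA=ws.dA[:nsites][order].copy(),
        dB=ws.dB[:nsites][order].copy(),
        bits=ws.bits[:nsites][order].copy(),
        mrca=ws.mrca[:nmrca].copy(),
        theta=theta, rho=rho)


def locus_stats_vector(sim_or_counts, nA=None, nB=None, L=None) -> np.ndarray:
    """Per-locus 14-statistic vector (LOCUS_VEC_COLUMNS order)."""
    if isinstance(sim_or_counts, SimulatedLocus):
        sim = sim_or_counts
        dA, dB = sim.dA, sim.dB
        nA, nB, L = sim.spec.n_A, sim.spec.n_B, sim.spec.L
        nsites = sim.n_sites
    else:
        dA, dB = sim_or_counts
        dA = np.asarray(dA, dtype=np.int64)
        dB = np.asarray(dB, dtype=np.int64)
        nsites = len(dA)
    a1A, e1A, e2A = _tc(nA)
    a1B, e1B, e2B = _tc(nB)
    a1T, _, _ = _tc(nA + nB)
    return _locus_stats_kernel(np.ascontiguousarray(dA),
                               np.ascontiguousarray(dB),
                               nsites, nA, nB, L,
                               a1A, e1A, e2A, a1B, e1B, e2B, a1T)


def simulate_dataset(params: ParameterVector, loci: list[LocusSpec],
                     seed: int, workspace: Workspace | None = None,
                     return_sims: bool = False):
    """Simulate all loci independently under one parameter draw.

    Returns ``(per_locus, sims)``: a (n_loci, 14) matrix of per-locus
    statistics and, when ``return_sims``, the SimulatedLocus objects.
    Collapse ``per_locus[:, :12]`` with :func:`popgen.summarize_matrix`
    to obtain the 22-statistic dataset summary.
    """
    epochs = compile_epochs(params)
    n_max = max(s.n_A + s.n_B for s in loci)
    ws = workspace or Workspace(n_max)
    per_locus = np.empty((len(loci), 14))
    sims = []
    locus_seeds = np.random.default_rng(seed).integers(
        0, 2 ** 31, size=len(loci))
    for j, spec in enumerate(loci):
        sub_seed = int(locus_seeds[j])
        if return_sims:
            sim = simulate_locus(epochs, spec, sub_seed, ws)
            per_locus[j] = locus_stats_vector(sim)
            sims.append(sim)
        else:
            nsites, _nm, _t, _th, _rh = _run_kernel(epochs, spec, sub_seed, ws)
            per_locus[j] = locus_stats_vector(
                (ws.dA[:nsites], ws.dB[:nsites]), spec.n_A, spec.n_B, spec.L)
    return per_locus, sims


def dataset_summary(params: ParameterVector, loci: list[LocusSpec],
                    seed: int, workspace: Workspace | None = None
                    ) -> np.ndarray:
    """22-statistic summary vector of one simulated multilocus dataset."""
    per_locus, _ = simulate_dataset(params, loci, seed, workspace)
    values, _excl = popgen.summarize_matrix(per_locus[:, :12])
    return values


# ---------------------------------------------------------------------------
# interoperability


def haplotype_matrix(sim: SimulatedLocus) -> np.ndarray:
    """(n, S) 0/1 derived-allele matrix (rows: A haplotypes then B)."""
    n = sim.spec.n_A + sim.spec.n_B
    if sim.n_sites == 0:
        return np.zeros((n, 0), dtype=np.int8)
    as_u8 = sim.bits.view(np.uint8)  # little-endian words
    unpacked = np.unpackbits(as_u8, axis=1, bitorder="little")[:, :n]
    return np.ascontiguousarray(unpacked.T).astype(np.int8)  # (n, S)


def ms_block(sim: SimulatedLocus) -> str:
    """One ms-style replicate block (``//``, segsites, positions, 0/1
    haplotype rows)."""
    lines = ["//", f"segsites: {sim.n_sites}"]
    if sim.n_sites:
        lines.append("positions: " +
                     " ".join(f"{p:.5f}" for p in sim.positions))
        H = haplotype_matrix(sim)
        for row in H:
            lines.append("".join("1" if v else "0" for v in row))
    return "\n".join(lines) + "\n"
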