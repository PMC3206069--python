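"""Synthetic study generator: FASTA panels with known truth.

Produces desk-scale datasets shaped like a two-species resequencing
study: 29 unlinked coding loci, 31 + 48 diploid individuals (62 + 96
haplotypes), an outgroup sequence calibrated to 5 MY of divergence at two
years per generation, and per-locus synonymous masks.  Variation is
generated by the coalescent simulator under a chosen true model, planted
onto codon-structured reference sequences at four-fold degenerate third
positions (so the synonymous mask is honest), and written as plain FASTA
+ mask + manifest files, alongside a truth record sufficient to rerun any
experiment bit-identically.

The outgroup is realized as a single sequence (as when a reference genome
of a sister taxon is used): it carries the mutations of the lineage
joining the ingroup root to the calibrated outgroup split, and its own
polymorphism is not modeled.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import coalescent, popgen
from .alignments import LocusAlignment, write_locus_fasta, write_mask
from .demography import LocusSpec, ParameterVector, compile_epochs

__all__ = ["StudyTemplate", "StudyData", "generate_study",
           "worked_example_fixture"]

# codon prefixes whose third position is four-fold degenerate
_FOURFOLD_PREFIX = ["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"]
_BASES = "ACGT"


@dataclasses.dataclass
class StudyTemplate:
    """Study layout and ground truth for the synthetic generator.

    Defaults emulate the two-species panel the pipeline is designed for:
    29 loci of 402-1398 coding sites, 62 + 96 haploid sequences, a
    strict-isolation constant-size truth, and per-locus mutation rates
    log-normally scattered around 7e-9 per site per generation (the value
    implied by calibrating ~3.5% net synonymous outgroup divergence
    against a 5 MY split at 2 years/generation).
    """

    n_loci: int = 29
    L_coding_range: tuple[int, int] = (402, 1398)
    n_A: int = 62
    n_B: int = 96
    base_mu: float = 7e-9
    mu_log_sd: float = 0.2
    T_out_years: float = 5e6
    gen_years: float = 2.0
    rho_over_theta: float = 1.0
    true_params: ParameterVector = dataclasses.field(
        default_factory=lambda: ParameterVector(
            model="SIC", N_hal=82_000.0, N_lyr=79_200.0, N_anc=532_900.0,
            T_split=337_400.0))
    seed: int = 0

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclasses.dataclass
class StudyData:
    """Everything `generate_study` wrote, plus the in-memory truth."""

    root: Path
    manifest: Path
    truth: dict
    loci: list[LocusSpec]
    per_locus: np.ndarray       # (n_loci, 14) simulator-side statistics
    alignments: list[LocusAlignment]

    def summary_vector(self) -> np.ndarray:
        values, _ = popgen.summarize_matrix(self.per_locus[:, :12])
        return values


def _random_coding_reference(L_coding: int, rng: np.random.Generator) -> str:
    """Codon-structured reference whose every third position is four-fold
    degenerate."""
    n_codons = L_coding // 3
    prefixes = rng.choice(_FOURFOLD_PREFIX, size=n_codons)
    thirds = rng.choice(list(_BASES), size=n_codons)
    return "".join(p + t for p, t in zip(prefixes, thirds))


def _mutate(seq: list[str], pos_coding: int, base: str) -> None:
    seq[pos_coding] = base


def generate_study(template: StudyTemplate, out_dir: str | Path,
                   ) -> StudyData:
    """Write a complete synthetic study to ``out_dir``.

    Per locus: simulate haplotypes under the true model, relabel the
    segregating records onto distinct synonymous (third codon) positions,
    derive the outgroup by planting additional private mutations whose
    expected number matches the calibrated outgroup branch length
    (2*T_out - t_root generations at the locus mutation rate), and write
    FASTA + mask.  Loci whose simulated site count exceeds the number of
    synonymous positions are resampled with a fresh seed (diagnostic kept
    in the truth record).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(template.seed)
    p = template.true_params
    p.gen_years = template.gen_years
    epochs = compile_epochs(p)
    N_ref = epochs.N_ref
    T_out_gen = template.T_out_years / template.gen_years
    ws = coalescent.Workspace(template.n_A + template.n_B)

    specs: list[LocusSpec] = []
    alignments: list[LocusAlignment] = []
    per_locus = np.empty((template.n_loci, 14))
    truth_loci = []
    manifest_rows = ["locus_id\tfasta\tmask"]

    for j in range(template.n_loci):
        L_coding = int(rng.integers(template.L_coding_range[0] // 3,
                                    template.L_coding_range[1] // 3 + 1)) * 3
        L_syn = L_coding // 3
        mu = template.base_mu * float(
            rng.lognormal(-0.5 * template.mu_log_sd ** 2, template.mu_log_sd))
        spec = LocusSpec(f"locus{j:02d}", template.n_A, template.n_B,
                         L_syn, mu, template.rho_over_theta)
        resamples = 0
        while True:
            sim_seed = int(rng.integers(2 ** 31))
            sim = coalescent.simulate_locus(epochs, spec, sim_seed, ws)
            if sim.n_sites <= L_syn:
                break
            resamples += 1
            if resamples > 50:
                raise RuntimeError(
                    f"{spec.locus_id}: cannot host {sim.n_sites} sites in "
                    f"{L_syn} synonymous positions")
        per_locus[j] = coalescent.locus_stats_vector(sim)

        ref = _random_coding_reference(L_coding, rng)
        syn_cols = np.arange(2, L_coding, 3)      # third codon positions
        chosen = rng.choice(L_syn, size=sim.n_sites, replace=False)
        H = coalescent.haplotype_matrix(sim)      # (n, S)

        seqs = [list(ref) for _ in range(template.n_A + template.n_B)]
        outg = list(ref)
        for s in range(sim.n_sites):
            col = int(syn_cols[chosen[s]])
            anc = ref[col]
            derived = rng.choice([b for b in _BASES if b != anc])
            for hap in np.nonzero(H[:, s])[0]:
                _mutate(seqs[hap], col, derived)

        # Outgroup branch: mutations private to the outgroup lineage.
        # The expected count combines (i) the calibrated species path,
        # 2*T_out generations minus the part already inside the ingroup
        # genealogy, and (ii) an ancestral-polymorphism component equal to
        # the panel's mean within-species diversity -- the quantity the
        # Nei net-divergence correction later removes, so that the
        # realized *net* outgroup divergence is consistent with the 5 MY
        # calibration by construction.
        t_root_gen = _mean_root_time(sim) * 4.0 * N_ref
        branch_gen = max(2.0 * T_out_gen - t_root_gen, 0.0)
        pi_bar = 0.5 * (per_locus[j, 0] + per_locus[j, 1])  # per site
        n_out = rng.poisson(mu * L_syn * branch_gen + L_syn * pi_bar)
        free_cols = np.setdiff1d(np.arange(L_syn), chosen)
        n_out = min(n_out, len(free_cols))
        out_cols = rng.choice(free_cols, size=n_out, replace=False)
        for c in out_cols:
            col = int(syn_cols[c])
            anc = ref[col]
            _mutate(outg, col, rng.choice([b for b in _BASES if b != anc]))

        mask = np.zeros(L_coding, dtype=bool)
        mask[syn_cols] = True
        aln = LocusAlignment(spec.locus_id,
                             ["".join(s) for s in seqs[:template.n_A]],
                             ["".join(s) for s in seqs[template.n_A:]],
                             "".join(outg), mask)
        alignments.append(aln)
        specs.append(spec)

        fasta = out_dir / f"{spec.locus_id}.fasta"
        maskf = out_dir / f"{spec.locus_id}.mask.tsv"
        write_locus_fasta(fasta, aln, species=("hal", "lyr"))
        write_mask(maskf, mask)
        manifest_rows.append(f"{spec.locus_id}\t{fasta.name}\t{maskf.name}")
        truth_loci.append({
            "locus_id": spec.locus_id, "L_coding": L_coding, "L_syn": L_syn,
            "mu": mu, "sim_seed": sim_seed, "n_sites": int(sim.n_sites),
            "t_root_gen": t_root_gen, "n_outgroup_mut": int(n_out),
            "resamples": resamples})

    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(manifest_rows) + "\n")
    truth = {"template": template.to_json(),
             "model": p.model,
             "params": dataclasses.asdict(p),
             "N_ref": N_ref,
             "loci": truth_loci}
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return StudyData(out_dir, manifest, truth, specs, per_locus, alignments)


def _mean_root_time(sim: coalescent.SimulatedLocus) -> float:
    """Length-weighted mean marginal-MRCA time (coalescent units)."""
    if len(sim.mrca) == 0:
        return 0.0
    span = sim.mrca[:, 1] - sim.mrca[:, 0]
    return float((sim.mrca[:, 2] * span).sum() / span.sum())


# ---------------------------------------------------------------------------
# worked example


_L1_SITES = {  # 1-based masked positions -> (A alleles, B alleles, outgroup)
    3: ("AATT", "AAAA", "A"),
    6: ("CCCG", "CGGG", "C"),
    9: ("GGGG", "TTTT", "T"),
    12: ("TTTT", "TTTT", "C"),
    15: ("AAAC", "AAGG", "A"),
    18: ("AAAA", "AAAT", "N"),
}
_L2_SITES = {
    1: ("GGGT", "TTTT", "G"),
    2: ("AAAA", "AACC", "A"),
    3: ("CCCC", "AAAA", "C"),
    4: ("GGGG", "GGGT", "T"),
    5: ("AAAA", "AAAA", "A"),
    6: ("AAAA", "AAAA", "A"),
}

#: Hand-derived expectations for the worked example (exact fractions).
WORKED_EXPECTED = {
    "locus1": {
        "L_use": 5, "pi_A": 7 / 30, "pi_B": 1 / 5,
        "thetaW_A": 12 / 55, "thetaW_B": 12 / 55,
        "fst": 62 / 153, "K_AB": 19 / 40,
        "K_out": 9 / 16, "net_K_out": 83 / 240,
        "classes": {"sx_A": 1, "sx_B": 0, "sf_A": 1, "sf_B": 0,
                    "ss": 1, "sxA_fB": 0, "sxB_fA": 0},
        "skipped": {"multiallelic": 1, "outgroup_missing": 1,
                    "fixed_both": 1},
        "joint_sfs_cells": {(2, 0): 1, (1, 3): 1, (4, 0): 1},
    },
    "locus2": {
        "L_use": 6, "pi_A": 1 / 12, "pi_B": 7 / 36,
        "thetaW_A": 1 / 11, "thetaW_B": 2 / 11,
        "fst": 8 / 15, "K_AB": 5 / 12,
        "K_out": 3 / 8, "net_K_out": 17 / 72,
        "classes": {"sx_A": 0, "sx_B": 1, "sf_A": 0, "sf_B": 1,
                    "ss": 0, "sxA_fB": 1, "sxB_fA": 1},
        "skipped": {},
        "joint_sfs_cells": {(1, 4): 1, (0, 2): 1, (0, 4): 1, (4, 3): 1},
    },
}


def _build_from_sites(L: int, sites: dict, masked_only: bool):
    seqs_A = [["A"] * L for _ in range(4)]
    seqs_B = [["A"] * L for _ in range(4)]
    outg = ["A"] * L
    for pos, (a, b, o) in sites.items():
        for i in range(4):
            seqs_A[i][pos - 1] = a[i]
            seqs_B[i][pos - 1] = b[i]
        outg[pos - 1] = o
    mask = np.zeros(L, dtype=bool)
    if masked_only:
        mask[list(np.array(sorted(sites)) - 1)] = True
    else:
        mask[:] = True
    return (["".join(s) for s in seqs_A], ["".join(s) for s in seqs_B],
            "".join(outg), mask)


_WORKED_README = """\
Worked two-locus example
========================

Two hand-written loci, 4 + 4 haplotypes each, one outgroup sequence.
Every statistic below can be re-derived with pencil and paper.

locus1 (L = 18, synonymous mask on positions 3, 6, 9, 12, 15, 18)
-----------------------------------------------------------------
Masked site patterns (species A / species B / outgroup):
  pos  3  AATT / AAAA / A  -> exclusive polymorphism in A (Sx_A), dA=2
  pos  6  CCCG / CGGG / C  -> shared polymorphism (Ss), dA=1, dB=3
  pos  9  GGGG / TTTT / T  -> fixed difference, derived in A (Sf_A)
  pos 12  TTTT / TTTT / C  -> derived allele fixed in BOTH: excluded
  pos 15  AAAC / AAGG / A  -> three alleles in the ingroup: site dropped
  pos 18  AAAA / AAAT / N  -> outgroup missing: unpolarizable (still
                              usable for diversity)
Usable sites: 5 (all but pos 15).
  pi_A  = (2*2*2/12 + 2*1*3/12)/5            = 7/30
  pi_B  = (2*1*3/12 + 2*1*3/12)/5            = 1/5
  thetaW (both) = 2 / (1+1/2+1/3) / 5        = 12/55
  pi_T  = (3/7 + 4/7 + 4/7 + 1/4)/5          = 51/140
  FST   = 1 - ((7/30+1/5)/2) / (51/140)      = 62/153
  K_AB  = (8 + 10 + 16 + 0 + 4)/16 / 5       = 19/40
  K_out = (2 + 4 + 4 + 8) / 8 / 4            = 9/16   (4 callable sites)
  net_K_out = 9/16 - (7/30+1/5)/2            = 83/240

locus2 (L = 6, every position analyzed, no mask file)
-----------------------------------------------------
  pos 1  GGGT / TTTT / G  -> derived T fixed in B, 1/4 in A (SxA_fB)
  pos 2  AAAA / AACC / A  -> exclusive polymorphism in B (Sx_B)
  pos 3  CCCC / AAAA / C  -> fixed difference, derived in B (Sf_B)
  pos 4  GGGG / GGGT / T  -> derived G fixed in A, 3/4 in B (SxB_fA)
  pos 5, 6                -> invariant
  pi_A = 1/12, pi_B = 7/36, thetaW_A = 1/11, thetaW_B = 2/11
  FST = 8/15, K_AB = 5/12, K_out = 3/8, net_K_out = 17/72
"""


def worked_example_fixture(out_dir: str | Path) -> Path:
    """Write the tiny hand-derived two-locus dataset; returns the manifest
    path.  Expected statistics live in ``WORKED_EXPECTED``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a1, b1, o1, m1 = _build_from_sites(18, _L1_SITES, masked_only=True)
    a2, b2, o2, m2 = _build_from_sites(6, _L2_SITES, masked_only=False)
    aln1 = LocusAlignment("locus1", a1, b1, o1, m1)
    aln2 = LocusAlignment("locus2", a2, b2, o2, m2)
    write_locus_fasta(out_dir / "locus1.fasta", aln1, species=("hal", "lyr"))
    write_locus_fasta(out_dir / "locus2.fasta", aln2, species=("hal", "lyr"))
    write_mask(out_dir / "locus1.mask.tsv", m1)
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("locus_id\tfasta\tmask\n"
                        "locus1\tlocus1.fasta\tlocus1.mask.tsv\n"
                        "locus2\tlocus2.fasta\t\n")
    (out_dir / "README.txt").write_text(_WORKED_README)
    return manifest
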