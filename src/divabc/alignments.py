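"""Per-locus alignment container and file I/O.

A locus is a multiple sequence alignment of haploid sequences from two
ingroup species plus a single outgroup sequence, together with a boolean
mask selecting the synonymous positions that enter every downstream
statistic.  Sequence records follow the ``species|individual|haplotype``
naming convention; the outgroup record is prefixed ``OUT|``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTN-")

# byte codes used internally: A,C,G,T -> 0..3, N/- -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
MISSING = np.uint8(4)


def encode(seqs: list[str]) -> np.ndarray:
    """Encode sequences as a (n, L) uint8 matrix (A,C,G,T -> 0..3, else 4)."""
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(len(seqs), -1)


def decode(mat: np.ndarray) -> list[str]:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return ["".join(map(chr, lut[row])) for row in np.asarray(mat, dtype=np.uint8)]


@dataclasses.dataclass
class LocusAlignment:
    """One locus: species-A haplotypes, species-B haplotypes, one outgroup.

    Parameters
    ----------
    locus_id:
        Free-text locus label.
    seqs_A, seqs_B:
        Haploid sequences (aligned, equal length) for the two ingroup
        species.  At least two haplotypes per species.
    outgroup:
        Single aligned outgroup sequence used for polarization.
    syn_mask:
        Boolean array of length L; True marks an analyzed synonymous site.
        ``None`` means every position is analyzed.
    """

    locus_id: str
    seqs_A: list[str]
    seqs_B: list[str]
    outgroup: str
    syn_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        L = len(self.outgroup)
        if any(len(s) != L for s in self.seqs_A + self.seqs_B):
            raise ValueError(f"{self.locus_id}: sequences differ in length")
        if L < 1:
            raise ValueError(f"{self.locus_id}: empty alignment")
        if len(self.seqs_A) < 2 or len(self.seqs_B) < 2:
            raise ValueError(f"{self.locus_id}: need >=2 haplotypes per species")
        bad = set("".join(self.seqs_A) + "".join(self.seqs_B) + self.outgroup) - VALID_CHARS
        if bad:
            raise ValueError(f"{self.locus_id}: invalid characters {sorted(bad)}")
        if self.syn_mask is None:
            self.syn_mask = np.ones(L, dtype=bool)
        else:
            self.syn_mask = np.asarray(self.syn_mask, dtype=bool)
            if self.syn_mask.shape != (L,):
                raise ValueError(f"{self.locus_id}: mask length != alignment length")

    @property
    def L(self) -> int:
        return len(self.outgroup)

    @property
    def n_A(self) -> int:
        return len(self.seqs_A)

    @property
    def n_B(self) -> int:
        return len(self.seqs_B)

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Encoded (A, B, outgroup) arrays; outgroup is 1-D of length L."""
        return encode(self.seqs_A), encode(self.seqs_B), encode([self.outgroup])[0]


def read_locus_fasta(path: str | Path, locus_id: str | None = None,
                     syn_mask: np.ndarray | None = None) -> LocusAlignment:
    """Read one locus FASTA; records named ``species|individual|haplotype``.

    The two ingroup species are the first two distinct species labels in
    file order; the record whose ID starts with ``OUT`` is the outgroup.
    """
    path = Path(path)
    seqs_by_sp: dict[str, list[str]] = {}
    outgroup = None
    for rec in SeqIO.parse(str(path), "fasta"):
        sp = rec.id.split("|", 1)[0]
        if sp.upper() == "OUT":
            if outgroup is not None:
                raise ValueError(f"{path}: multiple outgroup records")
            outgroup = str(rec.seq).upper()
        else:
            seqs_by_sp.setdefault(sp, []).append(str(rec.seq).upper())
    if outgroup is None:
        raise ValueError(f"{path}: no OUT| outgroup record")
    if len(seqs_by_sp) != 2:
        raise ValueError(f"{path}: expected exactly 2 ingroup species, "
                         f"found {sorted(seqs_by_sp)}")
    sp_a, sp_b = list(seqs_by_sp)
    return LocusAlignment(locus_id or path.stem, seqs_by_sp[sp_a],
                          seqs_by_sp[sp_b], outgroup, syn_mask)


def write_locus_fasta(path: str | Path, aln: LocusAlignment,
                      species: tuple[str, str] = ("A", "B")) -> None:
    recs = []
    for sp, seqs in zip(species, (aln.seqs_A, aln.seqs_B)):
        for i, s in enumerate(seqs):
            recs.append(SeqRecord(Seq(s), id=f"{sp}|ind{i // 2}|h{i % 2}",
                                  description=""))
    recs.append(SeqRecord(Seq(aln.outgroup), id="OUT|ref|h0", description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_mask(path: str | Path, L: int) -> np.ndarray:
    """Two-column TSV (1-based position, 0/1 flag) -> boolean mask."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["pos", "flag"])
    mask = np.zeros(L, dtype=bool)
    pos = df["pos"].to_numpy(int)
    if (pos < 1).any() or (pos > L).any():
        raise ValueError(f"{path}: mask positions outside 1..{L}")
    mask[pos - 1] = df["flag"].to_numpy(int).astype(bool)
    return mask


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i, flag in enumerate(np.asarray(mask, dtype=int), start=1):
            fh.write(f"{i}\t{flag}\n")


def read_manifest(path: str | Path) -> list[LocusAlignment]:
    """Dataset manifest: TSV with columns locus_id, fasta, mask (mask may
    be empty).  Relative paths are resolved against the manifest location."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("locus_id", "fasta"):
        if col not in df.columns:
            raise ValueError(f"{path}: manifest lacks column '{col}'")
    loci = []
    for row in df.itertuples(index=False):
        fasta = path.parent / str(row.fasta)
        aln = read_locus_fasta(fasta, locus_id=str(row.locus_id))
        mask_field = getattr(row, "mask", None)
        if mask_field and not pd.isna(mask_field):
            aln.syn_mask = read_mask(path.parent / str(mask_field), aln.L)
        loci.append(aln)
    if not loci:
        raise ValueError(f"{path}: empty manifest")
    return loci
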