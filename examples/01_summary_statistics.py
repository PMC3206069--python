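"""Per-locus summary statistics on a tiny hand-checkable dataset.

Writes the two-locus worked example to a temporary directory, reads it
back through the FASTA/manifest interface, and prints every per-locus
statistic.  The values are exactly derivable by hand (see the README.txt
written next to the FASTA files).
"""

import tempfile
from pathlib import Path

from divabc import popgen, read_manifest, worked_example_fixture

with tempfile.TemporaryDirectory() as td:
    manifest = worked_example_fixture(Path(td))
    loci = read_manifest(manifest)
    results = [popgen.compute_locus_stats(a) for a in loci]

    for aln, (st, tab) in zip(loci, results):
        print(f"{aln.locus_id}: {aln.n_A}+{aln.n_B} haplotypes, "
              f"{st.L_use} usable synonymous sites")
        print(f"  pi          A={st.pi_A:.4f}  B={st.pi_B:.4f}   "
              "(mean pairwise diversity per site)")
        print(f"  theta_W     A={st.thetaW_A:.4f}  B={st.thetaW_B:.4f}")
        print(f"  Tajima's D  A={st.D_A:.3f}  B={st.D_B:.3f}")
        print(f"  F_ST = 1 - pi_s/pi_T = {st.fst:.4f}")
        print(f"  divergence  K_AB={st.K_AB:.4f}  K_out={st.K_out:.4f} "
              f" net={st.net_K_out:.4f}")
        print(f"  site classes: {tab.as_dict()}  (skipped: "
              f"{ {k: v for k, v in tab.skipped.items() if v} })")

    summ = popgen.summarize_dataset(results)
    print("\n22-statistic dataset summary (ABC input):")
    for name, value in zip(summ.names, summ.values):
        print(f"  {name:>14s} = {value: .5f}")
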