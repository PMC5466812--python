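"""Community phylogenetic structure of every sample x fraction.

Checks the null-model precondition (no phylogenetic signal in OTU
abundance), then computes SES of MPD and MNTD for the 38 communities
under the tip-shuffle null with 999 permutations. Negative SES with
p < 0.05 marks phylogenetic clustering. Writes results/structure.tsv.
"""

from pathlib import Path

from mycophylo import phylo
from mycophylo.structure import abundance_signal_check, structure_table
from mycophylo.tables import read_paired_table

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 14
N_PERM = 999


def main() -> None:
    table = read_paired_table(BASE / "data" / "counts.tsv")
    tree = phylo.read_newick(str(BASE / "data" / "tree.nwk"))
    check = abundance_signal_check(table, tree, n_permutations=N_PERM, seed=SEED)
    verdict = "WARNING: null model may inflate type-I error" if check["warn"] else "ok"
    print(f"abundance-signal precondition: K = {check['k']:.3f}, "
          f"p = {check['p_value']:.3f} ({verdict})")

    res = structure_table(table, tree, n_permutations=N_PERM, seed=SEED)
    res.to_csv(BASE / "structure.tsv", sep="\t", index=False)
    for metric in ("MPD", "MNTD"):
        sub = res[res["metric"] == metric]
        n_sig_neg = ((sub["ses"] < 0) & sub["significant"]).sum()
        print(f"SES_{metric}: mean {sub['ses'].mean():+.2f}; "
              f"{n_sig_neg}/{len(sub)} communities significantly clustered (p < 0.05)")
    print(f"wrote structure.tsv ({len(res)} rows, {N_PERM} permutations each)")


if __name__ == "__main__":
    main()
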