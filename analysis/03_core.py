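"""Core microbiome: OTUs shared by all plants, and the sampling-effort curve.

Uses the full (unrarefied) table: presence/absence of rare OTUs is the
whole point of the core, and subsampling would delete it. Writes
results/core/.
"""

from pathlib import Path

import pandas as pd

from mycophylo.coremicro import core_resampling_curve, core_sequence_fraction, shared_otus
from mycophylo.tables import read_paired_table

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "core"
SEED = 12
N_RESAMPLES = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_paired_table(BASE / "data" / "counts.tsv")
    frames = []
    for mode in ("DNA", "RNA", "both"):
        core = shared_otus(table, mode=mode)
        curve = core_resampling_curve(table, mode=mode,
                                      n_resamples=N_RESAMPLES, seed=SEED)
        frame = curve.to_frame()
        frame.insert(0, "mode", mode)
        frames.append(frame)
        line = f"  {mode} core across all {len(table.samples)} samples: {len(core)} OTUs"
        if core:
            stats = core_sequence_fraction(table, core)
            line += (f" ({100 * stats['fraction_of_total']:.1f}% of all reads; "
                     f"DNA share {100 * stats['core_dna_share']:.0f}%, "
                     f"RNA share {100 * stats['core_rna_share']:.0f}%)")
        print(line)
    pd.concat(frames).to_csv(OUT / "core_curve.tsv", sep="\t", index=False)
    print(f"wrote core_curve.tsv ({N_RESAMPLES} resamples per sampling size) to {OUT}")


if __name__ == "__main__":
    main()
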