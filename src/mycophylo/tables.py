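"""Paired DNA/RNA OTU tables: container, TSV I/O, replicate filter, rarefaction.

The central observation object is a counts matrix indexed by OTU with one
column per (sample, fraction) pair, where the fraction records the
nucleic-acid source of the amplicon library: DNA (community presence) or
RNA/cDNA (the metabolically active community). Columns are a pandas
MultiIndex ``(sample, fraction)``.

On disk the table is a TSV whose first column is ``otu_id`` and whose
remaining headers are ``<sample>_<DNA|RNA>`` (case-insensitive on read,
upper-case on write), optionally suffixed ``_rep<k>`` for technical
replicates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

FRACTIONS = ("DNA", "RNA")

__all__ = [
    "FRACTIONS",
    "PairedOtuTable",
    "read_paired_table",
    "write_paired_table",
    "replicate_consensus_filter",
    "read_sequence_multiset",
    "rarefy",
    "relative_abundance",
]


@dataclass(frozen=True)
class PairedOtuTable:
    """Non-negative integer counts per OTU x (sample, fraction).

    ``counts`` has a unique ``otu_id`` index and MultiIndex columns
    ``(sample, fraction)`` with both fractions present for every sample.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = sorted(c.index[c.index.duplicated()].unique())
            raise ValueError(f"duplicated otu_id: {dupes}")
        if (c.to_numpy() < 0).any():
            raise ValueError("negative counts")
        bad = [f for _, f in c.columns if f not in FRACTIONS]
        if bad:
            raise ValueError(f"unknown fraction labels: {sorted(set(bad))}")
        for s in self.samples:
            have = {f for smp, f in c.columns if smp == s}
            if have != set(FRACTIONS):
                raise ValueError(f"sample {s!r} missing fraction(s) {set(FRACTIONS) - have}")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(s for s, _ in self.counts.columns))

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def fraction(self, fraction: str) -> pd.DataFrame:
        """Counts of one fraction, columns indexed by sample."""
        return self.counts.xs(fraction, axis=1, level=1)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_empty_otus(self) -> "PairedOtuTable":
        keep = self.counts.sum(axis=1) > 0
        return PairedOtuTable(self.counts.loc[keep])


def _parse_column(name: str) -> tuple[str, str]:
    sample, _, frac = name.rpartition("_")
    if not sample or frac.upper() not in FRACTIONS:
        raise ValueError(
            f"column {name!r} does not match '<sample>_<DNA|RNA>'"
        )
    return sample, frac.upper()


def read_paired_table(path: str) -> PairedOtuTable:
    """Read a paired OTU count table from TSV.

    Rejects (rather than coerces) negative or non-integer counts,
    duplicated OTU ids, and unrecognised fraction suffixes.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        dupes = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicated otu_id in {path}: {dupes}")
    cols = [_parse_column(c) for c in raw.columns]
    for j, col in enumerate(raw.columns):
        vals = raw[col]
        if not np.allclose(vals, np.round(vals)):
            i = vals.index[~np.isclose(vals, np.round(vals))][0]
            raise ValueError(f"non-integer count at row {i!r}, column {col!r}")
        if (vals < 0).any():
            i = vals.index[vals < 0][0]
            raise ValueError(f"negative count at row {i!r}, column {col!r}")
    out = raw.astype(np.int64)
    out.columns = pd.MultiIndex.from_tuples(cols, names=["sample", "fraction"])
    out.index.name = "otu_id"
    return PairedOtuTable(out)


def write_paired_table(table: PairedOtuTable, path: str) -> None:
    flat = table.counts.copy()
    flat.columns = [f"{s}_{f}" for s, f in flat.columns]
    flat.index.name = "otu_id"
    flat.to_csv(path, sep="\t")


def replicate_consensus_filter(replicates: list[Counter]) -> Counter:
    """Keep only sequences observed in every technical replicate.

    Each replicate is a multiset (Counter) of exact sequence strings; a
    sequence is retained only if it occurs in all replicates, with
    retained multiplicity equal to its summed count across replicates.
    The order of replicates is immaterial.
    """
    if len(replicates) < 2:
        raise ValueError("replicate consensus requires >= 2 replicates")
    shared = set(replicates[0])
    for rep in replicates[1:]:
        shared &= set(rep)
    out: Counter = Counter()
    for seq in shared:
        out[seq] = sum(rep[seq] for rep in replicates)
    return out


def read_sequence_multiset(path: str) -> Counter:
    """Read one technical replicate's sequences from FASTA as a multiset.

    Identical strings collapse into one Counter entry, which is the
    representation :func:`replicate_consensus_filter` consumes.
    """
    import skbio

    out: Counter = Counter()
    for seq in skbio.io.read(str(path), format="fasta"):
        out[str(seq)] += 1
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def rarefy(table: PairedOtuTable, depth: int, seed: int) -> PairedOtuTable:
    """Subsample every (sample, fraction) column to exactly ``depth`` reads.

    Sampling is without replacement (multivariate hypergeometric), a
    single draw per column. Columns whose total is below ``depth`` are an
    error listing every deficient column, so the caller can decide to
    drop samples or lower the depth.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.column_totals()
    deficient = [f"{s}_{f}" for (s, f), t in totals.items() if t < depth]
    if deficient:
        raise ValueError(
            f"columns below rarefaction depth {depth}: {deficient}"
        )
    rng = np.random.default_rng(seed)
    out = table.counts.copy()
    for col in out.columns:
        colvals = out[col].to_numpy()
        if colvals.sum() == depth:
            continue
        out[col] = rng.multivariate_hypergeometric(colvals, depth)
    return PairedOtuTable(out)


def relative_abundance(table: PairedOtuTable) -> pd.DataFrame:
    """Per-column proportions; every column sums to 1.

    All-zero columns are an error (no composition is defined for them).
    """
    totals = table.column_totals()
    zero = [f"{s}_{f}" for (s, f), t in totals.items() if t == 0]
    if zero:
        raise ValueError(f"all-zero columns: {zero}")
    return table.counts / totals
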