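"""Core microbiome: OTUs shared across hosts, and the sampling-effort curve.

The "DNA core" / "RNA core" is the set of OTUs present (count >= 1) in
that fraction of every sampled plant; the "both" core requires presence
in both fractions of every plant. The resampling curve measures how the
core shrinks as more hosts are sampled, by drawing random sample subsets
of increasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import PairedOtuTable

__all__ = ["CoreCurve", "shared_otus", "core_resampling_curve", "core_sequence_fraction"]


@dataclass(frozen=True)
class CoreCurve:
    """Mean and sd of core size per sampling size k = 1..n_samples."""

    sampling_size: np.ndarray
    mean_core_size: np.ndarray
    sd_core_size: np.ndarray
    n_resamples: int
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sampling_size": self.sampling_size,
                "mean_core_size": self.mean_core_size,
                "sd_core_size": self.sd_core_size,
            }
        )


def _presence(table: PairedOtuTable, mode: str) -> pd.DataFrame:
    """Boolean OTU x sample matrix of membership under the given mode."""
    if mode == "both":
        return (table.fraction("DNA") > 0) & (table.fraction("RNA") > 0)
    if mode in ("DNA", "RNA"):
        return table.fraction(mode) > 0
    raise ValueError(f"mode must be DNA, RNA or both, got {mode!r}")


def shared_otus(table: PairedOtuTable, samples=None, mode: str = "both") -> set[str]:
    """OTUs present in the given fraction(s) of every listed sample.

    ``samples=None`` means all samples. ``mode='both'`` requires
    positivity in both the DNA and RNA fraction of each sample.
    """
    if samples is None:
        samples = table.samples
    samples = list(samples)
    if not samples:
        raise ValueError("samples must be non-empty")
    unknown = [s for s in samples if s not in table.samples]
    if unknown:
        raise KeyError(f"unknown sample id(s): {unknown}")
    pres = _presence(table, mode)[samples]
    return set(pres.index[pres.all(axis=1)])


def core_resampling_curve(
    table: PairedOtuTable,
    mode: str = "both",
    n_resamples: int = 1000,
    seed: int = 0,
) -> CoreCurve:
    """Core size as a function of the number of hosts sampled.

    For each k in 1..n_samples, draws ``n_resamples`` uniform k-subsets
    of samples (without replacement within a draw) and records the mean
    and sd of the shared-OTU count. At k = n_samples the subset is the
    full panel and the sd is zero.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    pres = _presence(table, mode).to_numpy()
    samples = table.samples
    n = len(samples)
    means, sds = np.empty(n), np.empty(n)
    for k in range(1, n + 1):
        if k == n:
            sizes = np.array([pres.all(axis=1).sum()], dtype=float)
        else:
            sizes = np.empty(n_resamples)
            for r in range(n_resamples):
                cols = rng.choice(n, size=k, replace=False)
                sizes[r] = pres[:, cols].all(axis=1).sum()
        means[k - 1] = sizes.mean()
        sds[k - 1] = sizes.std(ddof=0) if sizes.size > 1 else 0.0
    return CoreCurve(np.arange(1, n + 1), means, sds, n_resamples, mode)


def core_sequence_fraction(table: PairedOtuTable, core: set[str]) -> dict:
    """Share of all sequences carried by the core, and its DNA/RNA split.

    Returns the core's proportion of total counts plus the proportions
    of the core's own counts that fall in each fraction.
    """
    unknown = core - set(table.otu_ids)
    if unknown:
        raise KeyError(f"core contains unknown OTUs: {sorted(unknown)}")
    total = table.counts.to_numpy().sum()
    if total == 0:
        raise ValueError("empty table")
    core_rows = table.counts.loc[sorted(core)] if core else table.counts.iloc[:0]
    core_total = core_rows.to_numpy().sum()
    out = {"fraction_of_total": core_total / total}
    if core_total > 0:
        by_frac = core_rows.T.groupby(level="fraction").sum().sum(axis=1)
        out["core_dna_share"] = float(by_frac.get("DNA", 0) / core_total)
        out["core_rna_share"] = float(by_frac.get("RNA", 0) / core_total)
    else:
        out["core_dna_share"] = out["core_rna_share"] = float("nan")
    return out
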