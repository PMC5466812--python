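"""The mean expression ratio: a per-OTU RNA:DNA activity trait.

For each OTU the trait is

    mean expression ratio = mean RA_RNA / (mean RA_RNA + mean RA_DNA)

where RA is the relative abundance of the OTU within a sample's
fraction and the means run over exactly the n samples in which the OTU
is present in the DNA and/or the RNA fraction (zeros in the missing
fraction count for those samples; samples where the OTU is absent from
both contribute nothing, not even to n). The ratio lies in [0, 1]:
0 means never detected in RNA, 1 never detected in DNA, 0.5 equal mean
relative abundance in both fractions. It proxies relative
transcriptional activity but is not a direct growth measurement.

Two standard errors are available: the default treats the per-sample
ratios r_i = RA_RNA,i / (RA_RNA,i + RA_DNA,i) as n observations and
reports their SEM; the alternative propagates the SEs of the two means
through the ratio by the delta method. OTUs supported by a single
sample have no defined SE and are substituted (default: the median SE
of the n >= 2 OTUs) so that downstream signal statistics that require
finite SEs stay computable; every substitution is flagged in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import PairedOtuTable, relative_abundance

__all__ = ["mean_expression_ratio", "ratio_standard_error"]


def _support(table: PairedOtuTable) -> pd.DataFrame:
    """Boolean OTU x sample matrix: present in DNA and/or RNA."""
    return (table.fraction("DNA") > 0) | (table.fraction("RNA") > 0)


def mean_expression_ratio(
    table: PairedOtuTable,
    se_method: str = "per_sample_ratio",
    n1_se_policy: str = "median",
) -> pd.DataFrame:
    """Per-OTU mean expression ratio, standard error and support count.

    Returns a DataFrame indexed by otu_id with columns ``value`` (the
    ratio), ``se``, ``n`` (supporting samples) and ``se_substituted``
    (True where an n = 1 SE was filled by policy). OTUs present in no
    sample are excluded from the output.

    ``se_method``: ``per_sample_ratio`` (SEM of the per-sample ratios)
    or ``delta`` (delta-method propagation from the two fraction means).
    ``n1_se_policy``: ``median`` substitutes the median SE of all
    n >= 2 OTUs for n = 1 OTUs; ``nan`` leaves them missing.
    """
    ra = relative_abundance(table)
    ra_dna = ra.xs("DNA", axis=1, level=1)
    ra_rna = ra.xs("RNA", axis=1, level=1)
    support = _support(table)
    n = support.sum(axis=1)
    present = n > 0

    sup = support.to_numpy()
    dna = ra_dna.to_numpy()
    rna = ra_rna.to_numpy()
    with np.errstate(invalid="ignore"):
        mean_dna = np.where(sup, dna, 0.0).sum(axis=1) / n.to_numpy()
        mean_rna = np.where(sup, rna, 0.0).sum(axis=1) / n.to_numpy()
        value = mean_rna / (mean_rna + mean_dna)

    if se_method == "per_sample_ratio":
        se = _per_sample_ratio_se(dna, rna, sup, n.to_numpy())
    elif se_method == "delta":
        se = _delta_se(dna, rna, sup, n.to_numpy(), mean_dna, mean_rna)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    out = pd.DataFrame(
        {"value": value, "se": se, "n": n},
        index=table.counts.index,
    ).loc[present]
    out["se_substituted"] = False

    single = out["n"] == 1
    if single.any():
        if n1_se_policy == "median":
            donor = out.loc[~single, "se"]
            fill = float(donor.median()) if len(donor) else 0.0
            out.loc[single, "se"] = fill
            out.loc[single, "se_substituted"] = True
        elif n1_se_policy == "nan":
            out.loc[single, "se"] = np.nan
            out.loc[single, "se_substituted"] = True
        else:
            raise ValueError(f"unknown n1_se_policy {n1_se_policy!r}")
    return out


def _per_sample_ratio_se(dna, rna, sup, n):
    """SEM of the per-sample ratios over the supporting samples."""
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = dna + rna
        r = np.where(sup & (denom > 0), rna / np.where(denom > 0, denom, 1.0), np.nan)
    se = np.full(len(n), np.nan)
    for i in range(len(n)):
        ri = r[i][sup[i]]
        if ri.size >= 2:
            se[i] = ri.std(ddof=1) / np.sqrt(ri.size)
        elif ri.size == 1:
            se[i] = np.nan  # flagged, substituted by policy
    return se


def _delta_se(dna, rna, sup, n, mean_dna, mean_rna):
    """Delta-method SE of R = mR/(mR+mD) from the SEs of the two means."""
    se = np.full(len(n), np.nan)
    tot = mean_dna + mean_rna
    for i in range(len(n)):
        if n[i] < 2:
            continue
        d = dna[i][sup[i]]
        r = rna[i][sup[i]]
        var_d = d.var(ddof=1) / n[i]
        var_r = r.var(ddof=1) / n[i]
        # dR/dmR = mD/tot^2, dR/dmD = -mR/tot^2 ; means independent-ish
        se[i] = np.sqrt(
            (mean_dna[i] ** 2 * var_r + mean_rna[i] ** 2 * var_d)
        ) / tot[i] ** 2
    return se


def ratio_standard_error(table: PairedOtuTable, otu_id: str) -> float:
    """SEM of the per-sample expression ratios for one OTU.

    NaN (flagged) when the OTU is supported by a single sample; the
    table-level routine substitutes per policy.
    """
    res = mean_expression_ratio(table, n1_se_policy="nan")
    if otu_id not in res.index:
        raise KeyError(f"OTU {otu_id!r} is present in no sample")
    return float(res.loc[otu_id, "se"])
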