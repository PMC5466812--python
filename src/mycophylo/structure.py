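"""Community phylogenetic structure: MPD, MNTD and standardized effect sizes.

MPD is the mean patristic distance over all unordered pairs of
co-occurring OTUs; MNTD the mean distance from each member to its
nearest co-occurring relative. Both are compared against a tip-shuffle
null: community membership, richness and abundances are held fixed
while tip labels are permuted across the phylogeny, which under a fixed
community is equivalent to drawing a uniformly random tip subset of the
same size. The standardized effect size

    SES = (observed - null mean) / null sd

is negative with a small lower-tail p when co-occurring OTUs are more
closely related than expected (phylogenetic clustering, the signature
of environmental filtering) and positive under overdispersion.

The fixed-abundance null is only calibrated when OTU abundance itself
carries no phylogenetic signal; :func:`abundance_signal_check` reports
Blomberg's K on per-OTU total abundance so the pipeline can warn.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import phylo
from .tables import FRACTIONS, PairedOtuTable

__all__ = ["SesResult", "mpd", "mntd", "ses", "structure_table", "abundance_signal_check"]

_METRICS = ("MPD", "MNTD")


@dataclass(frozen=True)
class SesResult:
    """One community's structure test (one Table-style cell)."""

    community_id: str
    metric: str
    n_otus: int
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_permutations: int
    degenerate: bool = False


def _submatrix(dist: pd.DataFrame, community) -> np.ndarray:
    members = list(community)
    missing = [m for m in members if m not in dist.index]
    if missing:
        raise KeyError(f"community members not in distance matrix: {missing}")
    return dist.loc[members, members].to_numpy()


def _mpd_from_array(d: np.ndarray, weights: np.ndarray | None = None) -> float:
    k = d.shape[0]
    iu = np.triu_indices(k, 1)
    if weights is None:
        return float(d[iu].mean())
    w = np.outer(weights, weights)[iu]
    return float(np.average(d[iu], weights=w))


def _mntd_from_array(d: np.ndarray, weights: np.ndarray | None = None) -> float:
    dd = d + np.diag(np.full(d.shape[0], np.inf))
    nearest = dd.min(axis=1)
    if weights is None:
        return float(nearest.mean())
    return float(np.average(nearest, weights=weights))


def mpd(community, dist: pd.DataFrame, weights: pd.Series | None = None) -> float:
    """Mean pairwise phylogenetic distance within a community.

    Unweighted by default; with ``weights`` (abundances) pairs are
    weighted by the product of member abundances.
    """
    members = list(community)
    if len(members) < 2:
        raise ValueError("MPD undefined for communities with < 2 OTUs")
    w = weights.reindex(members).to_numpy() if weights is not None else None
    return _mpd_from_array(_submatrix(dist, members), w)


def mntd(community, dist: pd.DataFrame, weights: pd.Series | None = None) -> float:
    """Mean distance from each member to its nearest co-occurring OTU."""
    members = list(community)
    if len(members) < 2:
        raise ValueError("MNTD undefined for communities with < 2 OTUs")
    w = weights.reindex(members).to_numpy() if weights is not None else None
    return _mntd_from_array(_submatrix(dist, members), w)


def ses(
    community,
    tree: dendropy.Tree | None = None,
    metric: str = "MPD",
    n_permutations: int = 999,
    seed: int = 0,
    dist: pd.DataFrame | None = None,
    community_id: str = "",
    tail: str = "lower",
) -> SesResult:
    """Standardized effect size of MPD or MNTD under the tip-shuffle null.

    Tip labels are shuffled across the phylogeny while the community
    matrix stays fixed; with membership held constant this amounts to
    re-drawing an equal-sized random tip set from the pool, so the null
    is sampled by permuting the rows/columns of the distance matrix.
    ``p = (count(null <= observed) + 1) / (n_permutations + 1)`` for the
    default lower (clustering) tail; ``tail='two-sided'`` doubles the
    smaller tail.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    if dist is None:
        if tree is None:
            raise ValueError("provide a tree or a distance matrix")
        dist = phylo.cophenetic_distances(tree)
    members = list(community)
    k = len(members)
    if k < 2:
        raise ValueError("SES undefined for communities with < 2 OTUs")
    stat = _mpd_from_array if metric == "MPD" else _mntd_from_array
    observed = stat(_submatrix(dist, members))

    rng = np.random.default_rng(seed)
    d = dist.to_numpy()
    n = d.shape[0]
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        idx = rng.choice(n, size=k, replace=False)
        null[i] = stat(d[np.ix_(idx, idx)])
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    # relative floor: a null that only varies at float precision is flat
    degenerate = (
        not np.isfinite(null_sd)
        or null_sd <= 1e-10 * max(abs(null_mean), 1.0)
    )
    z = (observed - null_mean) / null_sd if not degenerate else np.nan
    p_low = (np.sum(null <= observed) + 1) / (n_permutations + 1)
    if tail == "lower":
        p = p_low
    elif tail == "two-sided":
        p_high = (np.sum(null >= observed) + 1) / (n_permutations + 1)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return SesResult(
        community_id=community_id,
        metric=metric,
        n_otus=k,
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        ses=float(z),
        p_value=float(p),
        n_permutations=n_permutations,
        degenerate=degenerate,
    )


def structure_table(
    table: PairedOtuTable,
    tree: dendropy.Tree,
    metrics=_METRICS,
    n_permutations: int = 999,
    seed: int = 0,
    pool: str = "all",
    max_missing_fraction: float = 0.05,
) -> pd.DataFrame:
    """SES of each metric for every sample x fraction community.

    The local pool is the union of OTUs over all samples and both
    fractions (``pool='all'``) or the per-fraction unions
    (``pool='per_fraction'``). OTUs absent from the tree are dropped
    with a warning column; if more than ``max_missing_fraction`` of the
    table's OTUs are missing the run aborts. Rows for empty or
    single-OTU communities are emitted flagged, not dropped.
    """
    tips = set(phylo.tip_labels(tree))
    missing = [o for o in table.otu_ids if o not in tips]
    if len(missing) > max_missing_fraction * max(len(table.otu_ids), 1):
        raise ValueError(
            f"{len(missing)}/{len(table.otu_ids)} OTUs absent from tree"
        )
    dist_full = phylo.cophenetic_distances(tree)
    n_jobs = len(FRACTIONS) * len(table.samples) * len(metrics)
    seeds = np.random.SeedSequence(seed).generate_state(n_jobs) >> 1
    job = 0
    rows = []
    pooled = [o for o in table.otu_ids if o in tips]
    for frac in FRACTIONS:
        frac_counts = table.fraction(frac)
        if pool == "all":
            pool_otus = pooled
        elif pool == "per_fraction":
            present = frac_counts.sum(axis=1) > 0
            pool_otus = [o for o in frac_counts.index[present] if o in tips]
        else:
            raise ValueError(f"unknown pool {pool!r}")
        dist = dist_full.loc[pool_otus, pool_otus]
        for sample in table.samples:
            col = frac_counts[sample]
            community = [o for o in col.index[col > 0] if o in pool_otus]
            cid = f"{sample}_{frac}"
            for metric in metrics:
                sub_seed = int(seeds[job])
                job += 1
                if len(community) < 2:
                    rows.append(
                        {
                            "sample": sample, "fraction": frac, "metric": metric,
                            "n_otus": len(community), "observed": np.nan,
                            "null_mean": np.nan, "null_sd": np.nan, "ses": np.nan,
                            "p_value": np.nan, "degenerate": True,
                        }
                    )
                    continue
                res = ses(
                    community, metric=metric, n_permutations=n_permutations,
                    seed=sub_seed, dist=dist, community_id=cid,
                )
                rows.append(
                    {
                        "sample": sample, "fraction": frac, "metric": metric,
                        "n_otus": res.n_otus, "observed": res.observed,
                        "null_mean": res.null_mean, "null_sd": res.null_sd,
                        "ses": res.ses, "p_value": res.p_value,
                        "degenerate": res.degenerate,
                    }
                )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < 0.05
    return out


def abundance_signal_check(
    table: PairedOtuTable, tree: dendropy.Tree, n_permutations: int = 999, seed: int = 0
) -> dict:
    """Blomberg's K on per-OTU total abundance, the null-model precondition.

    The fixed-abundance tip-shuffle null inflates type-I error when
    abundance itself is phylogenetically structured; a significant K
    here is a warning for the SES stage.
    """
    from .signal import blomberg_k, k_significance

    tips = set(phylo.tip_labels(tree))
    abundance = table.counts.sum(axis=1)
    abundance = abundance[[o in tips for o in abundance.index]].astype(float)
    k = blomberg_k(tree, abundance)
    p = k_significance(tree, abundance, n_permutations=n_permutations, seed=seed)
    return {"k": k, "p_value": p, "warn": p < 0.05}
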