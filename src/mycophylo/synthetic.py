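"""Synthetic trees, traits, communities and paired DNA/RNA count tables.

The generator emulates the statistical structure of a root fungal
microbiome survey: 19 host plants, each yielding one DNA and one RNA
amplicon library built from co-extracted nucleic acids, a few hundred
OTUs with strongly uneven abundances, and a rooted phylogeny over the
OTU pool. Per-OTU latent "activity" in [0, 1] governs how reads split
between the fractions, so the downstream mean expression ratio is a
monotone estimate of it.

Nothing at the nucleotide level is simulated: "sequences" in the
technical replicates are read tokens labelled by their OTU, which is all
the replicate-consensus filter needs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .tables import FRACTIONS, PairedOtuTable, replicate_consensus_filter
from . import phylo

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_bm_trait",
    "simulate_community",
    "simulate_paired_counts",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults mirror the surveyed design: 19 plants, a regional pool of
    300 OTUs of which each plant hosts 140, sequencing depth 2,000 reads
    per sample x fraction, duplicate technical replicates, log-normal
    latent abundances, and Brownian-motion activity on a Yule tree.
    """

    n_samples: int = 19
    n_pool_otus: int = 300
    richness_per_sample: int = 140
    assembly_mode: str = "random"  # random | filtered | overdispersed
    trait_model: str = "brownian"  # brownian | white_noise | constant
    bm_rate: float = 1.0  # trait variance per unit branch length
    sequencing_depth: int = 2000
    n_tech_replicates: int = 2
    birth_rate: float = 1.0
    abundance_sdlog: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.richness_per_sample > self.n_pool_otus:
            raise ValueError("richness_per_sample exceeds n_pool_otus")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.n_tech_replicates < 2:
            raise ValueError("need >= 2 technical replicates")

    def manifest(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree: rooted, bifurcating, ultrametric.

    Lineages split after exponential waiting times with per-lineage rate
    ``birth_rate``; after the last split every extant lineage is
    extended by a final exponential epoch so all branch lengths are
    strictly positive and all tips are contemporaneous. Tips are
    labelled ``otu001..``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_tips)))
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    # active lineages as (parent_node, pending_length)
    root = tree.seed_node
    active = [[root, 0.0]]
    # split the root immediately: a rooted Yule tree starts with 2 lineages
    while len(active) < n_tips:
        k = len(active)
        if k >= 2:
            dt = rng.exponential(1.0 / (birth_rate * k))
            for lin in active:
                lin[1] += dt
        idx = rng.integers(0, len(active)) if len(active) > 1 else 0
        parent, pending = active.pop(int(idx))
        node = parent
        if parent is not root or pending > 0 or len(active) > 0:
            node = dendropy.Node()
            parent.add_child(node)
            node.edge.length = pending
        active.append([node, 0.0])
        active.append([node, 0.0])
    # final epoch so pendant edges are positive
    dt = rng.exponential(1.0 / (birth_rate * n_tips))
    order = rng.permutation(n_tips)
    for rank, (parent, pending) in enumerate(active):
        leaf = dendropy.Node()
        parent.add_child(leaf)
        leaf.edge.length = pending + dt
        label = f"otu{order[rank] + 1:0{width}d}"
        leaf.taxon = taxa.new_taxon(label)
    tree.is_rooted = True
    return tree


def simulate_bm_trait(
    tree: dendropy.Tree, sigma2: float = 1.0, root_value: float = 0.0, seed: int = 0
) -> pd.Series:
    """Brownian-motion trait at the tips.

    Evolves the trait down the tree with independent N(0, sigma2 * b)
    increments per branch of length b, so the tip vector is multivariate
    normal with mean ``root_value`` and covariance ``sigma2 * C``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values = {tree.seed_node: root_value}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            b = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(sigma2 * b)) if sigma2 > 0 and b > 0 else 0.0
            values[node] = values[node.parent_node] + step
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return pd.Series(out, name="trait")


def simulate_white_noise_trait(
    tree: dendropy.Tree, variance: float = 1.0, mean: float = 0.0, seed: int = 0
) -> pd.Series:
    """iid normal trait ignoring the tree: no phylogenetic signal."""
    rng = np.random.default_rng(seed)
    labels = phylo.tip_labels(tree)
    return pd.Series(rng.normal(mean, np.sqrt(variance), len(labels)),
                     index=labels, name="trait")


def simulate_community(
    tree: dendropy.Tree, assembly_mode: str, richness: int, seed: int = 0
) -> list[str]:
    """One community (OTU membership) assembled from the tree's tip pool.

    ``random`` draws tips uniformly without replacement; ``filtered``
    draws them from within a single randomly chosen clade of at least
    ``richness`` tips (phylogenetic clustering by construction, the
    signature of environmental filtering); ``overdispersed`` selects
    tips greedily to maximise the minimum pairwise distance.
    """
    labels = phylo.tip_labels(tree)
    n = len(labels)
    if richness > n:
        raise ValueError("richness exceeds number of tips")
    rng = np.random.default_rng(seed)
    if richness == n:
        return list(labels)
    if assembly_mode == "random":
        return list(rng.choice(labels, size=richness, replace=False))
    if assembly_mode == "filtered":
        clades = []
        for node in tree.postorder_internal_node_iter():
            tips = [l.taxon.label for l in node.leaf_iter()]
            if richness <= len(tips) < n:
                clades.append(tips)
        if not clades:
            raise ValueError(
                f"no proper clade with >= {richness} tips; cannot emulate filtering"
            )
        clade = clades[rng.integers(0, len(clades))]
        return list(rng.choice(clade, size=richness, replace=False))
    if assembly_mode == "overdispersed":
        d = phylo.cophenetic_distances(tree).to_numpy()
        start = int(rng.integers(0, n))
        chosen = [start]
        mind = d[start].copy()
        mind[start] = -np.inf
        for _ in range(richness - 1):
            nxt = int(np.argmax(mind))
            chosen.append(nxt)
            mind = np.minimum(mind, d[nxt])
            mind[nxt] = -np.inf
        return [labels[i] for i in chosen]
    raise ValueError(f"unknown assembly_mode {assembly_mode!r}")


def simulate_paired_counts(
    memberships: dict[str, list[str]],
    activity: pd.Series,
    depth: int = 2000,
    n_tech_replicates: int = 2,
    seed: int = 0,
    abundance_sdlog: float = 1.5,
    apply_filter: bool = True,
) -> tuple[PairedOtuTable, dict]:
    """Paired DNA/RNA counts for each sample, via technical replicates.

    For every sample a latent abundance is drawn per member OTU
    (log-normal, meanlog 0, sdlog ``abundance_sdlog``, emulating the
    dominance of a few OTUs). DNA reads are multinomial with weights
    proportional to latent x (1 - activity), RNA reads with weights
    latent x activity — i.e. the RNA composition is the DNA composition
    reweighted by activity/(1 - activity). Each fraction is sequenced as
    ``n_tech_replicates`` independent multinomial replicates of ``depth``
    reads whose read multisets feed the replicate-consensus filter; the
    returned table holds the consensus counts (summed across replicates
    over OTUs seen in every replicate).

    Returns ``(table, replicates)`` where ``replicates`` maps
    ``(sample, fraction)`` to the list of per-replicate Counters of OTU
    read tokens.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n_tech_replicates < 2:
        raise ValueError("need >= 2 technical replicates")
    act = activity.astype(float)
    if ((act < 0) | (act > 1)).any():
        raise ValueError("activity values must lie in [0, 1]")
    for sample, members in memberships.items():
        missing = [m for m in members if m not in act.index]
        if missing:
            raise KeyError(f"activity undefined for {missing} in sample {sample}")

    rng = np.random.default_rng(seed)
    all_otus = sorted({m for mem in memberships.values() for m in mem})
    replicates: dict = {}
    consensus: dict = {}
    for sample, members in memberships.items():
        members = list(members)
        latent = rng.lognormal(0.0, abundance_sdlog, len(members))
        a = act[members].to_numpy()
        weights = {"DNA": latent * (1.0 - a), "RNA": latent * a}
        for frac in FRACTIONS:
            w = weights[frac]
            tot = w.sum()
            if tot <= 0:
                raise ValueError(
                    f"no probability mass in {frac} fraction of sample {sample}"
                )
            p = w / tot
            reps = []
            for _ in range(n_tech_replicates):
                draw = rng.multinomial(depth, p)
                reps.append(Counter({m: int(c) for m, c in zip(members, draw) if c}))
            replicates[(sample, frac)] = reps
            kept = replicate_consensus_filter(reps) if apply_filter else sum(reps, Counter())
            consensus[(sample, frac)] = kept

    counts = pd.DataFrame(
        0,
        index=pd.Index(all_otus, name="otu_id"),
        columns=pd.MultiIndex.from_product(
            [list(memberships), FRACTIONS], names=["sample", "fraction"]
        ),
        dtype=np.int64,
    )
    for key, counter in consensus.items():
        for otu, c in counter.items():
            counts.loc[otu, key] = c
    return PairedOtuTable(counts), replicates


def simulate_dataset(config: SimulationConfig) -> dict:
    """Full synthetic study: tree, activity trait, communities, counts.

    The activity trait is the logistic transform of the chosen trait
    model (Brownian motion on the tree, white noise, or constant 0.5) so
    it lies in [0, 1]. Returns a dict with keys ``tree``, ``activity``,
    ``memberships``, ``table``, ``replicates`` and ``config``.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_seed, trait_seed, comm_seed, count_seed = (
        int(s) for s in ss.generate_state(4) >> 1
    )
    tree = simulate_yule_tree(config.n_pool_otus, config.birth_rate, tree_seed)
    if config.trait_model == "brownian":
        raw = simulate_bm_trait(tree, config.bm_rate, 0.0, trait_seed)
        activity = 1.0 / (1.0 + np.exp(-raw))
    elif config.trait_model == "white_noise":
        raw = simulate_white_noise_trait(tree, config.bm_rate, 0.0, trait_seed)
        activity = 1.0 / (1.0 + np.exp(-raw))
    elif config.trait_model == "constant":
        activity = pd.Series(0.5, index=phylo.tip_labels(tree))
    else:
        raise ValueError(f"unknown trait_model {config.trait_model!r}")
    comm_rng = np.random.SeedSequence(comm_seed).generate_state(config.n_samples) >> 1
    memberships = {
        f"s{i + 1:02d}": simulate_community(
            tree, config.assembly_mode, config.richness_per_sample, int(comm_rng[i])
        )
        for i in range(config.n_samples)
    }
    table, replicates = simulate_paired_counts(
        memberships,
        activity,
        depth=config.sequencing_depth,
        n_tech_replicates=config.n_tech_replicates,
        seed=count_seed,
        abundance_sdlog=config.abundance_sdlog,
    )
    return {
        "tree": tree,
        "activity": activity,
        "memberships": memberships,
        "table": table,
        "replicates": replicates,
        "config": config,
    }
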