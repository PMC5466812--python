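"""Simulators: Yule trees, BM traits, community assembly, paired counts."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mycophylo import phylo
from mycophylo.signal import blomberg_k
from mycophylo.structure import ses
from mycophylo.synthetic import (
    SimulationConfig,
    simulate_bm_trait,
    simulate_community,
    simulate_dataset,
    simulate_paired_counts,
    simulate_yule_tree,
)


class TestYuleTree:
    def test_minimal_bifurcation(self):
        tree = simulate_yule_tree(2, seed=0)
        assert len(tree.leaf_nodes()) == 2
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 1

    def test_node_count_identity(self):
        tree = simulate_yule_tree(50, seed=1)
        internal = sum(1 for n in tree.preorder_node_iter() if not n.is_leaf())
        assert internal == 49
        assert len(tree.leaf_nodes()) == 50

    @pytest.mark.parametrize("seed", [0, 5, 99])
    def test_ultrametric_positive_branches(self, seed):
        tree = simulate_yule_tree(20, seed=seed)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
        for e in tree.preorder_edge_iter():
            if e.head_node is not tree.seed_node:
                assert e.length > 0

    def test_reproducible_under_seed(self):
        a = simulate_yule_tree(15, seed=4).as_string(schema="newick")
        b = simulate_yule_tree(15, seed=4).as_string(schema="newick")
        assert a == b

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, seed=0)


class TestBmTrait:
    def test_zero_rate_constant_at_root_value(self):
        tree = simulate_yule_tree(10, seed=2)
        x = simulate_bm_trait(tree, 0.0, 3.5, seed=0)
        assert (x == 3.5).all()

    def test_star_tree_tip_variance_matches_closed_form(self, star_tree):
        sigma2, t_len = 2.0, 1.0
        tips = np.array([
            simulate_bm_trait(star_tree, sigma2, 0.0, seed=r).to_numpy()
            for r in range(1000)
        ])
        assert tips.var() == pytest.approx(sigma2 * t_len, rel=0.1)

    def test_sister_covariance_matches_vcv_entry(self):
        tree = phylo.read_newick("((A:1.0,B:1.0):3.0,C:4.0);")
        reps = np.array([
            simulate_bm_trait(tree, 1.0, 0.0, seed=r)[["A", "B"]].to_numpy()
            for r in range(500)
        ])
        cov = np.cov(reps.T)[0, 1]
        assert cov == pytest.approx(3.0, rel=0.2)  # shared stem length

    def test_mean_k_near_one_under_bm(self):
        tree = simulate_yule_tree(100, seed=3)
        ks = [blomberg_k(tree, simulate_bm_trait(tree, 1.0, 0.0, seed=r))
              for r in range(200)]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_negative_rate_rejected(self):
        tree = simulate_yule_tree(5, seed=0)
        with pytest.raises(ValueError):
            simulate_bm_trait(tree, -1.0, 0.0, seed=0)


@pytest.fixture(scope="module")
def tree():
    return simulate_yule_tree(64, seed=10)


@pytest.fixture(scope="module")
def paired_setup():
    otus = [f"o{i}" for i in range(6)]
    memberships = {f"s{j}": otus for j in range(4)}
    activity = pd.Series([0.0, 1.0, 0.2, 0.8, 0.5, 0.5], index=otus)
    return memberships, activity


class TestCommunity:
    @pytest.mark.parametrize("mode", ["random", "filtered", "overdispersed"])
    def test_full_richness_returns_whole_pool(self, tree, mode):
        got = simulate_community(tree, mode, 64, seed=0)
        assert sorted(got) == sorted(phylo.tip_labels(tree))

    @pytest.mark.parametrize("mode", ["random", "filtered", "overdispersed"])
    def test_membership_size_and_uniqueness(self, tree, mode):
        got = simulate_community(tree, mode, 12, seed=1)
        assert len(got) == 12 and len(set(got)) == 12

    def test_filtered_draws_within_one_clade(self, tree):
        dist = phylo.cophenetic_distances(tree)
        members = simulate_community(tree, "filtered", 10, seed=2)
        rng = np.random.default_rng(0)
        rand_mpds = []
        labels = list(dist.index)
        for _ in range(100):
            sub = rng.choice(labels, 10, replace=False)
            rand_mpds.append(dist.loc[sub, sub].to_numpy().mean())
        clade_mpd = dist.loc[members, members].to_numpy().mean()
        assert clade_mpd < np.mean(rand_mpds)

    def test_filtered_without_big_clade_fails_loudly(self):
        tree = simulate_yule_tree(8, seed=0)
        with pytest.raises(ValueError, match="clade"):
            simulate_community(tree, "filtered", 7, seed=0)

    def test_overdispersed_beats_random_min_distance(self, tree):
        dist = phylo.cophenetic_distances(tree)
        over = simulate_community(tree, "overdispersed", 8, seed=3)
        rnd = simulate_community(tree, "random", 8, seed=3)
        def min_d(mem):
            sub = dist.loc[mem, mem].to_numpy()
            return sub[np.triu_indices(len(mem), 1)].min()
        assert min_d(over) >= min_d(rnd)

    def test_filtered_communities_cluster_downstream(self, tree):
        """SES_MPD is negative for clade-restricted communities."""
        dist = phylo.cophenetic_distances(tree)
        negatives = 0
        for rep in range(30):
            members = simulate_community(tree, "filtered", 12, seed=rep)
            res = ses(members, dist=dist, metric="MPD", n_permutations=199, seed=rep)
            negatives += res.ses < 0
        assert negatives >= 27


class TestPairedCounts:
    def test_zero_activity_means_no_rna(self, paired_setup):
        memberships, activity = paired_setup
        table, _ = simulate_paired_counts(memberships, activity, depth=500, seed=0)
        assert (table.fraction("RNA").loc["o0"] == 0).all()

    def test_full_activity_means_no_dna(self, paired_setup):
        memberships, activity = paired_setup
        table, _ = simulate_paired_counts(memberships, activity, depth=500, seed=0)
        assert (table.fraction("DNA").loc["o1"] == 0).all()

    def test_replicates_conserve_depth(self, paired_setup):
        memberships, activity = paired_setup
        _, reps = simulate_paired_counts(memberships, activity, depth=321, seed=1)
        for counters in reps.values():
            for c in counters:
                assert sum(c.values()) == 321

    def test_bit_identical_under_seed(self, paired_setup):
        memberships, activity = paired_setup
        a, _ = simulate_paired_counts(memberships, activity, depth=200, seed=9)
        b, _ = simulate_paired_counts(memberships, activity, depth=200, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_invalid_activity_rejected(self, paired_setup):
        memberships, _ = paired_setup
        bad = pd.Series(1.5, index=[f"o{i}" for i in range(6)])
        with pytest.raises(ValueError, match="activity"):
            simulate_paired_counts(memberships, bad, depth=100, seed=0)

    def test_consensus_filter_drops_non_shared_reads(self, paired_setup):
        memberships, activity = paired_setup
        table, reps = simulate_paired_counts(memberships, activity, depth=50, seed=2)
        # consensus counts never exceed the straight replicate sum
        raw, _ = simulate_paired_counts(memberships, activity, depth=50, seed=2,
                                        apply_filter=False)
        assert (table.counts.to_numpy() <= raw.counts.to_numpy()).all()


class TestDataset:
    def test_manifest_and_determinism(self):
        cfg = SimulationConfig(n_samples=4, n_pool_otus=30, richness_per_sample=15,
                               sequencing_depth=200, seed=12)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a["table"].counts, b["table"].counts)
        assert a["tree"].as_string(schema="newick") == b["tree"].as_string(schema="newick")
        assert "n_samples" in cfg.manifest()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_pool_otus=10, richness_per_sample=20)
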