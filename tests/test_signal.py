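"""Blomberg's K, Kse and the contrast-variance permutation test."""

import numpy as np
import pandas as pd
import pytest

from mycophylo import phylo
from mycophylo.signal import blomberg_k, k_significance, kse, signal_table
from mycophylo.synthetic import (
    simulate_bm_trait,
    simulate_white_noise_trait,
    simulate_yule_tree,
)


@pytest.fixture(scope="module")
def yule100():
    return simulate_yule_tree(100, seed=42)


def balanced_tree(depth):
    """Fully balanced bifurcating tree with unit branches."""
    def build(d, prefix):
        if d == 0:
            return f"{prefix}:1.0"
        return f"({build(d - 1, prefix + 'l')},{build(d - 1, prefix + 'r')}):1.0"
    return phylo.read_newick(f"({build(depth - 1, 'l')},{build(depth - 1, 'r')});")


class TestBlombergK:
    def test_star_tree_k_is_one(self, star_tree):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = pd.Series(rng.normal(size=8), index=phylo.tip_labels(star_tree))
            assert blomberg_k(star_tree, x) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=1)
        k = blomberg_k(yule100, x)
        assert blomberg_k(yule100, 3.0 * x - 7.0) == pytest.approx(k, rel=1e-9)

    def test_branch_scale_invariance(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=2)
        k = blomberg_k(yule100, x)
        scaled = yule100.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 25.0
        assert blomberg_k(scaled, x) == pytest.approx(k, rel=1e-9)

    def test_shuffling_destroys_signal(self):
        tree = balanced_tree(6)  # deep balanced 64-tip tree
        labels = phylo.tip_labels(tree)
        rng = np.random.default_rng(3)
        ks = []
        for rep in range(200):
            x = simulate_bm_trait(tree, 1.0, 0.0, seed=rep).to_numpy()
            shuffled = pd.Series(x[rng.permutation(len(x))], index=labels)
            ks.append(blomberg_k(tree, shuffled))
        assert np.mean(ks) < 0.5

    def test_white_noise_low_k(self):
        tree = balanced_tree(6)
        ks = [
            blomberg_k(tree, simulate_white_noise_trait(tree, 1.0, 0.0, seed=r))
            for r in range(200)
        ]
        assert np.mean(ks) < 0.6

    def test_constant_trait_rejected(self, yule100):
        x = pd.Series(1.0, index=phylo.tip_labels(yule100))
        with pytest.raises(ValueError, match="degenerate"):
            blomberg_k(yule100, x)


class TestKse:
    def test_reduces_to_k_at_zero_se(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=5)
        se = pd.Series(0.0, index=x.index)
        assert kse(yule100, x, se) == pytest.approx(blomberg_k(yule100, x), abs=1e-9)

    def test_corrects_attenuation_from_noise(self, yule100):
        """With known observation SEs, Kse on the noisy trait sits closer
        to the BM value 1 than raw K does (on average)."""
        rng = np.random.default_rng(6)
        sigma_obs = 0.8
        se = pd.Series(sigma_obs, index=phylo.tip_labels(yule100))
        raw, corrected = [], []
        for rep in range(60):
            x = simulate_bm_trait(yule100, 1.0, 0.0, seed=1000 + rep)
            noisy = x + rng.normal(0.0, sigma_obs, len(x))
            raw.append(blomberg_k(yule100, noisy))
            corrected.append(kse(yule100, noisy, se))
        assert abs(np.mean(corrected) - 1.0) < abs(np.mean(raw) - 1.0)

    def test_huge_se_flagged_degenerate(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=7)
        se = pd.Series(1e6, index=x.index)
        _, details = kse(yule100, x, se, return_details=True)
        assert details["degenerate"]

    def test_non_finite_se_rejected(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=8)
        se = pd.Series(np.inf, index=x.index)
        with pytest.raises(ValueError, match="finite"):
            kse(yule100, x, se)

    def test_nonnegative(self, yule100):
        for rep in range(5):
            x = simulate_white_noise_trait(yule100, 1.0, 0.0, seed=rep)
            se = pd.Series(0.1, index=x.index)
            assert kse(yule100, x, se) >= 0


class TestSignificance:
    def test_reproducible_under_seed(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=9)
        a = k_significance(yule100, x, n_permutations=999, seed=12)
        b = k_significance(yule100, x, n_permutations=999, seed=12)
        assert a == b

    def test_bm_trait_detected(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=10)
        assert k_significance(yule100, x, n_permutations=199, seed=0) < 0.05


class TestSignalTable:
    def test_single_global_scope_one_row(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=11)
        traits = pd.DataFrame({"value": x, "se": 0.05})
        out = signal_table({"all": yule100}, traits, n_permutations=99, seed=0)
        assert len(out) == 1 and out.loc[0, "scope"] == "all"

    def test_reference_tips_excluded(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=12)
        traits = pd.DataFrame({"value": x, "se": 0.05})
        out = signal_table(
            {"all": yule100}, traits, n_permutations=99, seed=0,
            exclude_tips=set(x.index[:10]),
        )
        assert out.loc[0, "n_tips"] == 90

    def test_small_scope_skipped_with_warning(self, yule100):
        x = simulate_bm_trait(yule100, 1.0, 0.0, seed=13)
        traits = pd.DataFrame({"value": x.iloc[:3], "se": 0.05})
        with pytest.warns(UserWarning, match="skipped"):
            out = signal_table({"tiny": yule100}, traits, n_permutations=99, seed=0)
        assert out.empty

    def test_planted_signal_recovered_in_order(self):
        """BM activity on one clade, white noise on another: scoped K ordered."""
        tree = simulate_yule_tree(80, seed=30)
        left, right = tree.seed_node.child_nodes()
        clade_a = [l.taxon.label for l in left.leaf_iter()]
        clade_b = [l.taxon.label for l in right.leaf_iter()]
        if len(clade_a) < 10 or len(clade_b) < 10:
            pytest.skip("unbalanced root split for this seed")
        sub_a = tree.clone(depth=1)
        sub_a.retain_taxa_with_labels(clade_a)
        sub_b = tree.clone(depth=1)
        sub_b.retain_taxa_with_labels(clade_b)
        bm = simulate_bm_trait(sub_a, 1.0, 0.0, seed=31)
        wn = simulate_white_noise_trait(sub_b, 1.0, 0.0, seed=32)
        traits = pd.DataFrame({"value": pd.concat([bm, wn]), "se": 0.0})
        out = signal_table({"bm_clade": sub_a, "wn_clade": sub_b}, traits,
                           n_permutations=199, seed=1).set_index("scope")
        assert out.loc["bm_clade", "kse"] > out.loc["wn_clade", "kse"]
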