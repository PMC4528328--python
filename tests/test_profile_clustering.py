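"""Gower distance, UPGMA clustering, tissue-specificity binning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magic_mae.profile_clustering import (
    Dendrogram,
    cluster_profiles,
    gower_distance,
    pairwise_distances,
    specificity_bins,
    upgma,
)
from magic_mae.synthetic_data import simulate_profiles

NA = np.nan


class TestGowerDistance:
    def test_mismatch_fraction_over_shared(self):
        assert gower_distance([1, 0, 1, NA], [1, 1, 0, 1]) == pytest.approx(2 / 3)

    def test_identity_and_complement(self):
        assert gower_distance([1, 0, 1], [1, 0, 1]) == 0.0
        assert gower_distance([1, 0, 1], [0, 1, 0]) == 1.0

    def test_no_shared_genes_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            gower_distance([1, NA], [NA, 0])

    def test_triangle_inequality_on_complete_profiles(self, rng):
        for _ in range(200):
            a, b, c = (rng.integers(0, 2, 12).astype(float) for _ in range(3))
            dab = gower_distance(a, b)
            dbc = gower_distance(b, c)
            dac = gower_distance(a, c)
            assert dac <= dab + dbc + 1e-12


def brute_force_upgma(dist: pd.DataFrame):
    """Independent dict-based UPGMA for cross-checking (same tie-break rule)."""
    clusters = {name: (name, [name], 0.0) for name in dist.index}

    def d(m1, m2):
        return np.mean([[dist.loc[a, b] for b in m2] for a in m1])

    merges = []
    while len(clusters) > 1:
        best = None
        for l1, l2 in itertools.combinations(sorted(clusters), 2):
            dd = d(clusters[l1][1], clusters[l2][1])
            key = (dd, min(l1, l2), max(l1, l2))
            if best is None or key < best:
                best = key
        dd, l1, l2 = best
        merges.append((l1, l2, dd / 2.0))
        members = clusters.pop(l1)[1] + clusters.pop(l2)[1]
        clusters[min(l1, l2)] = (min(l1, l2), members, dd / 2.0)
    return merges


def random_distance_matrix(rng, labels):
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.uniform(0.05, 1.0, len(iu[0]))
    m += m.T
    return pd.DataFrame(m, index=labels, columns=labels)


class TestUpgma:
    def test_hand_example(self):
        d = pd.DataFrame(
            [[0, 2, 8], [2, 0, 8], [8, 8, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = upgma(d)
        assert [(m.left, m.right, m.height) for m in tree.merges] == [
            ("A", "B", 1.0),
            ("A", "C", 4.0),
        ]

    def test_two_samples_single_merge(self):
        d = pd.DataFrame([[0, 3], [3, 0]], index=["x", "y"], columns=["x", "y"],
                         dtype=float)
        tree = upgma(d)
        assert tree.merges[0].height == 1.5

    def test_all_equal_distances_lexicographic_merges(self):
        labels = list("DACB")
        d = pd.DataFrame(1.0 - np.eye(4), index=labels, columns=labels)
        tree = upgma(d)
        assert (tree.merges[0].left, tree.merges[0].right) == ("A", "B")
        assert all(m.height == 0.5 for m in tree.merges)

    def test_single_sample_rejected(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            upgma(d)

    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_matches_brute_force_reference(self, rng, n_leaves):
        labels = [f"s{i}" for i in range(n_leaves)]
        for _ in range(500):
            d = random_distance_matrix(rng, labels)
            tree = upgma(d)
            ref = brute_force_upgma(d)
            got = [(m.left, m.right, m.height) for m in tree.merges]
            want = [(min(a, b), max(a, b), h) for a, b, h in ref]
            got = [(min(a, b), max(a, b), h) for a, b, h in got]
            assert [g[:2] for g in got] == [w[:2] for w in want]
            np.testing.assert_allclose([g[2] for g in got], [w[2] for w in want])

    def test_heights_ultrametric(self, rng):
        labels = [f"s{i}" for i in range(6)]
        for _ in range(100):
            d = random_distance_matrix(rng, labels)
            tree = upgma(d)
            heights = [m.height for m in tree.merges]
            assert np.all(np.diff(heights) >= -1e-12)
            coph = tree.cophenetic()
            for i, j, k in itertools.combinations(labels, 3):
                trio = sorted([coph.loc[i, j], coph.loc[j, k], coph.loc[i, k]])
                assert trio[1] == pytest.approx(trio[2])

    def test_newick_parses_with_branch_lengths(self):
        d = pd.DataFrame(
            [[0, 2, 8], [2, 0, 8], [8, 8, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        import dendropy

        nwk = upgma(d).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"A", "B", "C"}
        root_to_leaf = tree.calc_node_root_distances(return_leaf_distances_only=True)
        np.testing.assert_allclose(root_to_leaf, 4.0)


class TestClusterProfiles:
    def test_recovers_planted_topology(self):
        profiles, newick = simulate_profiles(
            n_genes=2000, switch_prob=0.05, mae_fraction=0.3, seed=21
        )
        tree, sim = cluster_profiles(profiles)
        # planted tree: ((A,B),(C,D)) vs (E,F); cherries must merge first
        first_pairs = {frozenset((m.left, m.right)) for m in tree.merges[:3]}
        assert first_pairs == {
            frozenset("AB"), frozenset("CD"), frozenset("EF"),
        }
        assert (sim.to_numpy() <= 1.0).all()

    def test_duplicated_sample_merges_at_zero(self):
        profiles, _ = simulate_profiles(n_genes=200, switch_prob=0.1, seed=3)
        profiles["A2"] = profiles["A"]
        tree, _ = cluster_profiles(profiles)
        first = tree.merges[0]
        assert {first.left, first.right} == {"A", "A2"}
        assert first.height == 0.0

    def test_sample_order_invariance(self):
        profiles, _ = simulate_profiles(n_genes=300, switch_prob=0.1, seed=5)
        t1, _ = cluster_profiles(profiles)
        t2, _ = cluster_profiles(profiles[sorted(profiles.columns, reverse=True)])
        assert [(m.left, m.right, m.height) for m in t1.merges] == [
            (m.left, m.right, m.height) for m in t2.merges
        ]

    def test_missing_entries_use_pairwise_shared_genes(self):
        profiles = pd.DataFrame(
            {"s1": [1, 0, NA, 1], "s2": [1, NA, 0, 0], "s3": [1, 0, 0, 1]},
            index=[f"g{i}" for i in range(4)],
        )
        d = pairwise_distances(profiles)
        assert d.loc["s1", "s2"] == pytest.approx(0.5)  # shared genes g0, g3
        assert d.loc["s1", "s3"] == 0.0


class TestSpecificityBins:
    def make(self):
        profiles = pd.DataFrame(
            {"s1": [1, 0, 1, NA], "s2": [0, 0, 1, 1], "s3": [NA, 0, 1, 1]},
            index=[f"g{i}" for i in range(4)],
        )
        expressed = pd.DataFrame(
            {"s1": [True, False, True, False],
             "s2": [False, True, True, True],
             "s3": [False, False, True, True]},
            index=profiles.index,
        )
        return profiles, expressed

    def test_bin_assignment_and_proportions(self):
        profiles, expressed = self.make()
        out = specificity_bins(profiles, expressed)
        # g0 expressed in 1 sample -> bin 1; g2 in 3 samples -> bin 3
        b1 = out[(out["bin"] == 1) & (out["sample"] == "s1")]
        assert b1["mae_proportion"].iloc[0] == 1.0  # g0 is MAE in s1
        b3 = out[(out["bin"] == 3) & (out["sample"] == "s2")]
        assert b3["mae_proportion"].iloc[0] == 1.0

    def test_empty_cells_omitted(self):
        profiles, expressed = self.make()
        out = specificity_bins(profiles, expressed)
        # bin 1 has no expressed genes in s3 (g0 not expressed there)
        assert out[(out["bin"] == 1) & (out["sample"] == "s3")].empty

    def test_planted_specificity_trend(self):
        # MAE probability decreasing with expression breadth -> decreasing medians
        rng = np.random.default_rng(8)
        n, samples = 3000, [f"s{i}" for i in range(5)]
        breadth = rng.integers(1, 6, n)
        expressed = pd.DataFrame(
            [np.isin(np.arange(5), rng.choice(5, b, replace=False)) for b in breadth],
            index=[f"g{i}" for i in range(n)], columns=samples,
        )
        p_mae = 0.5 - 0.08 * breadth
        calls = pd.DataFrame(
            (rng.random((n, 5)).T < p_mae).T.astype(float),
            index=expressed.index, columns=samples,
        )
        out = specificity_bins(calls, expressed)
        medians = out.groupby("bin")["median"].first()
        assert (np.diff(medians.to_numpy()) < 0).all()
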