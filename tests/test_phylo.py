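import itertools

import dendropy
import numpy as np
import pytest

from cpakit.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_supports,
    nj_tree,
    pairwise_distances,
    phylogenetic_diversity,
    select_diverse_subset,
)
from cpakit.synthetic import simulate_tree
from conftest import patristic_matrix, random_additive_tree


def brute_force_pd(tree: dendropy.Tree, subset) -> float:
    """Union of leaf-to-leaf paths, computed edge by edge."""
    subset = set(subset)
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below & subset and subset - below:
            total += node.edge.length or 0.0
    return total


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]))


class TestPairwiseDistances:
    def test_identical_rows_distance_zero(self, lg):
        dm = pairwise_distances(["a", "b"], ["MKVD", "MKVD"], lg)
        assert dm.matrix[0, 1] == 0.0

    def test_saturated_pair_capped(self, lg):
        dm = pairwise_distances(["a", "b"], ["AAAAAAAAAA", "KKKKKKKKKK"], lg)
        assert dm.matrix[0, 1] == pytest.approx(3.0)

    def test_gap_sites_excluded_pairwise(self, lg):
        dm = pairwise_distances(["a", "b"], ["MK-D", "MKV-"], lg)
        dm2 = pairwise_distances(["a", "b"], ["MK", "MK"], lg)
        assert dm.matrix[0, 1] == dm2.matrix[0, 1]

    def test_incomparable_pair_named(self, lg):
        with pytest.raises(ValueError, match="a.*b"):
            pairwise_distances(["a", "b"], ["M-", "-K"], lg)

    def test_recovers_simulated_distance(self, lg):
        # simulation oracle: two sequences at known divergence
        rng = np.random.default_rng(8)
        true_t, L = 0.3, 2000
        errs = []
        for _ in range(10):
            anc = lg.sample_equilibrium(rng, L)
            P = lg.transition_matrix(true_t)
            u = rng.random(L)
            der = (P[anc].cumsum(axis=1) > u[:, None]).argmax(axis=1)
            from cpakit.substitution import decode_states
            dm = pairwise_distances(["a", "b"],
                                    [decode_states(anc), decode_states(der)], lg)
            errs.append(abs(dm.matrix[0, 1] - true_t))
        assert np.mean(errs) < 0.05


class TestNeighborJoining:
    def test_four_leaf_additive_recovery(self):
        tree = dendropy.Tree.get(data="((a:1,b:2):1.5,(c:0.5,d:3):1);",
                                 schema="newick")
        labels, mat = patristic_matrix(tree)
        result = nj_tree(DistanceMatrix(labels, mat))
        assert bipartitions(result) == {frozenset({"a", "b"})}
        _, back = patristic_matrix(result)
        assert np.allclose(back, mat, atol=1e-9)

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]])))

    def test_additive_recovery_suite(self):
        # 50 random 5-8 leaf trees: NJ must reproduce topology and path lengths
        rng = np.random.default_rng(11)
        for _ in range(50):
            tree = random_additive_tree(rng, int(rng.integers(5, 9)))
            labels, mat = patristic_matrix(tree)
            result = nj_tree(DistanceMatrix(labels, mat))
            assert bipartitions(result) == bipartitions(tree)
            _, back = patristic_matrix(result)
            assert np.allclose(back, mat, atol=1e-8)

    def test_agrees_with_independent_nj_implementation(self):
        # cross-check against scikit-bio's NJ on a non-additive matrix
        import skbio

        rng = np.random.default_rng(4)
        n = 7
        labels = [f"L{i}" for i in range(n)]
        noise = rng.uniform(0.1, 1.0, (n, n))
        mat = (noise + noise.T) / 2
        np.fill_diagonal(mat, 0.0)
        mine = nj_tree(DistanceMatrix(labels, mat))
        theirs_nwk = skbio.tree.nj(
            skbio.DistanceMatrix(mat, ids=labels)).write([]).pop()
        theirs = dendropy.Tree.get(data=theirs_nwk, schema="newick")
        assert bipartitions(mine) == bipartitions(theirs)


class TestBipartitions:
    def test_four_leaf_tree_single_split(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1);", schema="newick")
        assert bipartitions(tree) == {frozenset({"a", "b"})}

    def test_split_count_is_n_minus_3(self):
        rng = np.random.default_rng(2)
        for n in (4, 6, 9, 14):
            tree = random_additive_tree(rng, n)
            # rooted binary tree: the root edge merges two splits -> n-3 internal
            assert len(bipartitions(tree)) == n - 3

    def test_rerooted_copy_same_splits(self):
        rng = np.random.default_rng(3)
        tree = random_additive_tree(rng, 8)
        splits = bipartitions(tree)
        clone = tree.clone(depth=1)
        node = [n for n in clone.preorder_node_iter()
                if n.is_internal() and n.parent_node is not None][1]
        clone.reroot_at_node(node)
        assert bipartitions(clone) == splits


@pytest.fixture(scope="module")
def signal_msa():
    # overwhelming signal for the ab|cde split via many diagnostic columns
    rows = {
        "a": "AAAAAAAAAA" + "DDDDDDDDDD",
        "b": "AAAAAAAAAC" + "DDDDDDDDDE",
        "c": "KKKKKKKKKK" + "GGGGGGGGGG",
        "d": "KKKKKKKKKR" + "GGGGGGGGGH",
        "e": "KKKKKKKKKW" + "GGGGGGGGGY",
    }
    return list(rows.keys()), list(rows.values())


class TestBootstrap:
    def test_unanimous_edge_support_one(self, signal_msa, lg):
        ids, rows = signal_msa
        tree = bootstrap_supports(ids, rows, n_replicates=20, seed=5, model=lg)
        supports = {
            frozenset(lf.taxon.label for lf in node.leaf_iter()):
                node.annotations.get_value("support")
            for node in tree.preorder_node_iter()
            if node.parent_node is not None and not node.is_leaf()
        }
        ab = [v for k, v in supports.items() if k in
              ({"a", "b"}, {"c", "d", "e"})]
        assert ab and all(v == 1.0 for v in ab)

    def test_single_replicate_supports_binary(self, signal_msa, lg):
        ids, rows = signal_msa
        tree = bootstrap_supports(ids, rows, n_replicates=1, seed=2, model=lg)
        vals = [node.annotations.get_value("support")
                for node in tree.preorder_node_iter()
                if node.parent_node is not None and not node.is_leaf()
                and node.annotations.get_value("support") is not None]
        assert vals and all(v in (0.0, 1.0) for v in vals)

    def test_deterministic_given_seed(self, signal_msa, lg):
        ids, rows = signal_msa
        t1 = bootstrap_supports(ids, rows, 10, seed=7, model=lg)
        t2 = bootstrap_supports(ids, rows, 10, seed=7, model=lg)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


class TestPhylogeneticDiversity:
    def test_all_leaves_equals_total_branch_length(self):
        rng = np.random.default_rng(6)
        tree = random_additive_tree(rng, 9)
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        total = sum(e.length for e in tree.preorder_edge_iter() if e.length)
        assert phylogenetic_diversity(tree, leaves) == pytest.approx(total)

    def test_cherry_equals_pendant_sum(self):
        tree = dendropy.Tree.get(data="((a:1,b:2):1.5,(c:0.5,d:3):1);",
                                 schema="newick")
        assert phylogenetic_diversity(tree, ["a", "b"]) == pytest.approx(3.0)

    def test_matches_path_union_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            tree = random_additive_tree(rng, 8)
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            for _ in range(5):
                k = int(rng.integers(2, 8))
                subset = list(rng.choice(leaves, size=k, replace=False))
                assert phylogenetic_diversity(tree, subset) == pytest.approx(
                    brute_force_pd(tree, subset))

    def test_unknown_leaf_rejected(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,c:1);", schema="newick")
        with pytest.raises(ValueError, match="zzz"):
            phylogenetic_diversity(tree, ["a", "zzz"])


class TestDiverseSubsetSelection:
    def test_k_equals_n_returns_all(self):
        rng = np.random.default_rng(10)
        tree = random_additive_tree(rng, 7)
        leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        assert select_diverse_subset(tree, 7) == leaves

    def test_k2_is_diameter_pair(self):
        rng = np.random.default_rng(12)
        tree = random_additive_tree(rng, 8)
        labels, mat = patristic_matrix(tree)
        i, j = np.unravel_index(np.argmax(mat), mat.shape)
        assert set(select_diverse_subset(tree, 2)) == {labels[i], labels[j]}

    def test_greedy_matches_exhaustive_maximum(self):
        # greedy PD is provably optimal; verify exhaustively on small trees
        rng = np.random.default_rng(13)
        for n in (6, 9, 12):
            tree = random_additive_tree(rng, n)
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            for k in range(2, n + 1):
                greedy = select_diverse_subset(tree, k)
                greedy_pd = phylogenetic_diversity(tree, greedy)
                best = max(phylogenetic_diversity(tree, list(c))
                           for c in itertools.combinations(leaves, k))
                assert greedy_pd == pytest.approx(best, abs=1e-9)

    def test_pd_non_decreasing_in_k(self):
        rng = np.random.default_rng(14)
        tree = random_additive_tree(rng, 10)
        pds = [phylogenetic_diversity(tree, select_diverse_subset(tree, k))
               for k in range(2, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(pds, pds[1:]))

    def test_k_out_of_range(self):
        tree = simulate_tree(5, 0)
        with pytest.raises(ValueError):
            select_diverse_subset(tree, 1)
        with pytest.raises(ValueError):
            select_diverse_subset(tree, 6)
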