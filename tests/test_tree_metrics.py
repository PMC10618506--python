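import dendropy
import numpy as np
import pytest
from math import comb

import oracles
from conftest import random_binary_tree
from seqfunnel.seqio import parse_newick
from seqfunnel.tree_metrics import (
    METRIC_NAMES,
    TreeComparisonError,
    compare_all,
    cophenetic_l2,
    mast_distance,
    matching_cluster,
    matching_pair,
    nodal_splitted,
    path_difference,
    quartet_distance,
    rf_distance,
    triples_distance,
)


def rooted_pair(n, seed):
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n)]
    return (
        random_binary_tree(labels, rng, rooted=True),
        random_binary_tree(labels, rng, rooted=True),
    )


class TestWorkedExamples:
    def test_identical_trees_all_zero(self, rng):
        t = random_binary_tree([f"t{i}" for i in range(6)], rng, rooted=True)
        u = parse_newick(t.as_string(schema="newick"), rooted=True)
        for res in compare_all(t, u):
            assert res.value == 0.0, res.metric

    def test_conflicting_quartet_values(self, quartet_trees):
        t1, t2 = quartet_trees
        assert rf_distance(t1, t2).value == 1.0
        assert quartet_distance(t1, t2).value == 1.0
        assert matching_pair(t1, t2).value == 4.0
        assert path_difference(t1, t2).value == 4.0
        assert cophenetic_l2(t1, t2).value == 4.0

    def test_conflicting_quartet_rooted_values(self, quartet_trees):
        # midpoint rooting puts the root on the internal edge of each tree
        t1, t2 = quartet_trees
        assert mast_distance(t1, t2).value == 2.0
        assert matching_cluster(t1, t2).value == 4.0
        assert triples_distance(t1, t2).value == 4.0

    def test_three_taxon_triple(self):
        t1 = parse_newick("((A:1,B:1):1,C:1);", rooted=True)
        t2 = parse_newick("((A:1,C:1):1,B:1);", rooted=True)
        assert triples_distance(t1, t2).value == 1.0

    def test_cophenetic_scales_with_branch_lengths(self, quartet_trees):
        t1, _ = quartet_trees
        doubled = parse_newick("((A:2,B:2):2,(C:2,D:2):2);")
        # each of the 6 pairwise paths doubles
        expected = np.sqrt(sum(p**2 for p in (2, 4, 4, 4, 4, 2)))
        assert cophenetic_l2(t1, doubled).value == pytest.approx(expected)

    def test_path_difference_branch_length_invariant(self, quartet_trees):
        t1, _ = quartet_trees
        stretched = parse_newick("((A:9,B:1):4,(C:2,D:7):1);")
        assert path_difference(t1, stretched).value == 0.0

    def test_nodal_splitted_hand_example(self):
        t1 = parse_newick("((A,B),C);", rooted=True)
        t2 = parse_newick("((A,C),B);", rooted=True)
        # up-distances for ordered pairs (A,B),(A,C),(B,A),(B,C),(C,A),(C,B):
        # t1: 1,2,1,2,1,1   t2: 2,1,1,1,1,2  -> diff (-1,1,0,1,0,-1), norm 2
        assert nodal_splitted(t1, t2).value == pytest.approx(2.0)


class TestContracts:
    def test_leaf_set_mismatch_reported(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        with pytest.raises(TreeComparisonError, match="leaf sets differ"):
            rf_distance(t1, t2)

    def test_symmetry_of_all_metrics(self):
        t1, t2 = rooted_pair(7, seed=11)
        for name, res in zip(METRIC_NAMES, compare_all(t1, t2)):
            rev = dict(zip(METRIC_NAMES, compare_all(t2, t1)))[name]
            assert res.value == pytest.approx(rev.value), name

    def test_compare_all_stable_order_and_nonnegative(self):
        t1, t2 = rooted_pair(6, seed=5)
        results = compare_all(t1, t2)
        assert tuple(r.metric for r in results) == METRIC_NAMES
        assert all(r.value >= 0 for r in results)

    def test_combinatorial_bounds(self):
        for seed in range(5):
            t1, t2 = rooted_pair(7, seed=seed)
            n = 7
            assert quartet_distance(t1, t2).value <= comb(n, 4)
            assert triples_distance(t1, t2).value <= comb(n, 3)
            assert rf_distance(t1, t2).value <= n - 3

    def test_normalized_in_unit_interval(self):
        t1, t2 = rooted_pair(8, seed=3)
        for res in compare_all(t1, t2):
            if res.normalized is not None:
                assert 0.0 <= res.normalized <= 1.0


ORACLES = {
    "rf": oracles.rf_oracle,
    "triples": oracles.triples_oracle,
    "quartet": oracles.quartet_oracle,
    "mast": oracles.mast_oracle,
    "matching_cluster": oracles.matching_cluster_oracle,
    "matching_pair": oracles.matching_pair_oracle,
    "nodal_splitted": oracles.nodal_splitted_oracle,
}

IMPLS = {
    "rf": rf_distance,
    "triples": triples_distance,
    "quartet": quartet_distance,
    "mast": mast_distance,
    "matching_cluster": matching_cluster,
    "matching_pair": matching_pair,
    "nodal_splitted": nodal_splitted,
}


class TestOracleEquivalence:
    """Every metric must agree with an independent brute-force computation
    on random small tree pairs (the acceptance sweep runs 200 pairs; the
    per-metric tests here are a quicker diagnostic slice)."""

    @pytest.mark.parametrize("metric", sorted(ORACLES))
    def test_metric_equals_bruteforce(self, metric):
        for seed in range(25):
            n = 4 + seed % 5  # 4..8 taxa
            t1, t2 = rooted_pair(n, seed=seed)
            got = IMPLS[metric](t1, t2).value
            want = ORACLES[metric](t1, t2)
            assert got == pytest.approx(want), f"{metric} seed={seed} n={n}"

    def test_rf_cross_checked_against_dendropy(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = [f"t{i}" for i in range(8)]
            taxa = dendropy.TaxonNamespace(labels)
            t1 = random_binary_tree(labels, rng, rooted=False)
            t2 = random_binary_tree(labels, rng, rooted=False)
            s1 = parse_newick(t1.as_string(schema="newick"))
            s2 = parse_newick(t2.as_string(schema="newick"))
            d1 = dendropy.Tree.get(data=s1.as_string(schema="newick"),
                                   schema="newick", taxon_namespace=taxa)
            d2 = dendropy.Tree.get(data=s2.as_string(schema="newick"),
                                   schema="newick", taxon_namespace=taxa)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2) / 2
            assert rf_distance(t1, t2).value == expected

    def test_cophenetic_and_path_against_dendropy_pdm(self):
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            labels = [f"t{i}" for i in range(7)]
            t1 = random_binary_tree(labels, rng, rooted=False)
            t2 = random_binary_tree(labels, rng, rooted=False)

            def pdm_vec(tree, weighted):
                pdm = tree.phylogenetic_distance_matrix()
                taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
                out = []
                for i, a in enumerate(taxa):
                    for b in taxa[i + 1:]:
                        if weighted:
                            out.append(pdm.patristic_distance(a, b))
                        else:
                            out.append(pdm.path_edge_count(a, b))
                return np.array(out, dtype=float)

            want_c = float(np.linalg.norm(pdm_vec(t1, True) - pdm_vec(t2, True)))
            want_p = float(np.linalg.norm(pdm_vec(t1, False) - pdm_vec(t2, False)))
            assert cophenetic_l2(t1, t2).value == pytest.approx(want_c)
            assert path_difference(t1, t2).value == pytest.approx(want_p)
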