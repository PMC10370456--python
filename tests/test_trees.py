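import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylorepro.evolve import yule_tree
from phylorepro.trees import (
    MAX_ENUMERABLE_TAXA,
    NewickParseError,
    TaxonSetError,
    Tree,
    TreeError,
    enumerate_topologies,
    n_topologies,
    nni_neighbors,
    parse_newick,
    rf_distance,
    rf_percent,
    same_topology,
    spr_neighbors,
)

from _oracles import brute_force_rf, splits_by_edge_removal


class TestNewick:
    def test_four_taxon_tree_has_five_edges_and_one_split(self):
        t = parse_newick("(A:1,B:1,(C:1,D:1):1);")
        assert t.n_taxa() == 4
        assert len(t.edges()) == 5
        assert len(t.bipartitions()) == 1

    def test_degree_two_root_suppressed_with_lengths_summed(self):
        t = parse_newick("((A:1,B:1):0.5,C:1);")
        assert len(t.root.children) == 3
        lengths = {n.label: n.length for n in t.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 1.5}

    def test_quoted_labels_and_comments(self):
        t = parse_newick("('sp one':1,'sp two'[a comment]:2,(C:1,D:1):1);")
        assert "sp one" in t.taxa and "sp two" in t.taxa

    def test_missing_lengths_use_default(self):
        t = parse_newick("(A,B,(C,D));", default_length=0.25)
        assert all(n.length == 0.25 for n in t.edges())

    @pytest.mark.parametrize("bad", ["", "(((", "(A:1,B:1", "not newick"])
    def test_malformed_input_raises_parse_error(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("(A:1,A:1,(C:1,D:1):1);")

    def test_negative_length_rejected_unless_clamped(self):
        with pytest.raises(TreeError, match="negative"):
            parse_newick("(A:1,B:-0.5,(C:1,D:1):1);")
        t = parse_newick("(A:1,B:-0.5,(C:1,D:1):1);", negative="clamp")
        assert min(n.length for n in t.edges()) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_preserves_topology_and_lengths(self, seed):
        t = yule_tree(16, seed)
        back = parse_newick(t.to_newick())
        assert back.bipartitions() == t.bipartitions()
        orig = sorted((n.label or "", n.length) for n in t.leaves())
        new = sorted((n.label or "", n.length) for n in back.leaves())
        for (la, xa), (lb, xb) in zip(orig, new):
            assert la == lb and math.isclose(xa, xb, rel_tol=1e-9)

    def test_roundtrip_invariant_under_leaf_order_permutation(self):
        a = parse_newick("((A:1,B:2):0.5,(C:1,D:1):0.5,E:2);")
        b = parse_newick("(E:2,(D:1,C:1):0.5,(B:2,A:1):0.5);")
        assert a.bipartitions() == b.bipartitions()
        assert a.topology_id() == b.topology_id()


class TestBipartitions:
    def test_star_tree_has_no_nontrivial_splits(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert t.bipartitions() == frozenset()

    @pytest.mark.parametrize("m", [5, 8, 12, 142])
    def test_fully_resolved_tree_has_m_minus_3_splits(self, m):
        t = yule_tree(m, seed=m)
        assert len(t.bipartitions()) == m - 3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_masks_agree_with_explicit_edge_removal(self, seed):
        t = yule_tree(8, seed)
        assert len(t.bipartitions()) == len(splits_by_edge_removal(t))


class TestRFDistance:
    def test_zero_iff_same_topology(self):
        t = yule_tree(10, seed=3)
        assert rf_distance(t, t) == 0
        assert same_topology(t, t.copy())

    def test_branch_length_changes_do_not_affect_topology_identity(self):
        t = yule_tree(8, seed=4)
        t2 = t.copy()
        for n in t2.edges():
            n.length *= 3.7
        assert same_topology(t, t2)
        assert rf_percent(t, t2) == 0.0

    def test_nni_neighbor_differs_in_exactly_one_split(self):
        t = yule_tree(8, seed=5)
        for nb in nni_neighbors(t):
            assert rf_distance(t, nb) == 2
            assert not same_topology(t, nb)

    def test_maximally_different_trees_hit_the_formula_ceiling(self):
        a = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(a, b) == 2 * (4 - 3)
        assert rf_percent(a, b) == 100.0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_symmetric_difference(self, seed):
        rng = np.random.default_rng(seed)
        t1 = yule_tree(8, int(rng.integers(1 << 30)))
        t2 = yule_tree(8, int(rng.integers(1 << 30)))
        assert rf_distance(t1, t2) == brute_force_rf(t1, t2)

    @pytest.mark.parametrize("seed", range(15))
    def test_is_a_metric_on_random_triples(self, seed):
        rng = np.random.default_rng(1000 + seed)
        a, b, c = (yule_tree(8, int(rng.integers(1 << 30))) for _ in range(3))
        assert rf_distance(a, b) == rf_distance(b, a)
        assert (rf_distance(a, b) == 0) == same_topology(a, b)
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)

    def test_taxon_mismatch_error_names_missing_labels(self):
        a = parse_newick("(A:1,B:1,(C:1,D:1):1);")
        b = parse_newick("(A:1,B:1,(C:1,E:1):1);")
        with pytest.raises(TaxonSetError, match="E"):
            rf_distance(a, b)

    def test_percent_formula_against_direct_arithmetic(self):
        m = 142
        t = yule_tree(m, seed=7)
        nb = t
        for tree in nni_neighbors(t):
            nb = tree
            break
        d = rf_distance(t, nb)
        assert rf_percent(t, nb) == pytest.approx(d / (2 * (m - 3)) * 100)

    def test_percent_requires_four_taxa_and_resolution(self):
        a = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="m="):
            rf_percent(a, a)
        star = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        resolved = yule_tree(5, seed=8, labels=["A", "B", "C", "D", "E"])
        assert rf_distance(star, resolved) == 2  # multifurcations allowed
        with pytest.raises(TreeError, match="resolved"):
            rf_percent(star, resolved)

    def test_agrees_with_dendropy_on_random_pairs(self):
        # independent cross-check against an established implementation
        for seed in range(10):
            t1 = yule_tree(10, seed)
            t2 = yule_tree(10, seed + 500)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == expected


class TestEnumeration:
    @pytest.mark.parametrize("m,count", [(3, 1), (4, 3), (5, 15), (6, 105),
                                         (7, 945)])
    def test_counts_match_double_factorial(self, m, count):
        taxa = [f"t{i}" for i in range(m)]
        topologies = list(enumerate_topologies(taxa))
        assert len(topologies) == count == n_topologies(m)
        keys = {t.topology_id() for t in topologies}
        assert len(keys) == count  # each exactly once

    def test_refuses_beyond_the_guard(self):
        taxa = [f"t{i}" for i in range(MAX_ENUMERABLE_TAXA + 1)]
        with pytest.raises(TreeError, match=str(MAX_ENUMERABLE_TAXA)):
            next(enumerate_topologies(taxa))


class TestMoves:
    @pytest.mark.parametrize("m", [5, 8, 12])
    def test_nni_neighborhood_size_is_2m_minus_6(self, m):
        t = yule_tree(m, seed=m + 40)
        neighbors = list(nni_neighbors(t))
        assert len(neighbors) == 2 * (m - 3)
        ids = {n.topology_id() for n in neighbors}
        assert len(ids) == len(neighbors)

    def test_spr_neighbors_are_valid_and_go_beyond_nni(self):
        t = yule_tree(7, seed=77)
        nni_ids = {n.topology_id() for n in nni_neighbors(t)}
        spr_ids = set()
        for nb in spr_neighbors(t):
            assert nb.taxa == t.taxa
            assert nb.is_binary()
            spr_ids.add(nb.topology_id())
        assert t.topology_id() not in spr_ids
        assert spr_ids - nni_ids  # SPR reaches strictly more topologies
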