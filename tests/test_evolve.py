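import math

import numpy as np
import pytest

from phylorepro.evolve import (
    RateModel,
    SimDesign,
    assign_autocorrelated_rates,
    derive_seed,
    gc_to_freqs,
    generate_model_tree,
    hundred_like_design,
    ladder_design,
    make_collection,
    phylo_information,
    simulate_alignment,
    yule_tree,
)
from phylorepro.models import hky, jc
from phylorepro.trees import enumerate_topologies, parse_newick

from _oracles import jc_expected_p


class TestModelTrees:
    def test_lengths_rescaled_to_target_exactly(self):
        t = generate_model_tree(4, 1.0, seed=1)
        assert t.tree_length() == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_reproduces_the_tree(self):
        a = generate_model_tree(9, 0.7, seed=5)
        b = generate_model_tree(9, 0.7, seed=5)
        assert a.to_newick() == b.to_newick()

    def test_yule_covers_all_six_taxon_topologies(self):
        expected = {t.topology_id()
                    for t in enumerate_topologies([f"t{i+1}" for i in range(6)])}
        seen = set()
        for seed in range(1000):
            seen.add(yule_tree(6, seed, labels=[f"t{i+1}" for i in range(6)])
                     .topology_id())
        assert seen == expected

    def test_rejects_degenerate_requests(self):
        with pytest.raises(ValueError):
            generate_model_tree(3, 1.0, seed=1)
        with pytest.raises(ValueError):
            generate_model_tree(6, 0.0, seed=1)


class TestRateModels:
    def test_strict_model_scales_uniformly(self):
        t = yule_tree(8, seed=2)
        out = assign_autocorrelated_rates(t, RateModel(kind="strict",
                                                       initial_rate=2e-9), 7)
        for a, b in zip(t.edges(), out.edges()):
            assert b.length == pytest.approx(a.length * 2e-9)

    def test_zero_variance_limit_equals_strict(self):
        t = yule_tree(8, seed=3)
        auto = assign_autocorrelated_rates(
            t, RateModel(kind="autocorrelated", initial_rate=1e-9,
                         autocorrelation_variance=0.0), 7)
        strict = assign_autocorrelated_rates(
            t, RateModel(kind="strict", initial_rate=1e-9), 7)
        for a, b in zip(auto.edges(), strict.edges()):
            assert a.length == pytest.approx(b.length)

    def test_parent_child_rates_are_positively_correlated(self):
        rm = RateModel(kind="autocorrelated", initial_rate=1.0,
                       autocorrelation_variance=0.5)
        parent_mult, child_mult = [], []
        for seed in range(250):
            t = yule_tree(10, seed=seed)
            out = assign_autocorrelated_rates(t, rm, seed)
            ratio = {}
            for a, b in zip(t.edges(), out.edges()):
                ratio[id(a)] = b.length / a.length if a.length > 0 else 1.0
            for a, b in zip(t.edges(), out.edges()):
                if a.parent is not None and id(a.parent) in ratio:
                    parent_mult.append(math.log(ratio[id(a.parent)]))
                    child_mult.append(math.log(ratio[id(a)]))
        r = np.corrcoef(parent_mult, child_mult)[0, 1]
        assert r > 0.3

    def test_invalid_rate_model_rejected(self):
        with pytest.raises(ValueError):
            RateModel(kind="clock-ish")
        with pytest.raises(ValueError):
            RateModel(autocorrelation_variance=-1.0)


class TestSequenceSimulation:
    def test_zero_length_tree_copies_the_root_state(self):
        t = parse_newick("(a:0,b:0,c:0,d:0);")
        aln = simulate_alignment(t, jc(), 200, seed=4)
        seqs = {aln.sequence(x) for x in aln.taxa}
        assert len(seqs) == 1

    def test_same_seed_same_alignment(self):
        t = generate_model_tree(6, 1.0, seed=5)
        m = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        a = simulate_alignment(t, m, 500, seed=6)
        b = simulate_alignment(t, m, 500, seed=6)
        assert a.fasta_str() == b.fasta_str()

    def test_saturated_branch_decouples_endpoint_states(self):
        model = hky(2.0, (0.1, 0.2, 0.3, 0.4))
        t = parse_newick("(a:5,b:5);")
        aln = simulate_alignment(t, model, 100_000, seed=7)
        codes = aln.matrix(("a", "b"))
        joint = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                joint[i, j] = ((codes[0] == i) & (codes[1] == j)).mean()
        outer = np.outer(model.pi, model.pi)
        assert np.abs(joint - outer).max() < 0.01

    def test_jc_substitution_process_matches_closed_form(self):
        d = 0.4
        t = parse_newick(f"(a:{d / 2},b:{d / 2});")
        aln = simulate_alignment(t, jc(), 100_000, seed=8)
        codes = aln.matrix(("a", "b"))
        p_obs = (codes[0] != codes[1]).mean()
        assert p_obs == pytest.approx(jc_expected_p(d), abs=0.01)

    def test_base_composition_converges_to_pi(self):
        model = hky(1.8, gc_to_freqs(0.7))
        t = generate_model_tree(6, 2.0, seed=9)
        aln = simulate_alignment(t, model, 100_000, seed=10)
        assert np.abs(aln.base_frequencies() - model.pi).max() < 0.01


class TestInformation:
    def test_product_and_zero_cases(self):
        t = generate_model_tree(6, 2.0, seed=11)
        assert phylo_information(t, 1000) == pytest.approx(2000.0)
        assert phylo_information(t, 0) == 0.0

    def test_invariant_under_serialization_roundtrip(self):
        t = generate_model_tree(8, 1.3, seed=12)
        back = parse_newick(t.to_newick(precision=17))
        assert phylo_information(back, 777) == pytest.approx(
            phylo_information(t, 777))


class TestCollections:
    def test_hundred_like_schema_and_ranges(self):
        design = hundred_like_design(master_seed=3, n_datasets=12)
        col = make_collection(design)
        assert len(col) == 12
        assert len({ds.seed for ds in col}) == 12
        for ds in col:
            assert ds.alignment.n_taxa() == 16
            assert 258 <= ds.alignment.length <= 2000
            assert 1.35 <= ds.params["kappa"] <= 2.6
            assert 0.39 <= ds.params["gc"] <= 0.82
            assert 0.05 <= ds.params["tree_length"] <= 0.3
            assert ds.model.kind == "HKY"

    def test_ladder_information_strictly_ordered_across_levels(self):
        design = ladder_design(master_seed=4, n_levels=3, per_level=4)
        col = make_collection(design)
        assert len(col) == 12
        by_level = {}
        for ds in col:
            by_level.setdefault(ds.level, []).append(ds.information)
        means = [np.mean(by_level[k]) for k in sorted(by_level)]
        assert means[0] < means[1] < means[2]
        assert all(ds.model.kind == "GTR" and ds.model.gamma_shape == 1.0
                   for ds in col)

    def test_master_seed_reproduces_byte_identical_data(self):
        d = hundred_like_design(master_seed=5, n_datasets=3)
        a = make_collection(d)
        b = make_collection(d)
        assert all(x.alignment.fasta_str() == y.alignment.fasta_str()
                   for x, y in zip(a, b))
        assert all(x.true_tree.to_newick() == y.true_tree.to_newick()
                   for x, y in zip(a, b))

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            SimDesign(length_range=(500, 100))
        with pytest.raises(ValueError):
            SimDesign(n_taxa=3)

    def test_derived_seeds_are_stable_and_bounded(self):
        s1 = derive_seed(42, 7)
        assert s1 == derive_seed(42, 7)
        assert 0 <= s1 < 2 ** 31
        assert derive_seed(42, 8) != s1
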