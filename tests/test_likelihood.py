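import math

import numpy as np
import pytest

from phylorepro.alignment import Alignment
from phylorepro.evolve import generate_model_tree, simulate_alignment
from phylorepro.likelihood import (
    TreeLikelihood,
    estimate_model_params,
    log_likelihood,
    optimize_branch_lengths,
)
from phylorepro.models import gtr, hky, jc
from phylorepro.trees import TreeError, parse_newick

from _oracles import brute_force_log_likelihood, jc_pairwise_mle


class TestPruning:
    def test_single_constant_site_on_zero_star_is_log_quarter(self):
        tree = parse_newick("(a:0,b:0,c:0,d:0);")
        aln = Alignment([(t, "A") for t in "abcd"])
        res = log_likelihood(tree, aln, jc())
        assert res.log_likelihood == pytest.approx(math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("seed,model", [
        (1, hky(2.0, (0.3, 0.2, 0.2, 0.3))),
        (2, hky(1.35, (0.09, 0.41, 0.41, 0.09), gamma_shape=1.0)),
        (3, gtr((1.5, 2.0, 0.7, 1.2, 3.1, 1.0), (0.2, 0.3, 0.3, 0.2),
                gamma_shape=0.5)),
    ])
    def test_matches_bruteforce_marginalization(self, seed, model):
        tree = generate_model_tree(5, 1.2, seed=seed)
        aln = simulate_alignment(tree, model, 40, seed=seed + 10)
        got = log_likelihood(tree, aln, model).log_likelihood
        expected = brute_force_log_likelihood(tree, aln, model)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_two_taxon_jc_closed_form(self):
        d = 0.3
        tree = parse_newick(f"(a:{d / 2},b:{d / 2});")
        aln = Alignment([("a", "AACGTTGCAC"), ("b", "AACGATGCAG")])
        p_same = 0.25 + 0.75 * math.exp(-4 * d / 3)
        p_diff = (1 - p_same) / 4 / 3 * 4  # per specific different base
        n_diff = sum(x != y for x, y in zip("AACGTTGCAC", "AACGATGCAG"))
        n_same = 10 - n_diff
        expected = (n_same * math.log(0.25 * p_same)
                    + n_diff * math.log(0.25 * (1 - p_same) / 3))
        got = log_likelihood(tree, aln, jc()).log_likelihood
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_newick_rooting_and_rotation(self):
        model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        tree = generate_model_tree(6, 1.0, seed=4)
        aln = simulate_alignment(tree, model, 300, seed=5)
        ll = log_likelihood(tree, aln, model).log_likelihood
        ll2 = log_likelihood(parse_newick(tree.to_newick(precision=17)), aln,
                             model).log_likelihood
        assert ll2 == pytest.approx(ll, abs=1e-9)

    def test_pattern_compression_is_exact(self):
        model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        tree = generate_model_tree(5, 1.0, seed=6)
        aln = simulate_alignment(tree, model, 60, seed=7)
        doubled = Alignment(
            [(t, aln.sequence(t) + aln.sequence(t)) for t in aln.taxa])
        ll = log_likelihood(tree, aln, model).log_likelihood
        ll2 = log_likelihood(tree, doubled, model).log_likelihood
        assert ll2 == pytest.approx(2 * ll, abs=1e-10)

    def test_loglikelihood_is_negative_and_taxa_checked(self):
        model = jc()
        tree = generate_model_tree(5, 1.0, seed=8)
        aln = simulate_alignment(tree, model, 100, seed=9)
        assert log_likelihood(tree, aln, model).log_likelihood < 0
        other = Alignment([(f"x{i}", "ACGT") for i in range(5)])
        with pytest.raises(TreeError, match="taxa"):
            log_likelihood(tree, other, model)

    def test_edge_likelihood_consistent_from_every_edge(self):
        model = hky(2.0, (0.3, 0.2, 0.2, 0.3), gamma_shape=1.0)
        tree = generate_model_tree(7, 1.0, seed=10)
        aln = simulate_alignment(tree, model, 200, seed=11)
        eng = TreeLikelihood(aln, model)
        ll = eng.log_likelihood(tree).log_likelihood
        partials = eng.compute_partials(tree)
        for v in tree.edges():
            upv, dv, sc = eng._edge_ll_terms(v, partials)
            assert eng._edge_ll(v.length, upv, dv, sc) == pytest.approx(
                ll, abs=1e-8)


class TestBranchOptimization:
    def test_two_taxon_mle_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n, n_diff = 500, 60
        seq_a = "".join(rng.choice(list("ACGT"), n))
        seq_b = list(seq_a)
        for i in range(n_diff):  # mutate first n_diff sites to a different base
            seq_b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq_b[i]]
        aln = Alignment([("a", seq_a), ("b", "".join(seq_b))])
        tree = parse_newick("(a:0.05,b:0.05);")
        t_opt, res = optimize_branch_lengths(tree, aln, jc())
        total = sum(n.length for n in t_opt.edges())
        assert total == pytest.approx(jc_pairwise_mle(n_diff / n), rel=1e-3)

    def test_sweep_trace_is_monotone_nondecreasing(self):
        model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        tree = generate_model_tree(8, 1.0, seed=12)
        aln = simulate_alignment(tree, model, 300, seed=13)
        _, res = optimize_branch_lengths(tree, aln, model)
        t = res.sweep_log_likelihoods
        assert all(b >= a for a, b in zip(t, t[1:]))
        assert res.log_likelihood == t[-1]

    def test_optimal_input_is_a_fixed_point(self):
        model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        tree = generate_model_tree(6, 1.0, seed=14)
        aln = simulate_alignment(tree, model, 500, seed=15)
        t1, r1 = optimize_branch_lengths(tree, aln, model)
        t2, r2 = optimize_branch_lengths(t1, aln, model)
        assert r2.log_likelihood == pytest.approx(r1.log_likelihood, abs=1e-3)
        for a, b in zip(t1.edges(), t2.edges()):
            assert b.length == pytest.approx(a.length, abs=1e-3)

    def test_epsilon_must_be_positive_and_bounds_respected(self):
        model = jc()
        tree = generate_model_tree(5, 1.0, seed=16)
        aln = simulate_alignment(tree, model, 100, seed=17)
        with pytest.raises(ValueError):
            optimize_branch_lengths(tree, aln, model, epsilon=0)
        t_opt, _ = optimize_branch_lengths(tree, aln, model)
        for n in t_opt.edges():
            assert 1e-8 <= n.length <= 10.0


class TestModelEstimation:
    def test_kappa_recovery_within_five_percent(self):
        true_model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        tree = generate_model_tree(8, 1.5, seed=18)
        aln = simulate_alignment(tree, true_model, 50_000, seed=19)
        start = hky(5.0, (0.3, 0.2, 0.2, 0.3))
        est = estimate_model_params(tree, aln, start, free=("kappa",))
        assert est.kappa == pytest.approx(2.0, rel=0.05)

    def test_empirical_frequencies_adopted(self):
        aln = Alignment([("a", "AAAACCGT"), ("b", "AAAACCGT")])
        tree = parse_newick("(a:0.01,b:0.01);")
        est = estimate_model_params(tree, aln, jc(), free=(),
                                    use_empirical_freqs=True)
        assert np.allclose(est.pi, aln.base_frequencies())

    def test_nothing_free_returns_template(self):
        model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = Alignment([("a", "ACGT"), ("b", "ACGT")])
        assert estimate_model_params(tree, aln, model, free=()) is model
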