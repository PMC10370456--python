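import numpy as np
import pytest

from phylorepro.evolve import generate_model_tree, simulate_alignment
from phylorepro.forest import (
    ForestMember,
    ForestRecord,
    breadth_vs_information,
    build_forest,
    forest_breadth,
    inaccuracy_ll_regression,
)
from phylorepro.likelihood import TreeLikelihood
from phylorepro.models import hky
from phylorepro.search import SearchConfig, heuristic_search
from phylorepro.trees import same_topology

from _oracles import ols_3point


@pytest.fixture(scope="module")
def weak_forest():
    """Forest on a low-information 10-taxon data set."""
    model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
    true = generate_model_tree(10, 0.15, seed=61)
    aln = simulate_alignment(true, model, 200, seed=62)
    rec = build_forest(aln, model, true, n_starts=6, seed=63)
    return true, aln, model, rec


def _member(i, dll, rf):
    return ForestMember(topology_id=f"m{i}", newick="", log_likelihood=-100 + dll,
                        delta_ll=dll, rf_percent_to_true=rf)


class TestBuildForest:
    def test_members_strictly_beat_the_true_tree(self, weak_forest):
        true, aln, model, rec = weak_forest
        eng = TreeLikelihood(aln, model)
        for m in rec.members:
            assert m.log_likelihood > rec.true_ll
            assert m.delta_ll == pytest.approx(m.log_likelihood - rec.true_ll)

    def test_members_are_distinct_and_exclude_the_truth(self, weak_forest):
        true, _, _, rec = weak_forest
        ids = [m.topology_id for m in rec.members]
        assert len(set(ids)) == len(ids)
        assert true.topology_id() not in ids

    def test_weak_data_usually_grow_a_forest(self, weak_forest):
        _, _, _, rec = weak_forest
        assert rec.n_distinct >= 1
        assert rec.breadth is not None and rec.breadth > 0

    def test_best_member_agrees_with_heuristic_search_when_it_beats_truth(
            self, weak_forest):
        true, aln, model, rec = weak_forest
        res = heuristic_search(aln, model, SearchConfig(seed=63, n_starts=3))
        if res.best_ll > rec.true_ll and rec.members:
            assert rec.members[0].log_likelihood >= res.best_ll - 1e-3

    def test_more_starts_never_shrink_the_forest(self):
        model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        true = generate_model_tree(8, 0.15, seed=71)
        aln = simulate_alignment(true, model, 150, seed=72)
        small = build_forest(aln, model, true, n_starts=2, seed=5)
        large = build_forest(aln, model, true, n_starts=4, seed=5)
        assert large.n_distinct >= small.n_distinct
        if small.breadth is not None:
            assert large.breadth is not None
            assert large.breadth >= small.breadth - 1e-9

    def test_screen_margin_never_adds_members(self):
        model = hky(2.0, (0.3, 0.2, 0.2, 0.3))
        true = generate_model_tree(8, 0.15, seed=81)
        aln = simulate_alignment(true, model, 150, seed=82)
        exact = build_forest(aln, model, true, n_starts=3, seed=6)
        screened = build_forest(aln, model, true, n_starts=3, seed=6,
                                screen_margin=2.0)
        exact_ids = {m.topology_id for m in exact.members}
        screened_ids = {m.topology_id for m in screened.members}
        assert screened_ids <= exact_ids


class TestBreadth:
    def test_single_member_breadth(self):
        rec = ForestRecord("d", true_ll=-100.0, members=[_member(0, 5.0, 10.0)])
        assert forest_breadth(rec) == pytest.approx(5.0)

    def test_empty_forest_breadth_is_absent(self):
        rec = ForestRecord("d", true_ll=-100.0)
        assert forest_breadth(rec) is None

    def test_equals_independent_scan(self):
        members = [_member(i, dll, 10.0) for i, dll in enumerate([1.0, 7.5, 3.0])]
        rec = ForestRecord("d", true_ll=-100.0, members=members)
        assert forest_breadth(rec) == max(m.delta_ll for m in members)


class TestRegression:
    def test_identical_inaccuracies_give_flat_slope(self):
        members = [_member(i, d, 25.0) for i, d in enumerate([1.0, 2.0, 3.0])]
        rec = ForestRecord("d", true_ll=-100.0, members=members)
        slope, intercept, r = inaccuracy_ll_regression(rec)
        assert slope == 0.0 and intercept == 25.0 and r is None

    def test_three_point_ols_matches_closed_form(self):
        x, y = [1.0, 2.0, 4.0], [10.0, 14.0, 13.0]
        members = [_member(i, xi, yi) for i, (xi, yi) in enumerate(zip(x, y))]
        rec = ForestRecord("d", true_ll=-100.0, members=members)
        slope, intercept, r = inaccuracy_ll_regression(rec)
        exp_slope, exp_intercept = ols_3point(x, y)
        assert slope == pytest.approx(exp_slope)
        assert intercept == pytest.approx(exp_intercept)

    def test_order_invariant(self):
        members = [_member(i, xi, yi) for i, (xi, yi) in
                   enumerate([(1, 5), (2, 9), (3, 6), (4, 12)])]
        a = inaccuracy_ll_regression(ForestRecord("d", -1.0, members))
        b = inaccuracy_ll_regression(
            ForestRecord("d", -1.0, list(reversed(members))))
        assert a == pytest.approx(b)

    def test_too_few_members_refused(self):
        rec = ForestRecord("d", -1.0, [_member(0, 1.0, 5.0)])
        with pytest.raises(ValueError):
            inaccuracy_ll_regression(rec)


class TestBreadthVsInformation:
    def _records(self):
        recs = []
        for level, (info, breadth) in enumerate([(100, 8.0), (1000, 3.0),
                                                 (10000, 0.0)]):
            for i in range(5):
                members = ([_member(0, breadth, 10.0)] if breadth > 0 else [])
                r = ForestRecord(f"d{level}-{i}", true_ll=-50.0,
                                 members=members)
                r.information = info * (1 + 0.01 * i)
                r.level = level
                recs.append(r)
        return recs

    def test_monotone_decreasing_breadth_gives_spearman_minus_one(self):
        table = breadth_vs_information(self._records())
        assert len(table) == 3
        assert table.attrs["spearman_rho"] < -0.9
        assert (np.diff(table.mean_breadth.values) <= 0).all()

    def test_empty_forests_count_as_zero_in_level_means(self):
        table = breadth_vs_information(self._records())
        assert table.mean_breadth.iloc[-1] == 0.0

    def test_single_level_refused(self):
        recs = [r for r in self._records() if r.level == 0]
        with pytest.raises(ValueError):
            breadth_vs_information(recs)
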