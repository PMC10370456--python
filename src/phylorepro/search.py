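"""Seeded heuristic maximum-likelihood tree search, plus an exhaustive oracle.

The search is deliberately an *independent, desk-scale* ML engine: multiple
starting trees (stepwise addition under random taxon orders, and neighbor
joining on bootstrap-resampled sites), greedy NNI hill climbing with
best-improvement acceptance, and full branch-length re-optimization of
accepted moves.  The random seed controls starting trees and candidate
tie-breaking, and fully determines the outcome for fixed inputs — which is
exactly the property whose consequences this package studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from io import StringIO

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .alignment import Alignment
from .evolve import derive_seed
from .likelihood import DEFAULT_EPSILON, TreeLikelihood
from .models import SubstModel
from .trees import (
    Tree,
    TreeError,
    _node_path,
    _resolve_path,
    _swap_subtrees,
    enumerate_topologies,
    parse_newick,
    spr_neighbors,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "TraceEntry",
    "starting_trees",
    "hill_climb",
    "heuristic_search",
    "exhaustive_search",
    "exhaustive_scores",
]

MAX_EXHAUSTIVE_TAXA = 8


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of one heuristic search run.

    The seed fully determines the run for fixed data.  ``epsilon`` is the
    log-likelihood improvement threshold both for accepting a topological
    move and for branch-length convergence (default 0.0001).  ``refine_k``
    bounds how many top-ranked screened candidates are fully re-optimized
    per step before the search declares a local optimum.
    """

    seed: int = 111
    n_starts: int = 3
    moves: tuple[str, ...] = ("nni",)
    epsilon: float = DEFAULT_EPSILON
    retain_trace: bool = False
    initial_tree: Tree | None = None
    max_iterations: int = 200
    refine_k: int = 3
    max_sweeps: int = 60

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        bad = set(self.moves) - {"nni", "spr"}
        if bad:
            raise ValueError(f"unknown move types: {sorted(bad)}")


@dataclass
class TraceEntry:
    """One topology evaluated during the search."""

    newick: str
    topology_id: str
    log_likelihood: float
    accepted: bool
    refined: bool
    kind: str  # "start" | "nni" | "spr"
    start_index: int


@dataclass
class SearchResult:
    """Outcome of a (multi-start) heuristic search."""

    best_tree: Tree
    best_ll: float
    seed: int
    n_topologies_evaluated: int
    trace: list[TraceEntry] = field(default_factory=list)
    capped: bool = False
    start_lls: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------- #
# starting trees


def _jc_distance_matrix(aln: Alignment) -> np.ndarray:
    mat = aln.matrix()
    acgt = mat < 4  # codes 0..3 are unambiguous A,C,G,T
    m = aln.n_taxa()
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = acgt[i] & acgt[j]
            n_ok = int(ok.sum())
            if n_ok == 0:
                d = 5.0
            else:
                p = float((mat[i, ok] != mat[j, ok]).mean())
                if p >= 0.74:
                    d = 5.0  # saturation guard for the JC correction
                else:
                    d = max(0.0, -0.75 * np.log(1.0 - 4.0 * p / 3.0))
            D[i, j] = D[j, i] = d
    return D


def _nj_tree(aln: Alignment) -> Tree:
    dm = DistanceMatrix(_jc_distance_matrix(aln), ids=list(aln.taxa))
    sk = nj(dm)
    buf = StringIO()
    sk.write(buf, format="newick")
    return parse_newick(buf.getvalue(), negative="clamp")


def _stepwise_tree(engine: TreeLikelihood, rng: np.random.Generator,
                   init_length: float = 0.05) -> Tree:
    """Stepwise-addition tree under a random taxon order, each insertion
    scored by the full log-likelihood at unoptimized branch lengths."""
    taxa = list(engine.taxa)
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    from .trees import Node

    root = Node()
    for lab in order[:3]:
        root.add_child(Node(lab, init_length))
    tree = Tree(root)
    for k, lab in enumerate(order[3:], start=4):
        sub_aln = Alignment(
            (t, engine.alignment.sequence(t)) for t in sorted(order[:k])
        )
        sub_engine = TreeLikelihood(sub_aln, engine.model)
        best = None
        n_edges = len(tree.edges())
        for e in range(n_edges):
            cand = tree.copy()
            edge_node = cand.edges()[e]
            parent = edge_node.parent
            mid = Node(None, edge_node.length / 2.0)
            parent.children[parent.children.index(edge_node)] = mid
            mid.parent = parent
            edge_node.length /= 2.0
            mid.add_child(edge_node)
            mid.add_child(Node(lab, init_length))
            cand = Tree(cand.root)
            ll = sub_engine.log_likelihood(cand).log_likelihood
            if best is None or ll > best[0]:
                best = (ll, cand)
        tree = best[1]
    return tree


def starting_trees(aln: Alignment, model: SubstModel, n: int,
                   seed: int) -> list[Tree]:
    """Deterministic list of ``n`` starting trees for a given seed.

    Alternates stepwise-addition trees under random taxon orders with
    neighbor-joining trees built from bootstrap-resampled site columns —
    the two standard sources of good-but-variable initial topologies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    engine = TreeLikelihood(aln, model)
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        if k % 2 == 0:
            out.append(_stepwise_tree(engine, rng))
        else:
            boot = aln.bootstrap(rng)
            out.append(_nj_tree(boot))
    return out


# ---------------------------------------------------------------------- #
# hill climbing


def _apply_nni(tree: Tree, cand: dict) -> Tree:
    t2 = tree.copy()
    v = _resolve_path(t2, cand["edge_path"])
    c = _resolve_path(t2, cand["swap_child_path"])
    s = _resolve_path(t2, cand["swap_sibling_path"])
    _swap_subtrees(v, c, v.parent, s)
    v.length = cand["t_opt"]
    return t2


def hill_climb(start: Tree, aln: Alignment, model: SubstModel,
               cfg: SearchConfig, *, engine: TreeLikelihood | None = None,
               rng: np.random.Generator | None = None,
               start_index: int = 0) -> SearchResult:
    """Greedy best-improvement NNI (optionally SPR) hill climb from ``start``.

    Each step screens every neighbor with a quick score (cached partials,
    central edge re-optimized), ranks candidates under a seed-shuffled
    order, fully re-optimizes the top ``refine_k``, and accepts the first
    that improves the log-likelihood by more than ``epsilon``.  Terminates
    at a local optimum or at ``max_iterations`` (flagged ``capped``).
    """
    engine = engine or TreeLikelihood(aln, model)
    rng = rng or np.random.default_rng(cfg.seed)
    tree, res = engine.optimize_branch_lengths(
        start, epsilon=cfg.epsilon, max_sweeps=cfg.max_sweeps,
        warn_on_cap=False,
    )
    cur_ll = res.log_likelihood
    trace: list[TraceEntry] = []
    n_evaluated = 1
    if cfg.retain_trace:
        trace.append(TraceEntry(
            newick=tree.to_newick(), topology_id=tree.topology_id(),
            log_likelihood=cur_ll, accepted=True, refined=True,
            kind="start", start_index=start_index,
        ))
    capped = True
    for _ in range(cfg.max_iterations):
        cands = engine.screen_nni(tree)
        for c in cands:
            c["kind"] = "nni"
        if "spr" in cfg.moves:
            for nb in spr_neighbors(tree):
                cands.append({
                    "tree": nb,
                    "screened_ll": engine.log_likelihood(nb).log_likelihood,
                    "kind": "spr",
                })
        order = rng.permutation(len(cands))
        cands = [cands[i] for i in order]
        cands.sort(key=lambda c: -c["screened_ll"])
        n_evaluated += len(cands)

        cand_trees: dict[int, Tree] = {}
        if cfg.retain_trace:
            for i, c in enumerate(cands):
                t = c.get("tree") or _apply_nni(tree, c)
                cand_trees[i] = t
                trace.append(TraceEntry(
                    newick=t.to_newick(), topology_id=t.topology_id(),
                    log_likelihood=c["screened_ll"], accepted=False,
                    refined=False, kind=c["kind"], start_index=start_index,
                ))

        accepted = False
        for i, c in enumerate(cands[:max(1, cfg.refine_k)]):
            t = cand_trees.get(i) or c.get("tree") or _apply_nni(tree, c)
            t_opt, r = engine.optimize_branch_lengths(
                t, epsilon=cfg.epsilon, max_sweeps=cfg.max_sweeps,
                warn_on_cap=False,
            )
            if cfg.retain_trace:
                trace.append(TraceEntry(
                    newick=t_opt.to_newick(), topology_id=t_opt.topology_id(),
                    log_likelihood=r.log_likelihood,
                    accepted=r.log_likelihood > cur_ll + cfg.epsilon,
                    refined=True, kind=c["kind"], start_index=start_index,
                ))
            if r.log_likelihood > cur_ll + cfg.epsilon:
                tree, cur_ll = t_opt, r.log_likelihood
                accepted = True
                break
        if not accepted:
            capped = False
            break
    if capped:
        warnings.warn(
            f"hill climb hit max_iterations={cfg.max_iterations}",
            RuntimeWarning,
        )
    return SearchResult(
        best_tree=tree, best_ll=cur_ll, seed=cfg.seed,
        n_topologies_evaluated=n_evaluated, trace=trace, capped=capped,
        start_lls=[res.log_likelihood],
    )


def heuristic_search(aln: Alignment, model: SubstModel,
                     cfg: SearchConfig) -> SearchResult:
    """Multi-start heuristic ML search; the package's tree-inference engine.

    Runs ``n_starts`` hill climbs (from generated starting trees, or from
    ``cfg.initial_tree`` plus perturbed variants when one is supplied) and
    returns the best local optimum, with merged traces when retained.
    Identical inputs and seed give identical output.
    """
    engine = TreeLikelihood(aln, model)
    rng = np.random.default_rng(cfg.seed)
    if cfg.initial_tree is not None:
        # the supplied tree augments, not replaces, the normal search
        # effort: its neighborhood is explored by one climb while the
        # remaining starts are generated as usual
        starts = [cfg.initial_tree]
        if cfg.n_starts > 1:
            starts += starting_trees(aln, model, cfg.n_starts - 1,
                                     seed=derive_seed(cfg.seed, 17))
    else:
        starts = starting_trees(aln, model, cfg.n_starts,
                                seed=derive_seed(cfg.seed, 17))
    best: SearchResult | None = None
    all_trace: list[TraceEntry] = []
    n_eval = 0
    start_lls = []
    for idx, s in enumerate(starts):
        res = hill_climb(s, aln, model, cfg, engine=engine, rng=rng,
                         start_index=idx)
        n_eval += res.n_topologies_evaluated
        all_trace.extend(res.trace)
        start_lls.extend(res.start_lls)
        if (best is None or res.best_ll > best.best_ll
                or (res.best_ll == best.best_ll
                    and res.best_tree.topology_id() < best.best_tree.topology_id())):
            best = res
    return SearchResult(
        best_tree=best.best_tree, best_ll=best.best_ll, seed=cfg.seed,
        n_topologies_evaluated=n_eval, trace=all_trace,
        capped=best.capped, start_lls=start_lls,
    )


# ---------------------------------------------------------------------- #
# exhaustive oracle


def exhaustive_scores(aln: Alignment, model: SubstModel,
                      epsilon: float = DEFAULT_EPSILON):
    """Yield (tree, optimized log-likelihood) for every topology (m <= 8)."""
    if aln.n_taxa() > MAX_EXHAUSTIVE_TAXA:
        raise TreeError(
            f"exhaustive search refused for m={aln.n_taxa()} > "
            f"{MAX_EXHAUSTIVE_TAXA} taxa"
        )
    engine = TreeLikelihood(aln, model)
    for topo in enumerate_topologies(sorted(aln.taxa)):
        t_opt, res = engine.optimize_branch_lengths(topo, epsilon=epsilon)
        yield t_opt, res.log_likelihood


def exhaustive_search(aln: Alignment, model: SubstModel,
                      epsilon: float = DEFAULT_EPSILON) -> tuple[Tree, float]:
    """Global ML tree by scoring every topology; deterministic, seed-free.

    Ties (to within 1e-10) break on the canonical topology id.
    """
    best = None
    for t_opt, ll in exhaustive_scores(aln, model, epsilon=epsilon):
        key = (ll, t_opt.topology_id())
        if best is None or ll > best[1] + 1e-10 or (
                abs(ll - best[1]) <= 1e-10
                and t_opt.topology_id() < best[0].topology_id()):
            best = (t_opt, ll)
    return best
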