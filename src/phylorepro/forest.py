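"""The optimality forest: topologies whose likelihood beats the true tree's.

For a given alignment, heuristic searches from many starting trees retain
every topology they evaluate.  Pooling and deduplicating those topologies,
re-optimizing branch lengths on each, and keeping the ones whose
log-likelihood strictly exceeds the optimized true tree's yields the
*optimality forest*.  Its *breadth* — the log-likelihood gap between the
best tree found and the true tree — shrinks toward zero as phylogenetic
information grows, which is the mechanism linking irreproducibility to
data informativeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment
from .evolve import derive_seed
from .likelihood import TreeLikelihood
from .models import SubstModel
from .search import SearchConfig, hill_climb, starting_trees
from .trees import Tree, parse_newick, rf_percent

__all__ = [
    "ForestMember",
    "ForestRecord",
    "build_forest",
    "forest_breadth",
    "inaccuracy_ll_regression",
    "breadth_vs_information",
    "forest_frame",
]


@dataclass
class ForestMember:
    topology_id: str
    newick: str
    log_likelihood: float
    delta_ll: float        # log_likelihood - true_ll (strictly positive)
    rf_percent_to_true: float


@dataclass
class ForestRecord:
    """The optimality forest of one data set."""

    dataset_id: str
    true_ll: float
    members: list[ForestMember] = field(default_factory=list)
    n_pooled: int = 0       # distinct topologies evaluated before filtering
    information: float | None = None
    level: int | None = None

    @property
    def n_distinct(self) -> int:
        return len(self.members)

    @property
    def breadth(self) -> float | None:
        """Max member LL minus true-tree LL; None for an empty forest."""
        if not self.members:
            return None
        return max(m.delta_ll for m in self.members)


def build_forest(aln: Alignment, model: SubstModel, true_tree: Tree,
                 n_starts: int = 25, seed: int = 0,
                 cfg: SearchConfig | None = None,
                 screen_margin: float | None = None,
                 dataset_id: str = "dataset") -> ForestRecord:
    """Construct the optimality forest for one data set.

    Runs ``n_starts`` trace-retaining hill climbs from generated starting
    trees, pools every topology they evaluated (accepted and rejected
    candidates alike), deduplicates by canonical splits, re-optimizes branch
    lengths per distinct topology, and keeps those whose log-likelihood
    strictly exceeds the optimized true-tree log-likelihood.

    ``screen_margin``, when set, skips full re-optimization of pooled
    topologies whose retained quick score (a lower bound of their optimized
    log-likelihood) falls more than ``margin`` below the true tree's —
    a speed/completeness trade-off; None (default) re-optimizes everything.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    cfg = cfg or SearchConfig()
    cfg = replace(cfg, retain_trace=True, n_starts=n_starts, seed=seed)
    engine = TreeLikelihood(aln, model)
    true_opt, res_t = engine.optimize_branch_lengths(
        true_tree, epsilon=cfg.epsilon, max_sweeps=cfg.max_sweeps,
        warn_on_cap=False,
    )
    true_ll = res_t.log_likelihood
    true_id = true_tree.topology_id()

    rng = np.random.default_rng(seed)
    starts = starting_trees(aln, model, n_starts, seed=derive_seed(seed, 17))
    pool: dict[str, tuple[str, float]] = {}  # id -> (newick, best retained LL)
    for idx, s in enumerate(starts):
        res = hill_climb(s, aln, model, cfg, engine=engine, rng=rng,
                         start_index=idx)
        for entry in res.trace:
            prev = pool.get(entry.topology_id)
            if prev is None or entry.log_likelihood > prev[1]:
                pool[entry.topology_id] = (entry.newick, entry.log_likelihood)

    members = []
    for topo_id in sorted(pool):
        if topo_id == true_id:
            continue  # the true tree is by definition not a member
        newick, retained_ll = pool[topo_id]
        if screen_margin is not None and retained_ll < true_ll - screen_margin:
            continue
        tree = parse_newick(newick)
        t_opt, r = engine.optimize_branch_lengths(
            tree, epsilon=cfg.epsilon, max_sweeps=cfg.max_sweeps,
            warn_on_cap=False,
        )
        if r.log_likelihood > true_ll:
            members.append(ForestMember(
                topology_id=topo_id,
                newick=t_opt.to_newick(),
                log_likelihood=r.log_likelihood,
                delta_ll=r.log_likelihood - true_ll,
                rf_percent_to_true=rf_percent(t_opt, true_tree),
            ))
    members.sort(key=lambda m: (-m.log_likelihood, m.topology_id))
    return ForestRecord(
        dataset_id=dataset_id, true_ll=true_ll, members=members,
        n_pooled=len(pool),
    )


def forest_breadth(rec: ForestRecord) -> float | None:
    """Breadth of the forest: best member LL minus true-tree LL.

    None for an empty forest (no tree beat the true tree).
    """
    return rec.breadth


def inaccuracy_ll_regression(rec: ForestRecord
                             ) -> tuple[float, float, float | None]:
    """OLS of member inaccuracy (percent RF to truth) on delta log-likelihood.

    Returns (slope, intercept, correlation); correlation is None when either
    variable is degenerate.  A flat slope means finding higher-likelihood
    trees within the forest does not buy accuracy.
    """
    if rec.n_distinct < 3:
        raise ValueError("need at least 3 forest members for a regression")
    x = np.array([m.delta_ll for m in rec.members])
    y = np.array([m.rf_percent_to_true for m in rec.members])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all delta-LL equal")
    if np.ptp(y) == 0:
        # all members equally accurate: exact flat line, no correlation
        return 0.0, float(y[0]), None
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def forest_frame(records: list[ForestRecord]) -> pd.DataFrame:
    """Per-data set forest summary table (empty forests → breadth 0)."""
    rows = []
    for r in records:
        rows.append({
            "dataset_id": r.dataset_id,
            "true_ll": r.true_ll,
            "n_distinct": r.n_distinct,
            "n_pooled": r.n_pooled,
            "breadth": 0.0 if r.breadth is None else r.breadth,
            "breadth_defined": r.breadth is not None,
            "information": r.information,
            "level": r.level,
        })
    return pd.DataFrame(rows)


def breadth_vs_information(records: list[ForestRecord]) -> pd.DataFrame:
    """Per-level mean breadth and the breadth-information rank correlation.

    Requires at least two information levels.  Empty forests contribute a
    breadth of 0 to level means.  The returned table has one row per level
    plus Spearman statistics in the DataFrame ``attrs``.
    """
    df = forest_frame(records)
    if df.level.isna().all() or df.level.nunique() < 2:
        raise ValueError("need forest records from >= 2 information levels")
    table = (df.groupby("level")
               .agg(mean_information=("information", "mean"),
                    mean_breadth=("breadth", "mean"),
                    mean_n_distinct=("n_distinct", "mean"),
                    n=("dataset_id", "size"))
               .reset_index()
               .sort_values("mean_information"))
    rho, p = stats.spearmanr(df.information, df.breadth)
    table.attrs["spearman_rho"] = float(rho)
    table.attrs["spearman_p"] = float(p)
    return table
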