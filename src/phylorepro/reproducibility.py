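"""The two-run reproducibility protocol and its collection-level aggregation.

A data set is *computationally irreproducible* when two heuristic-search
runs on identical input, differing only in random seed, return different
topologies (Robinson-Foulds distance > 0; branch lengths are ignored).
The canonical protocol runs seeds 111 and 123, compares the two inferred
trees (Q1, Q2) with each other and with the true tree (T), and records
both topological (percent RF) and log-likelihood differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._stats import bootstrap_mean_ci, bootstrap_p_mean_less, cis_overlap
from .alignment import Alignment
from .evolve import SimDataset, derive_seed
from .likelihood import TreeLikelihood
from .models import SubstModel
from .search import SearchConfig, SearchResult, heuristic_search
from .trees import Tree, rf_percent, same_topology

__all__ = [
    "ReproRecord",
    "CollectionSummary",
    "DEFAULT_SEEDS",
    "two_run",
    "true_start_run",
    "aggregate",
    "run_collection",
    "records_frame",
    "evaluate_patterns",
]

#: the canonical first-run / second-run seeds
DEFAULT_SEEDS = (111, 123)

#: log-likelihoods closer than the branch-optimization epsilon are ties
LL_TIE_TOL = 1e-4


@dataclass
class ReproRecord:
    """Per-data set outcome of the two-run protocol."""

    dataset_id: str
    q1: Tree
    q2: Tree
    ll1: float
    ll2: float
    ll_true: float
    d_q1q2: float
    d_q1t: float
    d_q2t: float
    dll_12: float
    dll_1t: float
    dll_2t: float
    reproducible: bool
    information: float | None = None
    level: int | None = None
    q3: Tree | None = None
    ll3: float | None = None
    d_q3t: float | None = None


@dataclass
class CollectionSummary:
    """Aggregate over a collection, partitioned by reproducibility."""

    n_datasets: int
    n_irreproducible: int
    pct_irreproducible: float
    means_irreproducible: dict | None
    means_reproducible: dict | None
    mean_abs_dll_12: float
    mean_abs_dll_1t: float
    frac_ll1_ge_true: float
    table: pd.DataFrame


def two_run(aln: Alignment, model: SubstModel, true_tree: Tree,
            cfg_base: SearchConfig | None = None,
            seeds: tuple[int, int] = DEFAULT_SEEDS,
            dataset_id: str = "dataset",
            ) -> ReproRecord:
    """Run the two-seed protocol on one data set.

    The two runs differ only in seed; using the same seed twice is refused
    because it would mandatorily return the same phylogeny.  The true tree's
    log-likelihood is computed with branch lengths re-optimized on the data.
    """
    if seeds[0] == seeds[1]:
        raise ValueError(
            "the two runs must use distinct seeds: identical seeds would "
            "mandatorily produce the same phylogeny"
        )
    cfg_base = cfg_base or SearchConfig()
    r1 = heuristic_search(aln, model, replace(cfg_base, seed=seeds[0]))
    r2 = heuristic_search(aln, model, replace(cfg_base, seed=seeds[1]))
    engine = TreeLikelihood(aln, model)
    _, res_t = engine.optimize_branch_lengths(
        true_tree, epsilon=cfg_base.epsilon, max_sweeps=cfg_base.max_sweeps,
        warn_on_cap=False,
    )
    d12 = rf_percent(r1.best_tree, r2.best_tree)
    return ReproRecord(
        dataset_id=dataset_id,
        q1=r1.best_tree, q2=r2.best_tree,
        ll1=r1.best_ll, ll2=r2.best_ll, ll_true=res_t.log_likelihood,
        d_q1q2=d12,
        d_q1t=rf_percent(r1.best_tree, true_tree),
        d_q2t=rf_percent(r2.best_tree, true_tree),
        dll_12=r1.best_ll - r2.best_ll,
        dll_1t=r1.best_ll - res_t.log_likelihood,
        dll_2t=r2.best_ll - res_t.log_likelihood,
        reproducible=(d12 == 0.0),
    )


def true_start_run(aln: Alignment, model: SubstModel, true_tree: Tree,
                   cfg: SearchConfig | None = None) -> tuple[Tree, float]:
    """Heuristic search seeded with the true topology (the Q3 experiment).

    Branch lengths of the true topology are optimized first, then the hill
    climb explores outward, guaranteeing the true tree's neighborhood is
    evaluated.  The returned log-likelihood is therefore never below the
    optimized true-tree likelihood.
    """
    cfg = cfg or SearchConfig()
    cfg = replace(cfg, initial_tree=true_tree)
    res = heuristic_search(aln, model, cfg)
    return res.best_tree, res.best_ll


def run_collection(datasets: list[SimDataset],
                   cfg_base: SearchConfig | None = None,
                   seeds: tuple[int, int] = DEFAULT_SEEDS,
                   with_q3: bool = False,
                   progress: bool = False) -> list[ReproRecord]:
    """Two-run protocol over a simulated collection.

    ``with_q3`` additionally runs the true-tree-seeded search per data set.
    """
    records = []
    cfg_base = cfg_base or SearchConfig()
    for i, ds in enumerate(datasets):
        rec = two_run(ds.alignment, ds.model, ds.true_tree, cfg_base,
                      seeds=seeds, dataset_id=ds.dataset_id)
        rec.information = ds.information
        rec.level = ds.level
        if with_q3:
            q3_cfg = replace(cfg_base, seed=derive_seed(ds.seed, 3))
            q3, ll3 = true_start_run(ds.alignment, ds.model, ds.true_tree,
                                     q3_cfg)
            rec.q3, rec.ll3 = q3, ll3
            rec.d_q3t = rf_percent(q3, ds.true_tree)
        if progress:
            print(f"[{i + 1}/{len(datasets)}] {ds.dataset_id} "
                  f"reproducible={rec.reproducible} d_q1t={rec.d_q1t:.1f}")
        records.append(rec)
    return records


def records_frame(records: list[ReproRecord]) -> pd.DataFrame:
    """Tidy per-data set table of the two-run outcomes."""
    rows = []
    for r in records:
        rows.append({
            "dataset_id": r.dataset_id,
            "reproducible": r.reproducible,
            "d_q1q2": r.d_q1q2, "d_q1t": r.d_q1t, "d_q2t": r.d_q2t,
            "ll1": r.ll1, "ll2": r.ll2, "ll_true": r.ll_true,
            "dll_12": r.dll_12, "dll_1t": r.dll_1t, "dll_2t": r.dll_2t,
            "information": r.information, "level": r.level,
            "ll3": r.ll3, "d_q3t": r.d_q3t,
        })
    return pd.DataFrame(rows)


def aggregate(records: list[ReproRecord]) -> CollectionSummary:
    """Collection summary: irreproducibility rate and subset means.

    Subset means are reported as None when the corresponding subset is
    empty (e.g. a fully reproducible collection has no irreproducible
    means), never as NaN placeholders.
    """
    if not records:
        raise ValueError("no records to aggregate")
    df = records_frame(records)
    irr = df[~df.reproducible]
    rep = df[df.reproducible]

    def subset_means(sub: pd.DataFrame) -> dict | None:
        if sub.empty:
            return None
        return {
            "d_q1q2": float(sub.d_q1q2.mean()),
            "d_q1t": float(sub.d_q1t.mean()),
            "d_q2t": float(sub.d_q2t.mean()),
            "abs_dll_12": float(sub.dll_12.abs().mean()),
            "abs_dll_1t": float(sub.dll_1t.abs().mean()),
        }

    return CollectionSummary(
        n_datasets=len(df),
        n_irreproducible=len(irr),
        pct_irreproducible=100.0 * len(irr) / len(df),
        means_irreproducible=subset_means(irr),
        means_reproducible=subset_means(rep),
        mean_abs_dll_12=float(df.dll_12.abs().mean()),
        mean_abs_dll_1t=float(df.dll_1t.abs().mean()),
        frac_ll1_ge_true=float((df.ll1 >= df.ll_true - LL_TIE_TOL).mean()),
        table=df,
    )


# ---------------------------------------------------------------------- #
# the structural patterns the collection studies test


def evaluate_patterns(records: list[ReproRecord], seed: int = 0,
                      ladder_levels: pd.DataFrame | None = None) -> dict:
    """Evaluate the structural patterns P1-P4 on two-run records.

    P1: among irreproducible data sets, the two runs differ less from each
        other than from the truth (one-sided paired bootstrap p < 0.05).
    P2: the two runs are equally accurate (overlapping 95% bootstrap CIs
        of mean inaccuracy).
    P3: the inferred tree's log-likelihood is at least the optimized true
        tree's in the overwhelming majority of data sets.
    P4: across increasing information levels, the irreproducibility
        fraction is non-increasing (requires level labels).
    """
    df = records_frame(records)
    out: dict = {}
    irr = df[~df.reproducible]
    if len(irr) >= 3:
        p1 = bootstrap_p_mean_less(irr.d_q1q2.values, irr.d_q1t.values,
                                   seed=derive_seed(seed, 11))
        out["P1"] = {
            "applicable": True,
            "mean_d_q1q2": float(irr.d_q1q2.mean()),
            "mean_d_q1t": float(irr.d_q1t.mean()),
            "p_value": p1,
            "pass": p1 < 0.05 and irr.d_q1q2.mean() < irr.d_q1t.mean(),
        }
        _, lo1, hi1 = bootstrap_mean_ci(irr.d_q1t.values,
                                        seed=derive_seed(seed, 12))
        _, lo2, hi2 = bootstrap_mean_ci(irr.d_q2t.values,
                                        seed=derive_seed(seed, 13))
        out["P2"] = {
            "applicable": True,
            "ci_q1t": (lo1, hi1), "ci_q2t": (lo2, hi2),
            "pass": cis_overlap((lo1, hi1), (lo2, hi2)),
        }
    else:
        out["P1"] = {"applicable": False, "pass": None}
        out["P2"] = {"applicable": False, "pass": None}
    frac = float((df.ll1 >= df.ll_true - LL_TIE_TOL).mean())
    out["P3"] = {"applicable": True, "frac_ll1_ge_true": frac,
                 "pass": frac >= 0.9}
    if df.level.notna().any():
        lv = (df.assign(irr=~df.reproducible)
                .groupby("level")["irr"].mean().sort_index())
        diffs = np.diff(lv.values)
        out["P4"] = {
            "applicable": True,
            "irreproducibility_by_level": lv.to_dict(),
            "pass": bool(np.all(diffs <= 1e-12)),
        }
    else:
        out["P4"] = {"applicable": False, "pass": None}
    return out
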