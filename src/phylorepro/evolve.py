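"""Synthetic data generation: model trees, lineage rate models, sequence
simulation, and whole-collection designs.

This module is the package's stand-in for the study collections it emulates:

* a "hundred-like" collection — HKY alignments over a broad range of
  sequence lengths, GC contents and transition/transversion ratios, with
  autocorrelated lineage rates, at a desk-scale taxon count;
* an "informativeness ladder" — GTR+G4 alignments simulated at several
  levels of phylogenetic information (expected substitution count), used to
  study how reproducibility and the optimality forest depend on signal.

Phylogenetic information is measured as (sum of true-tree branch lengths) x
(alignment length), i.e. the expected number of substitutions in the
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .models import SubstModel, gtr, hky
from .trees import Node, Tree

__all__ = [
    "RateModel",
    "SimDesign",
    "SimDataset",
    "yule_tree",
    "generate_model_tree",
    "assign_autocorrelated_rates",
    "simulate_alignment",
    "phylo_information",
    "make_collection",
    "hundred_like_design",
    "ladder_design",
    "gc_to_freqs",
    "derive_seed",
]

_NUC = np.array(list("ACGT"))


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-dataset seed from a master seed via SeedSequence spawning,
    kept below 2**31 so it can be re-entered on a command line."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def gc_to_freqs(gc: float) -> tuple[float, float, float, float]:
    """Base frequencies ((1-GC)/2, GC/2, GC/2, (1-GC)/2) for (A, C, G, T)."""
    if not 0 < gc < 1:
        raise ValueError("GC content must be in (0, 1)")
    at = (1.0 - gc) / 2.0
    return (at, gc / 2.0, gc / 2.0, at)


# ---------------------------------------------------------------------- #
# model trees


def yule_tree(m: int, seed: int, labels: list[str] | None = None) -> Tree:
    """Pure-birth (Yule) topology with time-like branch lengths.

    Lineages split after Exp(k) waiting times (k = current lineage count);
    after the m-th lineage appears the process runs one further Exp(m)
    interval so pendant branches have positive length.  Branch lengths are
    divided by the total elapsed time, so durations are on a unit time
    scale.  The returned tree is unrooted (basal trifurcation), as
    throughout the package.
    """
    if m < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    if labels is None:
        width = len(str(m))
        labels = [f"t{str(i + 1).zfill(width)}" for i in range(m)]
    elif len(labels) != m:
        raise ValueError("labels length must equal m")

    birth_times = {}  # node -> absolute time of its origin
    root = Node()
    birth_times[id(root)] = 0.0
    active: list[Node] = []
    t = 0.0
    # the root splits immediately into 2 lineages (time tree convention)
    for _ in range(2):
        c = Node()
        root.add_child(c)
        birth_times[id(c)] = 0.0
        active.append(c)
    while len(active) < m:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node = active.pop(i)
        node.length = t - birth_times[id(node)]
        for _ in range(2):
            c = Node()
            node.add_child(c)
            birth_times[id(c)] = t
            active.append(c)
    t += rng.exponential(1.0 / m)
    order = rng.permutation(m)
    for node, lab in zip(active, (labels[i] for i in order)):
        node.length = t - birth_times[id(node)]
        node.label = lab
    # height-normalize to 1 time unit
    tree = Tree(root)
    for node in tree.edges():
        node.length /= t
    return tree


@dataclass(frozen=True)
class RateModel:
    """Among-lineage rate model.

    ``strict``: every branch uses ``initial_rate``.  ``autocorrelated``:
    log-rates evolve along the tree Brownian-style, child log-rate drawn
    from a normal centered on the parent log-rate (with the usual -v t/2
    mean correction so rates stay mean-stationary), variance
    ``autocorrelation_variance`` per unit time of the time tree; a branch's
    rate is the mean of its endpoint rates.
    """

    kind: str = "strict"
    initial_rate: float = 2e-9  # substitutions / site / year
    autocorrelation_variance: float = 0.04  # per unit time (tree height = 1)

    def __post_init__(self):
        if self.kind not in ("strict", "autocorrelated"):
            raise ValueError(f"unknown rate model kind {self.kind!r}")
        if self.initial_rate <= 0:
            raise ValueError("initial_rate must be positive")
        if self.autocorrelation_variance < 0:
            raise ValueError("autocorrelation_variance must be >= 0")


def assign_autocorrelated_rates(tree: Tree, rate_model: RateModel,
                                seed: int) -> Tree:
    """Multiply time-like branch lengths by lineage rates.

    Under the strict model the tree is returned unchanged (a copy).  Under
    the autocorrelated model, node log-rates follow the Kishino-Thorne
    recursion down from the root and each branch length is multiplied by
    the mean of its endpoint rates.
    """
    tree = tree.copy()
    if rate_model.kind == "strict":
        for node in tree.edges():
            node.length *= rate_model.initial_rate
        return tree
    rng = np.random.default_rng(seed)
    nu = rate_model.autocorrelation_variance
    log_rate = {id(tree.root): float(np.log(rate_model.initial_rate))}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_lr = log_rate[id(node.parent)]
        var = nu * node.length
        lr = rng.normal(parent_lr - var / 2.0, np.sqrt(var)) if var > 0 else parent_lr
        log_rate[id(node)] = float(lr)
        branch_rate = (np.exp(parent_lr) + np.exp(lr)) / 2.0
        node.length *= branch_rate
    return tree


def generate_model_tree(m: int, target_tree_length: float, seed: int,
                        rate_model: RateModel | None = None) -> Tree:
    """Random Yule topology whose branch lengths sum to
    ``target_tree_length`` expected substitutions per site.

    When a rate model is given, lineage rates modulate the relative branch
    lengths before the final rescaling (the rescaling controls total
    information; the rate model shapes among-branch variation).
    """
    if m < 4:
        raise ValueError("need at least 4 taxa for a model tree")
    if target_tree_length <= 0:
        raise ValueError("target_tree_length must be positive")
    tree = yule_tree(m, seed)
    if rate_model is not None:
        tree = assign_autocorrelated_rates(tree, rate_model, derive_seed(seed, 1))
    total = tree.tree_length()
    for node in tree.edges():
        node.length *= target_tree_length / total
    return tree


# ---------------------------------------------------------------------- #
# sequence simulation


def simulate_alignment(tree: Tree, model: SubstModel, length: int,
                       seed: int) -> Alignment:
    """Evolve ``length`` sites along ``tree`` under ``model``.

    The root state of each site is drawn from the stationary frequencies;
    states then evolve edge-wise through the model's transition matrices.
    With gamma rate heterogeneity each site is assigned one of the discrete
    rate categories once, and keeps it on every branch (no site swapping).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    pi = model.pi
    rates = model.category_rates()
    ncat = len(rates)
    site_cat = (rng.integers(0, ncat, size=length) if ncat > 1
                else np.zeros(length, dtype=int))
    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(4, size=length, p=pi)
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(length, dtype=np.int64)
        for c in range(ncat):
            mask = site_cat == c
            if not mask.any():
                continue
            P = model.transition_matrix(node.length, rates[c])
            P = P / P.sum(axis=1, keepdims=True)
            ps = parent_states[mask]
            u = rng.random(ps.size)
            cdf = np.cumsum(P, axis=1)
            child[mask] = (u[:, None] > cdf[ps]).sum(axis=1)
        states[id(node)] = child
    records = []
    for leaf in tree.leaves():
        records.append((leaf.label, "".join(_NUC[states[id(leaf)]])))
    records.sort(key=lambda r: r[0])
    return Alignment(records)


def phylo_information(tree: Tree, length: int) -> float:
    """Expected substitution count: (sum of branch lengths) x (sites)."""
    return tree.tree_length() * float(length)


# ---------------------------------------------------------------------- #
# collection designs


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a simulated collection.

    Model parameters for each data set are drawn uniformly from the stated
    ranges.  ``information_levels``, when given, override
    ``tree_length_range``: data sets are divided evenly across levels and
    each level's tree length is (target substitutions) / (sites drawn).
    """

    name: str = "custom"
    n_taxa: int = 16
    n_datasets: int = 100
    length_range: tuple[int, int] = (258, 2000)
    model_kind: str = "HKY"  # or "GTR"
    gc_range: tuple[float, float] = (0.39, 0.82)
    kappa_range: tuple[float, float] = (1.35, 2.6)
    gtr_exchangeability_range: tuple[float, float] = (0.5, 2.0)
    gamma_shape: float | None = None
    n_categories: int = 4
    tree_length_range: tuple[float, float] = (0.05, 0.3)
    information_levels: tuple[float, ...] | None = None
    rate_model: RateModel = field(default_factory=RateModel)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        for lo, hi, what in [
            (*self.length_range, "length_range"),
            (*self.gc_range, "gc_range"),
            (*self.kappa_range, "kappa_range"),
            (*self.tree_length_range, "tree_length_range"),
        ]:
            if lo > hi or lo <= 0:
                raise ValueError(f"empty or invalid range for {what}")
        if self.information_levels is not None and len(self.information_levels) < 1:
            raise ValueError("information_levels must be non-empty when given")


@dataclass
class SimDataset:
    """One simulated data set: the truth, the data, and its provenance."""

    dataset_id: str
    true_tree: Tree
    alignment: Alignment
    model: SubstModel
    seed: int
    information: float
    level: int | None = None
    params: dict = field(default_factory=dict)


def _draw_model(design: SimDesign, rng: np.random.Generator) -> tuple[SubstModel, dict]:
    gc = float(rng.uniform(*design.gc_range))
    freqs = gc_to_freqs(gc)
    if design.model_kind == "HKY":
        kappa = float(rng.uniform(*design.kappa_range))
        model = hky(kappa, freqs, gamma_shape=design.gamma_shape,
                    n_categories=design.n_categories)
        params = {"gc": gc, "kappa": kappa}
    elif design.model_kind == "GTR":
        lo, hi = design.gtr_exchangeability_range
        ex = tuple(float(x) for x in rng.uniform(lo, hi, size=6))
        model = gtr(ex, freqs, gamma_shape=design.gamma_shape,
                    n_categories=design.n_categories)
        params = {"gc": gc, "exchangeabilities": ex}
    else:
        raise ValueError(f"unknown model kind {design.model_kind!r}")
    if design.gamma_shape is not None:
        params["gamma_shape"] = design.gamma_shape
    return model, params


def make_collection(design: SimDesign) -> list[SimDataset]:
    """Generate the full collection a design describes, reproducibly.

    Every data set gets its own derived seed (recorded in the metadata) so
    any single data set can be regenerated in isolation.
    """
    datasets = []
    n_levels = (len(design.information_levels)
                if design.information_levels is not None else 0)
    for i in range(design.n_datasets):
        ds_seed = derive_seed(design.master_seed, i)
        rng = np.random.default_rng(ds_seed)
        length = int(rng.integers(design.length_range[0],
                                  design.length_range[1] + 1))
        model, params = _draw_model(design, rng)
        level = None
        if n_levels:
            level = i * n_levels // design.n_datasets
            target_subs = design.information_levels[level]
            tree_length = target_subs / length
        else:
            tree_length = float(rng.uniform(*design.tree_length_range))
        tree_seed = derive_seed(ds_seed, 101)
        aln_seed = derive_seed(ds_seed, 202)
        true_tree = generate_model_tree(
            design.n_taxa, tree_length, tree_seed, rate_model=design.rate_model
        )
        aln = simulate_alignment(true_tree, model, length, aln_seed)
        params.update({"length": length, "tree_length": tree_length})
        datasets.append(SimDataset(
            dataset_id=f"{design.name}-{i:04d}",
            true_tree=true_tree,
            alignment=aln,
            model=model,
            seed=ds_seed,
            information=phylo_information(true_tree, length),
            level=level,
            params=params,
        ))
    return datasets


def hundred_like_design(master_seed: int = 0, n_datasets: int = 100,
                        n_taxa: int = 16,
                        length_range: tuple[int, int] = (258, 2000),
                        ) -> SimDesign:
    """Desk-scale analog of the 100-alignment HKY collection.

    Sequence-length, GC and kappa ranges follow the source collection
    (lengths capped at 2,000 sites here); lineage rates are autocorrelated;
    total tree length is drawn from (0.05, 0.3) substitutions/site so the
    information content spans roughly 15-600 expected substitutions.
    """
    return SimDesign(
        name="hundred",
        n_taxa=n_taxa,
        n_datasets=n_datasets,
        length_range=length_range,
        model_kind="HKY",
        gc_range=(0.39, 0.82),
        kappa_range=(1.35, 2.6),
        gamma_shape=None,
        tree_length_range=(0.05, 0.3),
        rate_model=RateModel(kind="autocorrelated"),
        master_seed=master_seed,
    )


def ladder_design(master_seed: int = 0, n_levels: int = 3,
                  per_level: int = 15, n_taxa: int = 16,
                  info_min: float = 100.0, info_max: float = 600.0,
                  ) -> SimDesign:
    """Desk-scale analog of the informativeness-ladder collection.

    GTR+G4 (gamma shape 1.0), 300-1,000 sites, with target expected
    substitution counts spaced geometrically between ``info_min`` and
    ``info_max`` across ``n_levels`` levels.

    The default range keeps every data set inside the regime where expected
    substitutions measure usable signal: below ``info_min`` the likelihood
    surface is so flat that topology differences stop registering, while
    pushing far above ``info_max`` at these alignment lengths and this
    taxon count drives per-site tree lengths past ~2, where multiple hits
    (saturation) erode signal even as the nominal substitution count grows.
    """
    levels = tuple(np.geomspace(info_min, info_max, n_levels))
    return SimDesign(
        name="ladder",
        n_taxa=n_taxa,
        n_datasets=n_levels * per_level,
        length_range=(300, 1000),
        model_kind="GTR",
        gc_range=(0.39, 0.82),
        gamma_shape=1.0,
        n_categories=4,
        information_levels=levels,
        rate_model=RateModel(kind="strict"),
        master_seed=master_seed,
    )
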