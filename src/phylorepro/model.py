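"""High-level modelling interface: build once from data, fit, inspect.

``MLPhylogeny`` pairs an alignment with a substitution model;
``fit(seed=...)`` runs the seeded heuristic search and returns an
``MLPhylogenyResults`` carrying the estimated tree, its log-likelihood,
the search trace and a text ``summary()``.  Refitting with a different
seed is exactly the two-run reproducibility experiment.
"""

from __future__ import annotations

from dataclasses import replace

from .alignment import Alignment
from .likelihood import TreeLikelihood
from .models import SubstModel
from .reproducibility import DEFAULT_SEEDS, ReproRecord, two_run
from .search import SearchConfig, SearchResult, heuristic_search
from .trees import Tree, rf_percent, same_topology

__all__ = ["MLPhylogeny", "MLPhylogenyResults"]


class MLPhylogeny:
    """Maximum-likelihood phylogeny model for one alignment.

    Parameters
    ----------
    alignment : Alignment
        Nucleotide alignment (use ``Alignment.from_fasta`` /
        ``from_phylip`` for files).
    model : SubstModel
        Substitution model, e.g. ``models.hky(2.0, freqs)`` or
        ``models.gtr(..., gamma_shape=1.0)``.
    """

    def __init__(self, alignment: Alignment, model: SubstModel):
        self.alignment = alignment
        self.model = model
        self._engine = TreeLikelihood(alignment, model)

    @classmethod
    def from_fasta(cls, path, model: SubstModel) -> "MLPhylogeny":
        return cls(Alignment.from_fasta(path), model)

    def loglike(self, tree: Tree) -> float:
        """Log-likelihood of a given tree under this model (natural log)."""
        return self._engine.log_likelihood(tree).log_likelihood

    def fit(self, seed: int = DEFAULT_SEEDS[0],
            config: SearchConfig | None = None) -> "MLPhylogenyResults":
        """Seeded heuristic ML search; same seed, same result."""
        cfg = replace(config or SearchConfig(), seed=seed)
        res = heuristic_search(self.alignment, self.model, cfg)
        return MLPhylogenyResults(self, res, cfg)

    def fit_from_tree(self, tree: Tree, seed: int = DEFAULT_SEEDS[0],
                      config: SearchConfig | None = None
                      ) -> "MLPhylogenyResults":
        """Search started from a supplied topology (the Q3-style protocol)."""
        cfg = replace(config or SearchConfig(), seed=seed, initial_tree=tree)
        res = heuristic_search(self.alignment, self.model, cfg)
        return MLPhylogenyResults(self, res, cfg)

    def two_run(self, true_tree: Tree, seeds=DEFAULT_SEEDS,
                config: SearchConfig | None = None) -> ReproRecord:
        """The two-seed reproducibility protocol against a known tree."""
        return two_run(self.alignment, self.model, true_tree,
                       config or SearchConfig(), seeds=seeds)


class MLPhylogenyResults:
    """Fitted ML phylogeny: estimates, optimality score, and diagnostics."""

    def __init__(self, model: MLPhylogeny, search_result: SearchResult,
                 config: SearchConfig):
        self.model = model
        self.search_result = search_result
        self.config = config

    @property
    def tree(self) -> Tree:
        return self.search_result.best_tree

    @property
    def loglike(self) -> float:
        return self.search_result.best_ll

    @property
    def seed(self) -> int:
        return self.search_result.seed

    def rf_percent_to(self, other: Tree) -> float:
        return rf_percent(self.tree, other)

    def same_topology_as(self, other) -> bool:
        tree = other.tree if isinstance(other, MLPhylogenyResults) else other
        return same_topology(self.tree, tree)

    def newick(self) -> str:
        return self.tree.to_newick()

    def summary(self) -> str:
        aln = self.model.alignment
        sm = self.model.model
        gamma = (f"+G{sm.n_categories} (shape {sm.gamma_shape})"
                 if sm.gamma_shape is not None else "")
        lines = [
            "Maximum-Likelihood Phylogeny Results",
            "=" * 44,
            f"Taxa:                  {aln.n_taxa()}",
            f"Sites:                 {aln.length}",
            f"Substitution model:    {sm.kind}{gamma}",
            f"Seed:                  {self.seed}",
            f"Starting trees:        {self.config.n_starts}",
            f"Log-likelihood:        {self.loglike:.4f}",
            f"Tree length:           {self.tree.tree_length():.4f}",
            f"Topologies evaluated:  {self.search_result.n_topologies_evaluated}",
            f"Search capped:         {self.search_result.capped}",
            "=" * 44,
            "Re-fit with a different seed to probe computational",
            "reproducibility of the inferred topology.",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MLPhylogenyResults ll={self.loglike:.2f} "
                f"seed={self.seed}>")
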