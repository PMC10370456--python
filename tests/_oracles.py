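"""Independent oracles: brute-force and closed-form references that never
touch the implementation paths they are used to check."""

from __future__ import annotations

import itertools
import math

import numpy as np

from phylorepro.alignment import CHAR_PARTIALS


def jc_transition_diag(d: float) -> float:
    """Jukes-Cantor closed form: P(same state) after branch length d."""
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)


def jc_pairwise_mle(p: float) -> float:
    """Closed-form JC branch-length MLE from the differing-site proportion."""
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc_expected_p(d: float) -> float:
    """Expected differing-site proportion at JC distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


# ---------------------------------------------------------------------- #
# trees: split enumeration via explicit set partition


def splits_by_edge_removal(tree) -> set[frozenset]:
    """Non-trivial splits as orientation-free {block, complement} pairs,
    found by deleting each internal edge and collecting the leaf labels on
    each side by traversal — no bitmask machinery shared with the package."""
    all_taxa = set(tree.taxa)
    out = set()
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        below = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                below.add(n.label)
            stack.extend(n.children)
        other = all_taxa - below
        if len(below) >= 2 and len(other) >= 2:
            out.add(frozenset({frozenset(below), frozenset(other)}))
    return out


def brute_force_rf(t1, t2) -> int:
    return len(splits_by_edge_removal(t1) ^ splits_by_edge_removal(t2))


# ---------------------------------------------------------------------- #
# likelihood: full marginalization over internal-node states


def brute_force_log_likelihood(tree, aln, model) -> float:
    """Sum over all internal-node state assignments, per site pattern and
    rate category.  Exponential in internal nodes; fine below ~6 taxa."""
    taxa = sorted(aln.taxa)
    rates = model.category_rates()
    pi = model.pi
    partial_of = {c: np.array(v, dtype=float) for c, v in CHAR_PARTIALS.items()}
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    npat_chars = {t: aln.sequence(t) for t in taxa}
    L = aln.length
    site_liks = np.zeros(L)
    for r in rates:
        P = {
            id(n): model.transition_matrix(n.length, r)
            for n in nodes if n.parent is not None
        }
        for assign in itertools.product(range(4), repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            lik = np.full(L, pi[state[id(tree.root)]])
            for n in nodes:
                if n.parent is None:
                    continue
                ps = state[id(n.parent)]
                if n.is_leaf:
                    row = P[id(n)][ps]  # P(child state | parent state)
                    emis = np.array([
                        row @ partial_of[ch] for ch in npat_chars[n.label]
                    ])
                    lik = lik * emis
                else:
                    lik = lik * P[id(n)][ps, state[id(n)]]
            site_liks += lik / len(rates)
    return float(np.log(site_liks).sum())


def ols_3point(x, y):
    """Textbook OLS slope/intercept for a tiny sample."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return slope, y.mean() - slope * x.mean()
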