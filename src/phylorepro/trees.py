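"""Unrooted phylogenetic trees: structure, Newick I/O, bipartitions, distances.

Trees are stored as a rooted data structure whose root is an internal node of
degree 3 (a basal trifurcation), the conventional representation of an
unrooted binary tree.  All topological comparisons (bipartitions,
Robinson-Foulds distance, topology identity) are on unrooted splits, so the
placement of the structural root never matters.  Branch lengths are in
expected substitutions per site.
"""

from __future__ import annotations

import hashlib
from typing import Iterator, Sequence

import dendropy

__all__ = [
    "Tree",
    "Node",
    "TreeError",
    "NewickParseError",
    "TaxonSetError",
    "parse_newick",
    "rf_distance",
    "rf_percent",
    "same_topology",
    "enumerate_topologies",
    "nni_neighbors",
    "spr_neighbors",
]

# maximum taxon count for exhaustive topology enumeration: (2m-5)!! explodes
MAX_ENUMERABLE_TAXA = 8


class TreeError(ValueError):
    """Invalid tree structure or operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class TaxonSetError(TreeError):
    """Operation on trees with incompatible taxon sets."""


class Node:
    """A node of the rooted representation.

    ``length`` is the length of the edge to the parent (undefined, 0.0, for
    the structural root).
    """

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """Unrooted tree over a set of uniquely labelled taxa.

    Parameters
    ----------
    root : Node
        Root of the internal rooted representation.  Degree-2 roots produced
        by rooted Newick input are suppressed on construction (child edge
        lengths summed across the removed node).
    """

    def __init__(self, root: Node):
        self.root = _suppress_degree2_root(root)
        labels = [n.label for n in self.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeError("every leaf must carry a taxon label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate taxon labels: {dupes}")
        self.taxa: tuple[str, ...] = tuple(sorted(labels))
        self._index = {lab: i for i, lab in enumerate(self.taxa)}
        for node in self.postorder():
            if node is not self.root and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length!r}; "
                    "clamp or fix before constructing a Tree"
                )

    # ------------------------------------------------------------------ #
    # traversal

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def n_taxa(self) -> int:
        return len(self.taxa)

    def edges(self) -> list[Node]:
        """Every edge, identified by its child node (all nodes but the root)."""
        return [n for n in self.postorder() if n is not self.root]

    def internal_edges(self) -> list[Node]:
        """Edges whose removal yields a non-trivial split (child is internal)."""
        return [n for n in self.edges() if not n.is_leaf]

    def tree_length(self) -> float:
        """Sum of branch lengths (expected substitutions per site)."""
        return sum(n.length for n in self.edges())

    def is_binary(self) -> bool:
        """True when fully resolved: root degree 3, other internals degree 3."""
        if len(self.root.children) != 3 and self.n_taxa() > 3:
            return False
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            if len(node.children) != 2:
                return False
        return self.n_taxa() < 3 or len(self.root.children) == 3

    # ------------------------------------------------------------------ #
    # copying

    def copy(self) -> "Tree":
        return Tree(_copy_subtree(self.root, None))

    # ------------------------------------------------------------------ #
    # bipartitions and topology identity

    def _leaf_masks(self) -> dict[int, int]:
        """Bitmask of taxa below each node keyed by id(node)."""
        masks: dict[int, int] = {}
        for node in self.postorder():
            if node.is_leaf:
                masks[id(node)] = 1 << self._index[node.label]
            else:
                m = 0
                for c in node.children:
                    m |= masks[id(c)]
                masks[id(node)] = m
        return masks

    def bipartitions(self) -> frozenset[int]:
        """Non-trivial unrooted splits as canonical bitmasks.

        A split is the set of taxa on one side of an internal edge, encoded
        as an integer bitmask over the sorted taxon list, canonicalized so the
        side *not* containing the first taxon is stored.  Trivial splits
        (singleton / m-1 blocks) are excluded.
        """
        m = self.n_taxa()
        full = (1 << m) - 1
        masks = self._leaf_masks()
        out = set()
        for node in self.internal_edges():
            mask = masks[id(node)]
            size = mask.bit_count()
            if size < 2 or m - size < 2:
                continue
            if mask & 1:
                mask = full & ~mask
            out.add(mask)
        return frozenset(out)

    def topology_key(self) -> tuple[tuple[str, ...], tuple[int, ...]]:
        """Hashable canonical topology identifier (taxa + sorted splits)."""
        return (self.taxa, tuple(sorted(self.bipartitions())))

    def topology_id(self) -> str:
        """Short deterministic hex digest of the canonical topology."""
        taxa, splits = self.topology_key()
        payload = ";".join(taxa) + "|" + ",".join(map(str, splits))
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    # ------------------------------------------------------------------ #
    # Newick

    def to_newick(self, precision: int = 10) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def rec(node: Node) -> str:
            if node.is_leaf:
                return f"{_quote_label(node.label)}:{fmt(node.length)}"
            inner = ",".join(rec(c) for c in node.children)
            if node is self.root:
                return f"({inner})"
            return f"({inner}):{fmt(node.length)}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, default_length: float = 0.0,
                    negative: str = "error") -> "Tree":
        return parse_newick(text, default_length=default_length,
                            negative=negative)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree m={self.n_taxa()} length={self.tree_length():.4g}>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _copy_subtree(node: Node, parent: Node | None) -> Node:
    new = Node(node.label, node.length)
    new.parent = parent
    for c in node.children:
        new.children.append(_copy_subtree(c, new))
    return new


def _suppress_degree2_root(root: Node) -> Node:
    """Unroot: merge a degree-2 root, summing lengths across it.

    Repeated until the root has != 2 children (or is a leaf edge case with a
    single child for 2-taxon trees, which is kept as-is).
    """
    while len(root.children) == 2:
        a, b = root.children
        if a.is_leaf and b.is_leaf:
            break  # 2-taxon tree: keep the single edge
        # make the internal child the new root, reattach the other child
        keep, move = (a, b) if not a.is_leaf else (b, a)
        move.length = move.length + keep.length
        keep.parent = None
        keep.children.append(move)
        move.parent = keep
        keep.length = 0.0
        root = keep
    # suppress any internal unifurcations left by odd input
    _suppress_unifurcations(root)
    return root


def _suppress_unifurcations(root: Node) -> None:
    stack = list(root.children)
    while stack:
        node = stack.pop()
        while len(node.children) == 1 and not node.is_leaf:
            child = node.children[0]
            child.length += node.length
            child.parent = node.parent
            idx = node.parent.children.index(node)
            node.parent.children[idx] = child
            node = child
        stack.extend(node.children)


# ---------------------------------------------------------------------- #
# parsing


def parse_newick(text: str, default_length: float = 0.0,
                 negative: str = "error") -> Tree:
    """Parse one Newick tree into an (unrooted) :class:`Tree`.

    Quoted labels and bracketed comments are handled; missing branch lengths
    default to ``default_length``.  ``negative`` controls negative input
    lengths: ``"error"`` raises, ``"clamp"`` sets them to 0 (useful for
    distance-method trees such as neighbor joining output).
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length
        if length is None:
            length = default_length
        if length < 0:
            if negative == "clamp":
                length = 0.0
            else:
                raise TreeError(f"negative branch length {length} in Newick")
        node = Node(label, float(length))
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    return Tree(root)


def read_newick_file(path) -> list[Tree]:
    """Read a multi-tree file, one Newick string per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(path, trees: Sequence[Tree], precision: int = 10) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick(precision=precision) + "\n")


# ---------------------------------------------------------------------- #
# distances


def _check_same_taxa(t1: Tree, t2: Tree) -> None:
    if t1.taxa != t2.taxa:
        only1 = sorted(set(t1.taxa) - set(t2.taxa))
        only2 = sorted(set(t2.taxa) - set(t1.taxa))
        raise TaxonSetError(
            f"taxon sets differ; only in first: {only1}, only in second: {only2}"
        )


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    non-trivial bipartition sets.  Accepts multifurcating trees."""
    _check_same_taxa(t1, t2)
    return len(t1.bipartitions() ^ t2.bipartitions())

def rf_percent(t1: Tree, t2: Tree) -> float:
    """Percent topological difference, d_RF / (2 (m - 3)) * 100.

    Both trees must be fully resolved (the normalization is the maximum
    possible d_RF for binary trees) with at least 4 taxa.
    """
    _check_same_taxa(t1, t2)
    m = t1.n_taxa()
    if m < 4:
        raise TreeError(f"rf_percent undefined for m={m} < 4 taxa")
    if not (t1.is_binary() and t2.is_binary()):
        raise TreeError("rf_percent requires fully resolved (binary) trees")
    return rf_distance(t1, t2) / (2.0 * (m - 3)) * 100.0


def same_topology(t1: Tree, t2: Tree) -> bool:
    """Topology identity, ignoring branch lengths."""
    return rf_distance(t1, t2) == 0


# ---------------------------------------------------------------------- #
# enumeration


def enumerate_topologies(taxa: Sequence[str],
                         default_length: float = 0.1) -> Iterator[Tree]:
    """Yield every distinct unrooted binary topology on ``taxa`` exactly once.

    Uses stepwise insertion: the k-th taxon is attached to each edge of each
    (k-1)-taxon topology, which enumerates the (2m-5)!! topologies without
    duplication.  Bounded at m = 8 (10,395 topologies).
    """
    labels = sorted(set(taxa))
    if len(labels) != len(taxa):
        raise TreeError("duplicate taxon labels")
    m = len(labels)
    if m < 3:
        raise TreeError("need at least 3 taxa")
    if m > MAX_ENUMERABLE_TAXA:
        raise TreeError(
            f"refusing to enumerate m={m} > {MAX_ENUMERABLE_TAXA} taxa: "
            f"(2m-5)!! topologies is intractable"
        )

    def base() -> Tree:
        root = Node()
        for lab in labels[:3]:
            root.add_child(Node(lab, default_length))
        return Tree(root)

    def insert_all(tree: Tree, k: int) -> Iterator[Tree]:
        if k == m:
            yield tree
            return
        label = labels[k]
        n_edges = len(tree.edges())
        for e in range(n_edges):
            t2 = tree.copy()
            edge_node = t2.edges()[e]
            parent = edge_node.parent
            mid = Node(None, edge_node.length / 2.0)
            idx = parent.children.index(edge_node)
            parent.children[idx] = mid
            mid.parent = parent
            edge_node.length = edge_node.length / 2.0
            mid.add_child(edge_node)
            mid.add_child(Node(label, default_length))
            yield from insert_all(Tree(t2.root), k + 1)

    yield from insert_all(base(), 3)


def n_topologies(m: int) -> int:
    """(2m-5)!! — the number of unrooted binary topologies on m taxa."""
    if m < 3:
        raise TreeError("m must be >= 3")
    out = 1
    for k in range(3, 2 * m - 4, 2):
        out *= k
    return out


# ---------------------------------------------------------------------- #
# topological moves


def _node_path(tree: Tree) -> dict[int, tuple[int, ...]]:
    """Stable address of each node as a tuple of child indices from the root."""
    paths = {id(tree.root): ()}
    for node in tree.preorder():
        for i, c in enumerate(node.children):
            paths[id(c)] = paths[id(node)] + (i,)
    return paths


def _resolve_path(tree: Tree, path: tuple[int, ...]) -> Node:
    node = tree.root
    for i in path:
        node = node.children[i]
    return node


def nni_neighbors(tree: Tree) -> Iterator[Tree]:
    """All nearest-neighbor-interchange topologies: 2 per internal edge,
    2(m-3) in total for a fully resolved tree.

    Each neighbor is a fresh tree; the input is never mutated.  Branch
    lengths are carried over unchanged (the swapped edges keep their
    lengths), leaving optimization to the caller.
    """
    paths = _node_path(tree)
    for v in tree.internal_edges():
        p = v.parent
        sibling = next(c for c in p.children if c is not v)
        for c in v.children:
            t2 = tree.copy()
            v2 = _resolve_path(t2, paths[id(v)])
            s2 = _resolve_path(t2, paths[id(sibling)])
            c2 = _resolve_path(t2, paths[id(c)])
            _swap_subtrees(v2, c2, v2.parent, s2)
            yield t2


def _swap_subtrees(parent_a: Node, a: Node, parent_b: Node, b: Node) -> None:
    ia = parent_a.children.index(a)
    ib = parent_b.children.index(b)
    parent_a.children[ia] = b
    parent_b.children[ib] = a
    a.parent, b.parent = parent_b, parent_a


def spr_neighbors(tree: Tree) -> Iterator[Tree]:
    """Subtree prune-and-regraft topologies (one-edge prunes, all regrafts).

    Yields each resulting topology once per (prune edge, regraft edge) pair,
    excluding regrafts that restore the original topology.  Quadratic in m;
    intended for small desk-scale searches where a wider neighborhood than
    NNI is wanted.
    """
    paths = _node_path(tree)
    edges = tree.edges()
    for prune in edges:
        prune_path = paths[id(prune)]
        below = set()
        stack = [prune]
        while stack:
            n = stack.pop()
            below.add(id(n))
            stack.extend(n.children)
        for target in edges:
            if id(target) in below or target is prune:
                continue
            if target is prune.parent or target.parent is prune.parent:
                continue  # regrafting next to the origin restores the topology
            t2 = tree.copy()
            pr = _resolve_path(t2, prune_path)
            tg = _resolve_path(t2, paths[id(target)])
            if _spr_move(t2, pr, tg):
                try:
                    yield Tree(t2.root)
                except TreeError:
                    continue


def _spr_move(tree: Tree, prune: Node, target: Node) -> bool:
    """Detach ``prune`` (with its subtree), suppress the leftover degree-2
    node, and reinsert on the edge above ``target``.  Returns False when the
    move is structurally impossible."""
    p = prune.parent
    if p is None:
        return False
    p.children.remove(prune)
    prune.parent = None
    # suppress p if now degree 2 (one child + its parent)
    if len(p.children) == 1 and p is not tree.root:
        only = p.children[0]
        only.length += p.length
        only.parent = p.parent
        p.parent.children[p.parent.children.index(p)] = only
    elif p is tree.root and len(p.children) == 2:
        pass  # root trifurcation temporarily a bifurcation; Tree() suppresses
    # insert new node on target's edge
    tparent = target.parent
    if tparent is None:
        return False
    mid = Node(None, target.length / 2.0)
    tparent.children[tparent.children.index(target)] = mid
    mid.parent = tparent
    target.length /= 2.0
    mid.add_child(target)
    mid.add_child(prune)
    return True
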