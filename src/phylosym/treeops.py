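"""Unrooted phylogenetic trees: structure, Newick I/O, bipartitions, enumeration.

The central object is :class:`PhyloTree`, a lightweight undirected tree whose
leaves carry sample labels and whose branches optionally carry lengths and
bootstrap supports.  Trees are unrooted in the phylogenetic sense: any node may
serve as a traversal root, and all comparisons go through bipartitions (the two
leaf sets induced by deleting a branch).

Topology combinatorics live here too: the number of distinct unrooted binary
topologies on ``n`` labelled leaves is the double factorial ``(2n-5)!!``, and
:func:`enumerate_topologies` generates each of them exactly once by the classic
leaf-insertion recursion (every topology on ``n`` leaves arises uniquely by
attaching leaf ``n`` to one branch of a topology on ``n-1`` leaves).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterator

import dendropy

__all__ = [
    "BranchData",
    "PhyloTree",
    "NewickParseError",
    "count_topologies",
    "count_rooted_topologies",
    "enumerate_topologies",
    "random_topology",
    "adjacency_to_tree",
    "tree_to_adjacency",
    "read_newick",
    "write_newick",
]


class NewickParseError(ValueError):
    """Raised when Newick text cannot be parsed; message includes position info."""


@dataclass
class BranchData:
    length: float | None = None
    support: float | None = None

    def copy(self) -> "BranchData":
        return BranchData(self.length, self.support)


class PhyloTree:
    """An unrooted tree with labelled leaves and optional branch annotations.

    Nodes are opaque integers.  Leaves are the degree-one nodes and carry a
    unique string label; internal nodes are unlabelled.  The tree need not be
    binary (majority-rule consensus trees may contain polytomies).
    """

    def __init__(self) -> None:
        self._adj: dict[int, set[int]] = {}
        self._labels: dict[int, str] = {}
        self._edges: dict[frozenset[int], BranchData] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def add_node(self, label: str | None = None) -> int:
        node = self._next_id
        self._next_id += 1
        self._adj[node] = set()
        if label is not None:
            if label in self._labels.values():
                raise ValueError(f"duplicate leaf label {label!r}")
            self._labels[node] = label
        return node

    def connect(self, u: int, v: int, length: float | None = None,
                support: float | None = None) -> None:
        if u == v or u not in self._adj or v not in self._adj:
            raise ValueError("invalid edge endpoints")
        self._adj[u].add(v)
        self._adj[v].add(u)
        self._edges[frozenset((u, v))] = BranchData(length, support)

    def disconnect(self, u: int, v: int) -> BranchData:
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        return self._edges.pop(frozenset((u, v)))

    def remove_node(self, u: int) -> None:
        for v in list(self._adj[u]):
            self.disconnect(u, v)
        del self._adj[u]
        self._labels.pop(u, None)

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return list(self._adj)

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def neighbors(self, u: int) -> set[int]:
        return set(self._adj[u])

    def leaves(self) -> list[int]:
        return sorted(self._labels)

    @property
    def leaf_labels(self) -> set[str]:
        return set(self._labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    def label_of(self, node: int) -> str | None:
        return self._labels.get(node)

    def node_of(self, label: str) -> int:
        for node, lab in self._labels.items():
            if lab == label:
                return node
        raise KeyError(label)

    def edges(self) -> list[tuple[int, int, BranchData]]:
        out = []
        for key, data in self._edges.items():
            u, v = sorted(key)
            out.append((u, v, data))
        out.sort(key=lambda e: (e[0], e[1]))
        return out

    def branch(self, u: int, v: int) -> BranchData:
        return self._edges[frozenset((u, v))]

    def total_length(self) -> float:
        total = 0.0
        for _, _, data in self.edges():
            if data.length is None:
                raise ValueError("tree has branches without lengths")
            total += data.length
        return total

    def is_binary(self) -> bool:
        return all(self.degree(u) in (1, 3) for u in self._adj)

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {u: set(vs) for u, vs in self._adj.items()}
        t._labels = dict(self._labels)
        t._edges = {k: d.copy() for k, d in self._edges.items()}
        t._next_id = self._next_id
        return t

    # -- traversal / bipartitions ----------------------------------------

    def _ref_leaf(self) -> int:
        return min(self._labels, key=lambda u: self._labels[u])

    def postorder(self, root: int) -> list[tuple[int, int | None]]:
        """(node, parent) pairs, children before parents, from ``root``."""
        order: list[tuple[int, int | None]] = []
        stack: list[tuple[int, int | None]] = [(root, None)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nbr in sorted(self._adj[node]):
                if nbr != parent:
                    stack.append((nbr, node))
        order.reverse()
        return order

    def bipartition_map(self, include_trivial: bool = False
                        ) -> dict[frozenset[str], tuple[int, int]]:
        """Map each branch's canonical split to its ``(parent, child)`` pair.

        The canonical side of a split is the side *not* containing the
        alphabetically smallest leaf label, so identical splits from different
        trees compare equal.
        """
        if self.n_leaves < 2:
            return {}
        ref = self._ref_leaf()
        all_labels = frozenset(self._labels.values())
        below: dict[int, frozenset[str]] = {}
        splits: dict[frozenset[str], tuple[int, int]] = {}
        for node, parent in self.postorder(ref):
            if node in self._labels and node != ref:
                below[node] = frozenset((self._labels[node],))
            elif node != ref:
                below[node] = frozenset().union(
                    *(below[c] for c in self._adj[node] if c != parent))
            if parent is not None:
                side = below[node] if node != ref else all_labels - frozenset((self._labels[ref],))
                if include_trivial or 1 < len(side) < self.n_leaves - 1:
                    splits[side] = (parent, node)
        return splits

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        return set(self.bipartition_map(include_trivial))

    def distance(self, label_a: str, label_b: str) -> float:
        """Path length between two leaves (branch lengths required)."""
        a, b = self.node_of(label_a), self.node_of(label_b)
        dist = {a: 0.0}
        stack = [a]
        while stack:
            u = stack.pop()
            if u == b:
                return dist[u]
            for v in self._adj[u]:
                if v not in dist:
                    length = self._edges[frozenset((u, v))].length
                    if length is None:
                        raise ValueError("tree has branches without lengths")
                    dist[v] = dist[u] + length
                    stack.append(v)
        raise KeyError("leaves not connected")

    def suppress_degree_two(self) -> None:
        """Splice out degree-2 nodes, summing branch lengths across them."""
        for u in [n for n in self.nodes if self.degree(n) == 2 and n not in self._labels]:
            a, b = sorted(self._adj[u])
            da = self.disconnect(u, a)
            db = self.disconnect(u, b)
            del self._adj[u]
            length = None
            if da.length is not None and db.length is not None:
                length = da.length + db.length
            support = da.support if da.support is not None else db.support
            self.connect(a, b, length=length, support=support)

    # -- Newick I/O -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        tree = cls()
        node_map: dict[dendropy.Node, int] = {}
        for dnode in dtree.preorder_node_iter():
            label = dnode.taxon.label if dnode.taxon is not None else None
            if label is None and not dnode.child_nodes():
                label = dnode.label  # unquoted leaf without taxon
            node = tree.add_node(label if not dnode.child_nodes() else None)
            node_map[dnode] = node
            if dnode.parent_node is not None:
                support = None
                if dnode.child_nodes() and dnode.label is not None:
                    try:
                        support = float(dnode.label)
                    except ValueError:
                        support = None
                tree.connect(node_map[dnode.parent_node], node,
                             length=dnode.edge.length, support=support)
        tree.suppress_degree_two()
        if tree.n_leaves < 2:
            raise NewickParseError("tree must have at least two leaves")
        return tree

    def to_newick(self, lengths: bool = True, supports: bool = True) -> str:
        """Canonical Newick: rooted at the neighbour of the smallest leaf,
        children ordered by their smallest descendant label."""
        ref = self._ref_leaf()
        root = next(iter(self._adj[ref])) if self.degree(ref) else ref
        min_below: dict[int, str] = {}
        for node, parent in self.postorder(root):
            if node in self._labels:
                min_below[node] = self._labels[node]
            else:
                min_below[node] = min(min_below[c] for c in self._adj[node] if c != parent)

        def fmt(node: int, parent: int | None) -> str:
            children = sorted((c for c in self._adj[node] if c != parent),
                              key=lambda c: min_below[c])
            if node in self._labels:
                body = self._labels[node]
            else:
                body = "(" + ",".join(fmt(c, node) for c in children) + ")"
            suffix = ""
            if parent is not None:
                data = self._edges[frozenset((node, parent))]
                if supports and data.support is not None and node not in self._labels:
                    suffix += f"{data.support:g}"
                if lengths and data.length is not None:
                    suffix += f":{data.length:.10g}"
            return body + suffix

        return fmt(root, None) + ";"

    def __repr__(self) -> str:
        return f"PhyloTree(n_leaves={self.n_leaves})"


def read_newick(text: str) -> PhyloTree:
    """Parse Newick text into a :class:`PhyloTree` (raises on malformed input)."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, lengths: bool = True, supports: bool = True) -> str:
    """Serialize a tree to canonical Newick."""
    return tree.to_newick(lengths=lengths, supports=supports)


# -- topology combinatorics ----------------------------------------------


def count_topologies(n_leaves: int) -> int:
    """Number of unrooted binary topologies on ``n`` labelled leaves: (2n-5)!!."""
    if n_leaves < 3:
        raise ValueError("unrooted binary topologies require at least 3 leaves")
    out = 1
    for k in range(3, 2 * n_leaves - 4, 2):
        out *= k
    return out


def count_rooted_topologies(n_leaves: int) -> int:
    """Number of rooted binary shapes on ``n`` labelled leaves: (2n-3)!!."""
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    if n_leaves <= 2:
        return 1
    out = 1
    for k in range(3, 2 * n_leaves - 2, 2):
        out *= k
    return out


Adjacency = dict[int, set[int]]


def _adj_edges(adj: Adjacency) -> list[tuple[int, int]]:
    return sorted({(min(u, v), max(u, v)) for u, vs in adj.items() for v in vs})


def enumerate_topologies(n_leaves: int) -> Iterator[Adjacency]:
    """Yield every unrooted binary topology on leaves ``0..n-1`` exactly once.

    Internal nodes are numbered from ``n_leaves`` upward.  The recursion
    inserts leaf ``k`` on each branch of each topology on ``k`` leaves.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    base: Adjacency = {0: {n_leaves}, 1: {n_leaves}, 2: {n_leaves},
                       n_leaves: {0, 1, 2}}

    def expand(adj: Adjacency, next_leaf: int, next_internal: int) -> Iterator[Adjacency]:
        if next_leaf == n_leaves:
            yield adj
            return
        for u, v in _adj_edges(adj):
            new = {node: set(nbrs) for node, nbrs in adj.items()}
            w = next_internal
            new[u].discard(v)
            new[v].discard(u)
            new[w] = {u, v, next_leaf}
            new[u].add(w)
            new[v].add(w)
            new[next_leaf] = {w}
            yield from expand(new, next_leaf + 1, next_internal + 1)

    yield from expand(base, 3, n_leaves + 1)


def random_topology(n_leaves: int, rng) -> Adjacency:
    """A uniformly random unrooted binary topology via random leaf insertion."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    adj: Adjacency = {0: {n_leaves}, 1: {n_leaves}, 2: {n_leaves},
                      n_leaves: {0, 1, 2}}
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        edges = _adj_edges(adj)
        u, v = edges[int(rng.integers(len(edges)))]
        w = next_internal
        next_internal += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[w] = {u, v, leaf}
        adj[u].add(w)
        adj[v].add(w)
        adj[leaf] = {w}
    return adj


def adjacency_to_tree(adj: Adjacency, labels: list[str],
                      lengths: dict[tuple[int, int], float] | None = None) -> PhyloTree:
    """Build a :class:`PhyloTree` from an integer adjacency whose leaves
    ``0..len(labels)-1`` map to ``labels`` in order."""
    tree = PhyloTree()
    node_map: dict[int, int] = {}
    for node in sorted(adj):
        label = labels[node] if node < len(labels) else None
        node_map[node] = tree.add_node(label)
    for u, v in _adj_edges(adj):
        length = None
        if lengths is not None:
            length = lengths.get((u, v), lengths.get((v, u)))
        tree.connect(node_map[u], node_map[v], length=length)
    return tree


def tree_to_adjacency(tree: PhyloTree, sample_order: list[str]
                      ) -> tuple[Adjacency, dict[int, int]]:
    """Relabel a tree as an integer adjacency with leaves ``0..n-1`` following
    ``sample_order``; returns the adjacency and the original->new node map."""
    if set(sample_order) != tree.leaf_labels:
        raise ValueError("sample order does not match tree leaves")
    index = {label: i for i, label in enumerate(sample_order)}
    node_map: dict[int, int] = {}
    next_internal = len(sample_order)
    for node in sorted(tree.nodes):
        label = tree.label_of(node)
        if label is not None:
            node_map[node] = index[label]
        else:
            node_map[node] = next_internal
            next_internal += 1
    adj: Adjacency = {node_map[u]: {node_map[v] for v in tree.neighbors(u)}
                      for u in tree.nodes}
    return adj, node_map
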