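"""Ordered-character (Wagner) maximum parsimony on unrooted trees.

Characters take integer states 0..5 and evolve under an explicit transition
cost matrix; the default is the linear (ordered) cost ``|i - j|``, so a jump
between distant abundance states is proportionally more expensive than a jump
between adjacent ones.  The tree length under a cost matrix is the *p-score*:
the sum over characters of the minimum total transition cost over all internal
state assignments, computed by Sankoff dynamic programming.  Because the cost
matrix is symmetric the score is independent of the traversal root.

Search comes in two flavours: :func:`exhaustive_search` enumerates all
``(2n-5)!!`` unrooted binary topologies (the small-n oracle, and the way to
obtain *all* most-parsimonious trees), and :func:`heuristic_search` performs
random-addition stepwise insertion followed by NNI or SPR hill climbing.
Bootstrap support resamples characters with replacement, reruns the search and
tallies bipartitions of one best tree per pseudo-replicate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .treeops import (
    Adjacency,
    PhyloTree,
    _adj_edges,
    adjacency_to_tree,
    enumerate_topologies,
    tree_to_adjacency,
)

__all__ = [
    "CostMatrix",
    "SearchResult",
    "BootstrapResult",
    "sankoff_score",
    "exhaustive_search",
    "heuristic_search",
    "bootstrap",
    "assign_branch_lengths",
    "majority_rule_consensus",
]

_INF = 1e18


@dataclass(frozen=True)
class CostMatrix:
    """A symmetric state-transition cost matrix with zero diagonal.

    The triangle inequality is enforced so that a direct change is never more
    expensive than a detour through an intermediate state (otherwise the
    reported minimum would implicitly use unobserved intermediate steps).
    """

    costs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        object.__setattr__(self, "costs", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("cost matrix must be square")
        if (c < 0).any():
            raise ValueError("costs must be non-negative")
        if not np.allclose(c, c.T):
            raise ValueError("cost matrix must be symmetric")
        if np.diag(c).any():
            raise ValueError("diagonal must be zero")
        n = c.shape[0]
        for k in range(n):
            if (c > c[:, k:k + 1] + c[None, k, :] + 1e-12).any():
                raise ValueError("cost matrix violates the triangle inequality")

    @property
    def n_states(self) -> int:
        return self.costs.shape[0]

    @classmethod
    def ordered(cls, n_states: int = 6) -> "CostMatrix":
        """Wagner costs: cost(i, j) = |i - j|."""
        idx = np.arange(n_states)
        return cls(np.abs(idx[:, None] - idx[None, :]).astype(float))

    @classmethod
    def unit(cls, n_states: int = 6) -> "CostMatrix":
        """Fitch costs: 1 for any change."""
        return cls(1.0 - np.eye(n_states))


@dataclass
class SearchResult:
    score: int
    trees: list[PhyloTree]
    n_rearrangements: int
    seed: int | None = None


@dataclass
class BootstrapResult:
    supports: dict[frozenset, float]
    consensus: PhyloTree
    n_reps: int


class _Engine:
    """Pre-digested matrix + costs for fast repeated Sankoff evaluation.

    Character columns are compressed to unique site patterns with counts; a
    bootstrap pseudo-replicate only changes the pattern weights.
    """

    def __init__(self, samples: list[str], states: np.ndarray, costs: CostMatrix):
        self.samples = list(samples)
        states = np.asarray(states)
        if states.ndim != 2 or states.shape[0] != len(self.samples):
            raise ValueError("states must be (n_samples, n_characters)")
        if not np.issubdtype(states.dtype, np.integer):
            raise ValueError("states must be integers")
        n_states = costs.n_states
        if states.size and (states.min() < 0 or states.max() >= n_states):
            raise ValueError(f"states must lie in 0..{n_states - 1}")
        self.costs = costs.costs
        self.n = len(self.samples)
        self.n_char = states.shape[1]
        patterns, self.col_pattern = np.unique(states.T, axis=0, return_inverse=True)
        self.patterns = patterns  # (npat, n)
        self.weights = np.bincount(self.col_pattern,
                                   minlength=patterns.shape[0]).astype(float)
        self.n_pat = patterns.shape[0]
        leafcost = np.full((self.n, self.n_pat, n_states), _INF)
        rows = np.arange(self.n_pat)
        for leaf in range(self.n):
            leafcost[leaf, rows, patterns[:, leaf]] = 0.0
        self.leafcost = leafcost
        # per-topology minimum cost per pattern; a bootstrap replicate only
        # reweights patterns, so searches across replicates share this cache
        self._pattern_cache: dict[frozenset, np.ndarray] = {}

    def resample_weights(self, rng: np.random.Generator) -> np.ndarray:
        cols = rng.integers(0, self.n_char, self.n_char)
        return np.bincount(self.col_pattern[cols], minlength=self.n_pat).astype(float)

    # -- scoring ----------------------------------------------------------

    def _node_costs(self, adj: Adjacency) -> tuple[int, list[tuple[int, int]], dict]:
        """Root the topology and return (root, postorder (node,parent), cost arrays)."""
        present = sorted(u for u in adj if u < self.n)
        first = present[0]
        if len(adj) == 2:  # two-leaf tree: no internal node
            return first, [], {}
        root = next(iter(adj[first]))
        order: list[tuple[int, int | None]] = []
        stack: list[tuple[int, int | None]] = [(root, None)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nbr in sorted(adj[node]):
                if nbr != parent:
                    stack.append((nbr, node))
        order.reverse()
        C = self.costs
        cost: dict[int, np.ndarray] = {}
        for node, parent in order:
            if node < self.n:
                cost[node] = self.leafcost[node]
            else:
                total = None
                for child in adj[node]:
                    if child == parent:
                        continue
                    contrib = (cost[child][:, None, :] + C[None, :, :]).min(axis=2)
                    total = contrib if total is None else total + contrib
                cost[node] = total
        return root, order, cost

    def _topo_key(self, adj: Adjacency) -> frozenset:
        """Canonical key of a (possibly partial) topology: the set of rooted
        leaf clusters seen from the smallest present leaf."""
        present = sorted(u for u in adj if u < self.n)
        first = present[0]
        if len(adj) == 2:
            return frozenset((frozenset(present),))
        root = next(iter(adj[first]))
        below: dict[int, frozenset] = {}
        clusters = []
        stack: list[tuple[int, int | None]] = [(root, None)]
        order = []
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nbr in sorted(adj[node]):
                if nbr != parent:
                    stack.append((nbr, node))
        for node, parent in reversed(order):
            if node < self.n:
                below[node] = frozenset((node,))
            else:
                below[node] = frozenset().union(
                    *(below[c] for c in adj[node] if c != parent))
            if parent is not None:
                clusters.append(below[node])
        return frozenset(clusters)

    def pattern_scores(self, adj: Adjacency) -> np.ndarray:
        """Minimum transition cost of each site pattern on this topology."""
        key = self._topo_key(adj)
        cached = self._pattern_cache.get(key)
        if cached is not None:
            return cached
        if len(adj) == 2:
            leaves = sorted(adj)
            out = self.costs[self.patterns[:, leaves[0]],
                             self.patterns[:, leaves[1]]]
        else:
            root, _, cost = self._node_costs(adj)
            out = cost[root].min(axis=1)
        self._pattern_cache[key] = out
        return out

    def score(self, adj: Adjacency, weights: np.ndarray | None = None) -> float:
        w = self.weights if weights is None else weights
        return float(self.pattern_scores(adj) @ w)

    def branch_changes(self, adj: Adjacency,
                       weights: np.ndarray | None = None) -> dict[tuple[int, int], float]:
        """Minimum-cost changes per branch under a deterministic backtrace.

        State ambiguities are broken toward the lowest state index (np.argmin
        convention), so lengths are reproducible and sum exactly to the p-score.
        """
        w = self.weights if weights is None else weights
        C = self.costs
        if len(adj) == 2:
            leaves = sorted(adj)
            per_pat = C[self.patterns[:, leaves[0]], self.patterns[:, leaves[1]]]
            return {(leaves[0], leaves[1]): float(per_pat @ w)}
        root, order, cost = self._node_costs(adj)
        state: dict[int, np.ndarray] = {root: np.argmin(cost[root], axis=1)}
        lengths: dict[tuple[int, int], float] = {}
        for node, parent in reversed(order):
            if parent is None:
                continue
            sp = state[parent]
            sc = np.argmin(C[sp, :] + cost[node], axis=1)
            state[node] = sc
            key = (min(node, parent), max(node, parent))
            lengths[key] = float(C[sp, sc] @ w)
        return lengths


def _as_engine(matrix, costs: CostMatrix | None) -> _Engine:
    costs = CostMatrix.ordered() if costs is None else costs
    return _Engine(list(matrix.samples), np.asarray(matrix.states), costs)


def _adj_splits(adj: Adjacency, n: int) -> frozenset:
    """Canonical nontrivial splits (frozensets of leaf ints not containing 0)."""
    root = next(iter(adj[0]))
    splits = set()
    below: dict[int, frozenset[int]] = {}
    order: list[tuple[int, int | None]] = []
    stack: list[tuple[int, int | None]] = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nbr in sorted(adj[node]):
            if nbr != parent:
                stack.append((nbr, node))
    for node, parent in reversed(order):
        if node < n:
            below[node] = frozenset((node,))
        else:
            below[node] = frozenset().union(
                *(below[c] for c in adj[node] if c != parent))
        if parent is not None and 1 < len(below[node]) < n - 1:
            splits.add(below[node])
    return frozenset(splits)


# -- public scoring -------------------------------------------------------


def sankoff_score(tree: PhyloTree, matrix, costs: CostMatrix | None = None) -> int:
    """Parsimony length (p-score) of ``matrix`` on ``tree`` under ``costs``."""
    engine = _as_engine(matrix, costs)
    adj, _ = tree_to_adjacency(tree, engine.samples)
    score = engine.score(adj)
    return int(round(score))


def assign_branch_lengths(tree: PhyloTree, matrix,
                          costs: CostMatrix | None = None) -> PhyloTree:
    """Return a copy of ``tree`` whose branch lengths are the per-branch
    minimum-cost change counts; they sum exactly to the p-score."""
    engine = _as_engine(matrix, costs)
    adj, node_map = tree_to_adjacency(tree, engine.samples)
    lengths = engine.branch_changes(adj)
    out = tree.copy()
    for u, v, data in out.edges():
        iu, iv = node_map[u], node_map[v]
        data.length = lengths[(min(iu, iv), max(iu, iv))]
    return out


# -- search ---------------------------------------------------------------


def _stepwise_addition(engine: _Engine, order: list[int],
                       weights: np.ndarray | None) -> tuple[Adjacency, int]:
    n = engine.n
    a, b, c = order[:3]
    hub = n
    adj: Adjacency = {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
    next_internal = n + 1
    evaluated = 0
    for leaf in order[3:]:
        best = None
        best_edge = None
        for u, v in _adj_edges(adj):
            w = next_internal
            adj[u].discard(v)
            adj[v].discard(u)
            adj[w] = {u, v, leaf}
            adj[u].add(w)
            adj[v].add(w)
            adj[leaf] = {w}
            score = engine.score(adj, weights)
            evaluated += 1
            if best is None or score < best - 1e-9:
                best, best_edge = score, (u, v)
            del adj[w]
            del adj[leaf]
            adj[u].discard(w)
            adj[v].discard(w)
            adj[u].add(v)
            adj[v].add(u)
        u, v = best_edge
        w = next_internal
        next_internal += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[w] = {u, v, leaf}
        adj[u].add(w)
        adj[v].add(w)
        adj[leaf] = {w}
    return adj, evaluated


def _nni_neighbors(adj: Adjacency, n: int):
    for u, v in _adj_edges(adj):
        if u < n or v < n:
            continue
        a = min(x for x in adj[u] if x != v)
        for c in sorted(x for x in adj[v] if x != u):
            new = {node: set(nbrs) for node, nbrs in adj.items()}
            new[u].discard(a); new[a].discard(u)
            new[v].discard(c); new[c].discard(v)
            new[u].add(c); new[c].add(u)
            new[v].add(a); new[a].add(v)
            yield new


def _spr_neighbors(adj: Adjacency, n: int):
    edges = _adj_edges(adj)
    for u, v in edges + [(v, u) for u, v in edges]:
        # prune the v-side subtree by cutting (u, v); u must stay behind
        if len(adj[u]) == 1:
            continue
        rest = [x for x in adj[u] if x != v]
        if len(rest) != 2:
            continue  # non-binary residual node: leave in place
        a, b = rest
        # residual tree: everything reachable from a or b without crossing u,
        # with the degree-2 node u spliced out (edge a-b takes its place)
        res: Adjacency = {}
        stack = [a, b]
        while stack:
            x = stack.pop()
            if x in res:
                continue
            res[x] = {y for y in adj[x] if y != u}
            for y in res[x]:
                if y not in res:
                    stack.append(y)
        res[a].add(b)
        res[b].add(a)
        if len(res) < 2:
            continue
        for x, y in _adj_edges(res):
            if {x, y} == {a, b}:
                continue  # reattaching here recreates the original topology
            new = {node: set(nbrs) for node, nbrs in adj.items()}
            new[u] = set()
            new[a].discard(u); new[b].discard(u)
            new[a].add(b); new[b].add(a)
            new[x].discard(y); new[y].discard(x)
            new[x].add(u); new[y].add(u)
            new[u] = {x, y, v}
            yield new


def _hill_climb(engine: _Engine, adj: Adjacency, rearrangement: str,
                weights: np.ndarray | None) -> tuple[Adjacency, float, int]:
    neighbor_fn = _spr_neighbors if rearrangement == "spr" else _nni_neighbors
    score = engine.score(adj, weights)
    evaluated = 0
    while True:
        best_nbr = None
        best_score = score
        for nbr in neighbor_fn(adj, engine.n):
            s = engine.score(nbr, weights)
            evaluated += 1
            if s < best_score - 1e-9:
                best_score, best_nbr = s, nbr
        if best_nbr is None:
            return adj, score, evaluated
        adj, score = best_nbr, best_score


def _run_search(engine: _Engine, rng: np.random.Generator, n_starts: int,
                rearrangement: str, weights: np.ndarray | None
                ) -> tuple[float, list[Adjacency], int]:
    best_score = None
    best_adjs: list[Adjacency] = []
    best_keys: set[frozenset] = set()
    evaluated = 0
    for _ in range(n_starts):
        order = [int(x) for x in rng.permutation(engine.n)]
        adj, ev1 = _stepwise_addition(engine, order, weights)
        adj, score, ev2 = _hill_climb(engine, adj, rearrangement, weights)
        evaluated += ev1 + ev2
        if best_score is None or score < best_score - 1e-9:
            best_score = score
            best_adjs = [adj]
            best_keys = {_adj_splits(adj, engine.n)}
        elif abs(score - best_score) <= 1e-9:
            key = _adj_splits(adj, engine.n)
            if key not in best_keys:
                best_keys.add(key)
                best_adjs.append(adj)
    return best_score, best_adjs, evaluated


def heuristic_search(matrix, costs: CostMatrix | None = None, n_starts: int = 10,
                     rearrangement: str = "spr", seed: int | None = None) -> SearchResult:
    """Random-addition stepwise insertion + hill climbing by NNI or SPR.

    Returns every distinct best topology found across starts.  With four or
    fewer taxa the search space is covered trivially and the result matches
    :func:`exhaustive_search`.
    """
    if rearrangement not in ("spr", "nni"):
        raise ValueError("rearrangement must be 'spr' or 'nni'")
    engine = _as_engine(matrix, costs)
    if engine.n < 4:
        result = exhaustive_search(matrix, costs)
        result.seed = seed
        return result
    rng = np.random.default_rng(seed)
    score, adjs, evaluated = _run_search(engine, rng, n_starts, rearrangement, None)
    trees = [adjacency_to_tree(adj, engine.samples) for adj in adjs]
    return SearchResult(int(round(score)), trees, evaluated, seed)


def exhaustive_search(matrix, costs: CostMatrix | None = None,
                      max_taxa: int = 9) -> SearchResult:
    """Score every unrooted binary topology; return all optima.

    Guarded by ``max_taxa`` because the count grows as (2n-5)!!; larger
    problems belong to :func:`heuristic_search`.
    """
    engine = _as_engine(matrix, costs)
    if engine.n > max_taxa:
        raise ValueError(
            f"{engine.n} taxa exceed max_taxa={max_taxa}; use heuristic_search")
    if engine.n < 3:
        raise ValueError("need at least 3 taxa")
    best_score = None
    best_adjs: list[Adjacency] = []
    evaluated = 0
    for adj in enumerate_topologies(engine.n):
        score = engine.score(adj)
        evaluated += 1
        if best_score is None or score < best_score - 1e-9:
            best_score = score
            best_adjs = [adj]
        elif abs(score - best_score) <= 1e-9:
            best_adjs.append(adj)
    trees = [adjacency_to_tree(adj, engine.samples) for adj in best_adjs]
    return SearchResult(int(round(best_score)), trees, evaluated)


# -- bootstrap ------------------------------------------------------------


def bootstrap(matrix, costs: CostMatrix | None = None, n_reps: int = 1000,
              n_starts: int = 2, rearrangement: str = "spr",
              seed: int | None = None) -> BootstrapResult:
    """Character (column) bootstrap with majority-rule consensus.

    Each pseudo-replicate resamples columns with replacement to the original
    count, reruns the heuristic search, and contributes the bipartitions of one
    best tree (the first found, deterministic under the replicate's seed).
    Support is the percentage of replicates containing a bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    engine = _as_engine(matrix, costs)
    labels = engine.samples
    tally: Counter = Counter()
    all_labels = frozenset(labels)
    ref = min(labels)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for ss in streams:
        rng = np.random.default_rng(ss)
        weights = engine.resample_weights(rng)
        _, adjs, _ = _run_search(engine, rng, n_starts, rearrangement, weights)
        for split in _adj_splits(adjs[0], engine.n):
            side = frozenset(labels[i] for i in split)
            if ref in side:
                side = all_labels - side
            tally[side] += 1
    supports = {split: 100.0 * count / n_reps for split, count in tally.items()}
    consensus = majority_rule_consensus(supports, labels)
    return BootstrapResult(supports, consensus, n_reps)


def majority_rule_consensus(supports: dict[frozenset, float],
                            labels: list[str]) -> PhyloTree:
    """Build the strict-majority (>50%) consensus tree from split supports.

    Splits above 50% are pairwise compatible, so they nest when rooted at the
    reference leaf and can be assembled by containment.
    """
    ref = min(labels)
    majority = sorted(
        ((set(s), pct) for s, pct in supports.items() if pct > 50.0 and ref not in s),
        key=lambda item: -len(item[0]))
    tree = PhyloTree()
    root = tree.add_node()
    ref_node = tree.add_node(ref)
    tree.connect(root, ref_node)
    clade_nodes: list[tuple[set, int]] = []  # insertion order = decreasing size
    for side, pct in majority:
        parent = root
        for other, node in clade_nodes:
            if side < other:
                parent = node  # most recent (smallest) strict superset wins
        clade = tree.add_node()
        tree.connect(parent, clade, support=pct)
        clade_nodes.append((side, clade))
    for label in sorted(set(labels) - {ref}):
        parent = root
        for other, node in clade_nodes:
            if label in other:
                parent = node
        leaf = tree.add_node(label)
        tree.connect(parent, leaf)
    tree.suppress_degree_two()
    return tree


def annotate_supports(tree: PhyloTree, supports: dict[frozenset, float]) -> PhyloTree:
    """Copy ``tree`` with bootstrap supports written onto matching branches."""
    out = tree.copy()
    for split, (u, v) in out.bipartition_map().items():
        if split in supports:
            out.branch(u, v).support = supports[split]
    return out
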