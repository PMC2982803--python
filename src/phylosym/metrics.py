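"""Comparative analytics between community trees and host trees.

These are the quantities used to judge whether a microbial-community tree
recapitulates its host phylogeny: Robinson-Foulds distance, a congruence test
against explicit monophyly/sisterhood constraints, the exact probability that a
random unrooted binary topology satisfies those constraints, the apportionment
of branch length between species-discriminating internal branches and terminal
(individual) branches, the correlation between matched internal branch lengths
of two congruent trees, and the technical-replicate read-overlap statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from . import clustering
from .treeops import (
    PhyloTree,
    adjacency_to_tree,
    count_rooted_topologies,
    count_topologies,
    enumerate_topologies,
)

__all__ = [
    "CongruenceConstraints",
    "TopologyMismatchError",
    "rf_distance",
    "is_congruent",
    "count_topologies",
    "congruence_probability",
    "congruent_topology_count",
    "conspecific_constraints",
    "branch_apportionment",
    "internal_branch_correlation",
    "replicate_overlap",
]


class TopologyMismatchError(ValueError):
    """Raised when an operation requires two trees with identical topology."""


@dataclass(frozen=True)
class CongruenceConstraints:
    """Monophyly constraints in the unrooted sense.

    ``groups`` are disjoint leaf sets, each required to be separated from its
    complement by some bipartition; ``sisters`` are pairs of group indices
    whose union must additionally be separated (the two groups are adjacent).
    """

    groups: tuple[frozenset, ...]
    sisters: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        seen: set = set()
        for g in self.groups:
            if seen & g:
                raise ValueError("constraint groups must be disjoint")
            seen |= g
        used: set[int] = set()
        for i, j in self.sisters:
            if i == j or not (0 <= i < len(self.groups)) or not (0 <= j < len(self.groups)):
                raise ValueError("sister pairs must reference two distinct groups")
            if i in used or j in used:
                raise ValueError("a group may appear in at most one sister pair")
            used |= {i, j}


def conspecific_constraints(species_map: dict[str, str],
                            sister_species: list[tuple[str, str]] = ()
                            ) -> CongruenceConstraints:
    """Build constraints requiring each species' samples monophyletic, plus
    optional sisterhood between named species pairs."""
    species = sorted(set(species_map.values()))
    groups = tuple(frozenset(s for s, sp in species_map.items() if sp == name)
                   for name in species)
    index = {name: i for i, name in enumerate(species)}
    sisters = tuple((index[a], index[b]) for a, b in sister_species)
    return CongruenceConstraints(groups, sisters)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError("trees must share the same leaf set")
    return len(t1.bipartitions() ^ t2.bipartitions())


def _separated(splits: set[frozenset], all_labels: frozenset,
               side: frozenset) -> bool:
    if len(side) <= 1 or len(side) >= len(all_labels) - 1:
        return True  # trivial splits always exist on a tree
    comp = all_labels - side
    return side in splits or comp in splits


def is_congruent(tree: PhyloTree, constraints: CongruenceConstraints) -> bool:
    """True iff every constrained group (and every sister-pair union) is
    separated from its complement by some bipartition of ``tree``."""
    all_labels = frozenset(tree.leaf_labels)
    for g in constraints.groups:
        if not g <= all_labels:
            raise ValueError("constraint leaves missing from tree")
    splits = tree.bipartitions()
    for g in constraints.groups:
        if not _separated(splits, all_labels, g):
            return False
    for i, j in constraints.sisters:
        union = constraints.groups[i] | constraints.groups[j]
        if not _separated(splits, all_labels, frozenset(union)):
            return False
    return True


def congruent_topology_count(n_leaves: int,
                             constraints: CongruenceConstraints) -> int:
    """Number of unrooted binary topologies on ``n_leaves`` satisfying the
    constraints, by supertaxon collapse.

    Each required-monophyletic group collapses to a supertaxon contributing
    ``(2m-3)!!`` internal arrangements (rooted shapes on its m leaves); a
    sister pair of groups collapses to one supertaxon whose two children are
    the groups' subtrees.  The collapsed supertaxa then combine freely.
    """
    in_sister = {i for pair in constraints.sisters for i in pair}
    arrangements = 1
    n_super = n_leaves - sum(len(g) for g in constraints.groups)
    if n_super < 0:
        raise ValueError("constraints reference more leaves than the tree has")
    for i, g in enumerate(constraints.groups):
        arrangements *= count_rooted_topologies(len(g))
        if i not in in_sister:
            n_super += 1
    n_super += len(constraints.sisters)
    if n_super >= 3:
        arrangements *= count_topologies(n_super)
    return arrangements


def congruence_probability(n_leaves: int, constraints: CongruenceConstraints,
                           method: str = "collapse") -> Fraction:
    """Exact probability that a uniformly random unrooted binary topology
    satisfies the constraints.

    ``method='enumerate'`` cross-checks by scoring every topology with
    :func:`is_congruent` (guarded to small n).
    """
    total = count_topologies(n_leaves)
    if method == "collapse":
        return Fraction(congruent_topology_count(n_leaves, constraints), total)
    if method != "enumerate":
        raise ValueError("method must be 'collapse' or 'enumerate'")
    if n_leaves > 8:
        raise ValueError("full enumeration is limited to 8 leaves")
    labels = sorted({leaf for g in constraints.groups for leaf in g})
    extra = [f"_free{i}" for i in range(n_leaves - len(labels))]
    labels = sorted(labels + extra)
    hits = 0
    for adj in enumerate_topologies(n_leaves):
        if is_congruent(adjacency_to_tree(adj, labels), constraints):
            hits += 1
    return Fraction(hits, total)


# -- branch-length analytics ----------------------------------------------


def branch_apportionment(tree: PhyloTree, species_map: dict[str, str]
                         ) -> tuple[float, float]:
    """Fractions of total branch length on (species-discriminating internal
    branches, terminal branches).

    A species-discriminating branch is an internal branch whose bipartition
    keeps every species' samples on one side, i.e. the branches that survive
    collapsing each species to a single tip.  The two fractions need not sum
    to 1 if other internal branches exist.
    """
    if tree.leaf_labels != set(species_map):
        raise ValueError("species map must cover exactly the tree leaves")
    total = tree.total_length()
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    by_species: dict[str, set] = {}
    for sample, sp in species_map.items():
        by_species.setdefault(sp, set()).add(sample)
    terminal = 0.0
    discriminating = 0.0
    leaves = set(tree.leaves())
    for split, (u, v) in tree.bipartition_map(include_trivial=True).items():
        length = tree.branch(u, v).length
        if u in leaves or v in leaves:
            terminal += length
        elif all(members <= split or not (members & split)
                 for members in by_species.values()):
            discriminating += length
    return discriminating / total, terminal / total


def internal_branch_correlation(t1: PhyloTree, t2: PhyloTree,
                                relative: bool = True) -> tuple[float, float]:
    """Pearson correlation (and r²) between matched internal branch lengths.

    Trees must have identical topologies; branches are matched by bipartition.
    With ``relative=True`` each tree's internal lengths are first normalized to
    sum to 1.  Zero variance in either vector yields ``(nan, nan)``.
    """
    if rf_distance(t1, t2) != 0:
        raise TopologyMismatchError("trees must have identical topologies")
    m1 = t1.bipartition_map()
    m2 = t2.bipartition_map()
    splits = sorted(m1, key=sorted)
    if len(splits) < 3:
        raise ValueError("need at least 3 internal branches")
    x = np.array([t1.branch(*m1[s]).length for s in splits], dtype=float)
    y = np.array([t2.branch(*m2[s]).length for s in splits], dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("all matched internal branches need lengths")
    if relative:
        x = x / x.sum()
        y = y / y.sum()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


# -- technical-replicate overlap ------------------------------------------


def replicate_overlap(reads_a: list[tuple[str, str]],
                      reads_b: list[tuple[str, str]],
                      class_references: dict[str, str],
                      max_divergence: float = 0.5) -> float:
    """Fraction of reads in A with no match in B at the given divergence.

    Reads are ``(sequence, class_label)`` pairs; a read in A matches when some
    read in B of the same class has pairwise identity >= 100 - max_divergence
    under the clustering identity rules (class-reference-guided alignment,
    terminal gaps excluded, internal gaps counted as differences).
    """
    if not reads_a or not reads_b:
        raise ValueError("both read sets must be non-empty")
    threshold = 100.0 - max_divergence
    unmatched = 0
    by_class_a: dict[str, list[str]] = {}
    by_class_b: dict[str, list[str]] = {}
    for seq, cls in reads_a:
        by_class_a.setdefault(cls, []).append(seq)
    for seq, cls in reads_b:
        by_class_b.setdefault(cls, []).append(seq)
    for cls, seqs_a in by_class_a.items():
        seqs_b = by_class_b.get(cls)
        if seqs_b is None:
            unmatched += len(seqs_a)
            continue
        uniq_a = sorted(set(seqs_a))
        uniq_b = sorted(set(seqs_b))
        aln = clustering.align_sequences(uniq_a + uniq_b, class_references[cls])
        n_a = len(uniq_a)
        rows_a = np.arange(n_a)
        rows_b = np.arange(n_a, n_a + len(uniq_b))
        matched: set[int] = set()
        pairs = clustering.candidate_pairs(aln, within=False, split=n_a)
        if pairs.size:
            ident = clustering.pairwise_identities(aln, pairs[:, 0], pairs[:, 1])
            hit = ~np.isnan(ident) & (ident >= threshold)
            matched = {int(i) for i in np.unique(pairs[hit, 0])}
        lookup = {seq: (i in matched) for i, seq in enumerate(uniq_a)}
        unmatched += sum(1 for seq in seqs_a if not lookup[seq])
    return unmatched / len(reads_a)
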