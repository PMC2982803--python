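"""Species-level OTUs at a 99.5% identity threshold via Markov clustering.

Pipeline per taxonomic class: dereplicate reads into unique sequence types,
align every type to the class exemplar (reference-guided multiple alignment:
pairwise alignments merged on reference coordinates, with insertion columns
stacked after their reference column), compute pairwise percent identities
excluding terminal gaps, connect types at >= 99.5% identity into a weighted
graph, and cluster the graph with the Markov Clustering (MCL) algorithm at
inflation 1.5.  Clusters become OTUs carrying per-sample read counts; OTUs
present in two or more samples are *shared* and feed the phylogenetic
analysis, singletons are *unique*.

Identity convention: compared columns are those inside both rows' aligned
spans where at least one row has a base; a column where exactly one row has a
gap counts as one difference; columns where both rows are gapped (e.g. an
insertion neither carries) are not compared.  Terminal gap runs at either
row's 5' or 3' end are excluded entirely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np

__all__ = [
    "UniqueSequenceType",
    "ClassAlignment",
    "OTU",
    "dereplicate",
    "align_sequences",
    "align_class",
    "pairwise_identity",
    "pairwise_identities",
    "class_edges",
    "candidate_pairs",
    "build_similarity_graph",
    "mcl_cluster",
    "cluster_class",
    "make_otus",
    "partition_otus",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_GAP = 0
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN", start=1):
    _CODE[_b] = _i


@dataclass
class UniqueSequenceType:
    """A dereplicated sequence: identical reads (up to the length-trimming
    rule: a read that is a prefix of another is the same type) merged, with
    per-sample multiplicities.  The canonical sequence is the longest member."""

    canonical: str
    multiplicity: dict[str, int] = field(default_factory=dict)
    read_ids: list[str] = field(default_factory=list)
    class_label: str | None = None

    @property
    def total(self) -> int:
        return sum(self.multiplicity.values())


def dereplicate(reads) -> list[UniqueSequenceType]:
    """Merge reads identical after truncating the longer to the shorter.

    Reads are objects with ``read_id``, ``sample_id`` and ``sequence``.
    Processing distinct sequences from longest to shortest, a sequence joins
    the lexicographically smallest existing canonical it prefixes, else opens
    a new type.  Types are returned sorted by (-total count, canonical).
    """
    reads = list(reads)
    if not reads:
        raise ValueError("no reads to dereplicate")
    distinct = sorted({r.sequence for r in reads}, key=lambda s: (-len(s), s))
    canonicals: list[str] = []  # kept lexicographically sorted
    assign: dict[str, str] = {}
    import bisect
    for seq in distinct:
        pos = bisect.bisect_left(canonicals, seq)
        if pos < len(canonicals) and canonicals[pos].startswith(seq):
            assign[seq] = canonicals[pos]
        else:
            bisect.insort(canonicals, seq)
            assign[seq] = seq
    types: dict[str, UniqueSequenceType] = {}
    for read in reads:
        canon = assign[read.sequence]
        t = types.get(canon)
        if t is None:
            t = types[canon] = UniqueSequenceType(canonical=canon)
        sample = getattr(read, "sample_id", None) or "_unassigned"
        t.multiplicity[sample] = t.multiplicity.get(sample, 0) + 1
        t.read_ids.append(read.read_id)
    out = sorted(types.values(), key=lambda t: (-t.total, t.canonical))
    for t in out:
        t.read_ids.sort()
    return out


@dataclass
class ClassAlignment:
    """Reference-guided multiple alignment of one class's unique types.

    ``columns`` labels each matrix column: ``("ref", i)`` for 0-based
    reference position ``i`` or ``("ins", i, j)`` for the j-th stacked
    insertion column after reference position ``i``.  ``rows`` holds base
    codes (0 = gap); ``starts``/``ends`` delimit each row's aligned span
    (inclusive), outside of which gaps are terminal.
    """

    columns: list[tuple]
    rows: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    sequences: list[str]
    excluded: list[int] = field(default_factory=list)  # unalignable row indices

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def ref_start_column(self, row: int) -> int:
        """1-based reference position of the row's first aligned base."""
        label = self.columns[int(self.starts[row])]
        return label[1] + 1


def align_sequences(sequences: list[str], reference: str,
                    max_edit_fraction: float = 0.35) -> ClassAlignment:
    """Align each sequence to the class reference and merge by coordinates.

    Sequences whose best semi-global alignment exceeds ``max_edit_fraction``
    edits are flagged in ``excluded`` (their rows are all-gap) and should not
    enter the similarity graph.
    """
    n = len(sequences)
    placed: list[dict | None] = []
    ins_max: dict[int, int] = {}
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    for seq in sequences:
        res = edlib.align(seq, reference, mode="HW", task="path")
        if res["editDistance"] > max_edit_fraction * len(seq):
            placed.append(None)
            continue
        start = res["locations"][0][0]
        cigar = res["cigar"]
        # Unit-cost alignment may represent a substitution as an indel pair,
        # destabilising columns between near-identical sequences.  Prefer a
        # gapless placement whenever its mismatch count does not exceed the
        # edit distance plus the indel bases it replaces (the choice an
        # affine gap penalty would make).
        n_indel = sum(int(c) for c, op in _CIGAR_RE.findall(cigar)
                      if op in "ID")
        if n_indel:
            L = len(seq)
            seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            best_h, best_s = None, None
            for s in range(max(0, start - 3),
                           min(len(reference) - L, start + 3) + 1):
                h = int((seq_arr != ref_arr[s:s + L]).sum())
                if best_h is None or h < best_h:
                    best_h, best_s = h, s
            if best_h is not None and best_h <= res["editDistance"] + n_indel:
                start = best_s
                cigar = f"{L}M"
        cells: dict[int, int] = {}          # ref position -> base code (0 gap)
        inserts: dict[int, list[int]] = {}  # after ref position -> base codes
        qpos = 0
        tpos = start
        for count, op in _CIGAR_RE.findall(cigar):
            count = int(count)
            if op in "=XM":
                for _ in range(count):
                    cells[tpos] = int(_CODE[ord(seq[qpos])])
                    qpos += 1
                    tpos += 1
            elif op == "D":  # gap in query
                for _ in range(count):
                    cells[tpos] = _GAP
                    tpos += 1
            else:  # I: insertion in query, stacked after previous ref position
                anchor = tpos - 1
                lst = inserts.setdefault(anchor, [])
                for _ in range(count):
                    lst.append(int(_CODE[ord(seq[qpos])]))
                    qpos += 1
        for anchor, lst in inserts.items():
            ins_max[anchor] = max(ins_max.get(anchor, 0), len(lst))
        placed.append({"cells": cells, "inserts": inserts,
                       "start": start, "end": tpos - 1})

    columns: list[tuple] = []
    col_of_ref: dict[int, int] = {}
    ins_col: dict[tuple[int, int], int] = {}
    for i in range(len(reference)):
        col_of_ref[i] = len(columns)
        columns.append(("ref", i))
        for j in range(ins_max.get(i, 0)):
            ins_col[(i, j)] = len(columns)
            columns.append(("ins", i, j))
    rows = np.zeros((n, len(columns)), dtype=np.uint8)
    starts = np.zeros(n, dtype=np.int64)
    ends = np.zeros(n, dtype=np.int64)
    excluded: list[int] = []
    for r, info in enumerate(placed):
        if info is None:
            excluded.append(r)
            ends[r] = -1
            continue
        for refpos, code in info["cells"].items():
            rows[r, col_of_ref[refpos]] = code
        for anchor, lst in info["inserts"].items():
            for j, code in enumerate(lst):
                rows[r, ins_col[(anchor, j)]] = code
        starts[r] = col_of_ref[info["start"]]
        end_col = col_of_ref[info["end"]]
        # the span extends over any insertion columns the row occupies at its end
        for j in range(ins_max.get(info["end"], 0)):
            if rows[r, ins_col[(info["end"], j)]] != _GAP:
                end_col = ins_col[(info["end"], j)]
        ends[r] = end_col
    return ClassAlignment(columns, rows, starts, ends, list(sequences), excluded)


def align_class(types: list[UniqueSequenceType], class_reference: str,
                max_edit_fraction: float = 0.35) -> ClassAlignment:
    """Reference-guided alignment of a class's unique sequence types."""
    if not types:
        raise ValueError("no types to align")
    labels = {t.class_label for t in types if t.class_label is not None}
    if len(labels) > 1:
        raise ValueError("all types must share one class label")
    return align_sequences([t.canonical for t in types], class_reference,
                           max_edit_fraction)


# -- identities ------------------------------------------------------------


def pairwise_identities(aln: ClassAlignment, ia: np.ndarray, ib: np.ndarray,
                        chunk: int = 16384) -> np.ndarray:
    """Percent identity for row pairs (ia[k], ib[k]); NaN when no overlap."""
    ia = np.asarray(ia, dtype=np.int64)
    ib = np.asarray(ib, dtype=np.int64)
    out = np.empty(ia.size)
    cols = np.arange(aln.rows.shape[1])
    for lo in range(0, ia.size, chunk):
        hi = min(lo + chunk, ia.size)
        A = aln.rows[ia[lo:hi]]
        B = aln.rows[ib[lo:hi]]
        span_lo = np.maximum(aln.starts[ia[lo:hi]], aln.starts[ib[lo:hi]])[:, None]
        span_hi = np.minimum(aln.ends[ia[lo:hi]], aln.ends[ib[lo:hi]])[:, None]
        in_span = (cols >= span_lo) & (cols <= span_hi)
        nz_a = A != _GAP
        nz_b = B != _GAP
        compared = in_span & (nz_a | nz_b)
        matches = compared & nz_a & nz_b & (A == B)
        n_comp = compared.sum(axis=1)
        n_match = matches.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[lo:hi] = np.where(n_comp > 0, 100.0 * n_match / n_comp, np.nan)
    return out


def pairwise_identity(aln: ClassAlignment, i: int, j: int) -> float:
    """Percent identity between two rows of a class alignment (terminal gaps
    excluded; internal one-sided gaps count as differences)."""
    return float(pairwise_identities(aln, np.array([i]), np.array([j]))[0])


class _BitPlanes:
    """Bit-sliced alignment rows: three base bitplanes plus a nonzero plane,
    packed 64 columns per word, so pairwise difference and compared-column
    counts reduce to bitwise ops and popcounts."""

    def __init__(self, aln: ClassAlignment):
        rows = aln.rows
        n, C = rows.shape
        self.n_words = W = (C + 63) // 64
        padded = np.zeros((n, W * 64), dtype=np.uint8)
        padded[:, :C] = rows
        self.planes = [
            np.packbits((padded >> p) & 1, axis=1,
                        bitorder="little").view(np.uint64)
            for p in range(3)]
        self.nonzero = np.packbits(padded != 0, axis=1,
                                   bitorder="little").view(np.uint64)
        self.starts = aln.starts.astype(np.int64)
        self.ends = aln.ends.astype(np.int64)


def _span_word_masks(S: np.ndarray, E: np.ndarray, word: int) -> np.ndarray:
    """Per-pair uint64 mask selecting the span's columns inside one word."""
    lo = np.maximum(S, 64 * word)
    hi = np.minimum(E, 64 * word + 63)
    length = hi - lo + 1
    ones = np.uint64(0xFFFFFFFFFFFFFFFF)
    shift_r = np.clip(64 - length, 0, 63).astype(np.uint64)
    base = np.right_shift(ones, shift_r)
    mask = np.left_shift(base, np.clip(lo - 64 * word, 0, 63).astype(np.uint64))
    return np.where(length > 0, mask, np.uint64(0))


def class_edges(aln: ClassAlignment, threshold: float = 99.5,
                block: int = 512) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All row pairs at identity >= threshold, by blocked bit-sliced
    comparison: O(n² · words) bit operations with O(block · n) memory, which
    keeps abundant error-rich classes tractable without any candidate
    heuristics.  Returns (i, j, identity) arrays with i < j.

    Agrees exactly with :func:`pairwise_identities` (the byte-level route,
    kept as the small-scale reference implementation).
    """
    bp = _BitPlanes(aln)
    n = aln.n_rows
    ok = np.ones(n, dtype=bool)
    ok[aln.excluded] = False
    out_i: list[np.ndarray] = []
    out_j: list[np.ndarray] = []
    out_v: list[np.ndarray] = []
    for a0 in range(0, n, block):
        a1 = min(a0 + block, n)
        rows_a = np.arange(a0, a1)
        cols_b = np.arange(a0, n)  # upper triangle only
        S = np.maximum(bp.starts[rows_a][:, None], bp.starts[cols_b][None, :])
        E = np.minimum(bp.ends[rows_a][:, None], bp.ends[cols_b][None, :])
        diffs = np.zeros((rows_a.size, cols_b.size), dtype=np.int32)
        compared = np.zeros_like(diffs)
        for w in range(bp.n_words):
            mask = _span_word_masks(S, E, w)
            neq = np.zeros_like(mask)
            for plane in bp.planes:
                neq |= plane[rows_a, w][:, None] ^ plane[cols_b, w][None, :]
            union = bp.nonzero[rows_a, w][:, None] | bp.nonzero[cols_b, w][None, :]
            diffs += np.bitwise_count(neq & mask).astype(np.int32)
            compared += np.bitwise_count(union & mask).astype(np.int32)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(compared > 0,
                             100.0 * (compared - diffs) / compared, np.nan)
        hit = (compared > 0) & (ident >= threshold)
        hit &= rows_a[:, None] < cols_b[None, :]
        hit &= ok[rows_a][:, None] & ok[cols_b][None, :]
        ii, jj = np.nonzero(hit)
        out_i.append(rows_a[ii])
        out_j.append(cols_b[jj])
        out_v.append(ident[ii, jj])
    if not out_i:
        empty = np.empty(0)
        return empty.astype(np.int64), empty.astype(np.int64), empty
    return (np.concatenate(out_i), np.concatenate(out_j),
            np.concatenate(out_v))


def candidate_pairs(aln: ClassAlignment, within: bool = True,
                    split: int | None = None, window: int = 32,
                    all_pairs_max: int = 700) -> np.ndarray:
    """Row pairs worth an exact identity computation, as an (k, 2) int array.

    For small alignments this is simply all pairs.  For large ones, rows are
    bucketed by exact content over fixed non-overlapping column windows; any
    pair at >= 99.5% identity differs in at most ``floor(0.005 * span)``
    compared columns, which can spoil at most that many windows, so two
    qualifying rows always share at least one clean window whenever their
    overlap spans two more windows than their difference budget (true for all
    spans the length filter admits).  Pairs sharing a bucket are candidates;
    identity is then computed exactly, so the prefilter only affects speed,
    never which edges exist.  Pair codes are deduplicated in numpy chunks to
    keep memory bounded on abundant, error-rich classes.

    ``within=False`` with ``split=k`` restricts to cross pairs (i < k <= j).
    """
    n = aln.n_rows
    ok = np.ones(n, dtype=bool)
    ok[aln.excluded] = False
    idx = np.flatnonzero(ok)
    if n <= all_pairs_max:
        iu, ju = np.triu_indices(idx.size, 1)
        pairs = np.column_stack([idx[iu], idx[ju]])
        return _orient_pairs(pairs, within, split)
    buckets: dict[tuple[int, bytes], list[int]] = {}
    for r in idx:
        w0 = (aln.starts[r] + window - 1) // window
        w1 = (aln.ends[r] + 1) // window
        row = aln.rows[r]
        for w in range(int(w0), int(w1)):
            key = (w, row[w * window:(w + 1) * window].tobytes())
            buckets.setdefault(key, []).append(int(r))
    uniq = np.empty(0, dtype=np.int64)
    buffer: list[np.ndarray] = []
    buffered = 0
    seen_sets: set[int] = set()  # identical member sets recur across windows
    for members in buckets.values():
        m = len(members)
        if m < 2:
            continue
        key = hash(tuple(members))
        if key in seen_sets:
            continue
        seen_sets.add(key)
        arr = np.asarray(members, dtype=np.int64)  # ascending by construction
        iu, ju = np.triu_indices(m, 1)
        buffer.append(arr[iu] * n + arr[ju])
        buffered += iu.size
        if buffered > 16_000_000:
            uniq = np.unique(np.concatenate([uniq] + buffer))
            buffer, buffered = [], 0
    if buffer:
        uniq = np.unique(np.concatenate([uniq] + buffer))
    pairs = np.column_stack([uniq // n, uniq % n])
    return _orient_pairs(pairs, within, split)


def _orient_pairs(pairs: np.ndarray, within: bool,
                  split: int | None) -> np.ndarray:
    if within or split is None:
        return pairs
    cross = (pairs[:, 0] < split) != (pairs[:, 1] < split)
    pairs = pairs[cross]
    flip = pairs[:, 0] >= split
    pairs[flip] = pairs[flip][:, ::-1]
    return pairs


# -- graph + MCL -----------------------------------------------------------


def build_similarity_graph(n_nodes: int,
                           identities: list[tuple[int, int, float]],
                           node_weights: list[float] | None = None,
                           threshold: float = 99.5) -> nx.Graph:
    """Similarity graph over unique types: an undirected edge wherever
    identity >= threshold (inclusive), weighted by identity, plus a
    weight-100 self-loop on every node."""
    g = nx.Graph()
    for i in range(n_nodes):
        weight = 1.0 if node_weights is None else node_weights[i]
        g.add_node(i, multiplicity=weight)
        g.add_edge(i, i, weight=100.0)
    for i, j, ident in identities:
        if i != j and not np.isnan(ident) and ident >= threshold:
            g.add_edge(i, j, weight=float(ident))
    return g


def _mcl_iterate_dense(A: np.ndarray, inflation: float, expansion: int,
                       max_iter: int, tol: float) -> tuple[np.ndarray, bool]:
    M = A / A.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        P = np.linalg.matrix_power(M, expansion)
        P /= P.sum(axis=0, keepdims=True)
        P **= inflation
        P /= P.sum(axis=0, keepdims=True)
        P[P < 1e-12] = 0.0
        s = P.sum(axis=0, keepdims=True)
        s[s == 0] = 1.0
        P /= s
        delta = np.abs(P - M).max()
        M = P
        if delta < tol:
            return M, True
    return M, False


def _prune_columns(m, prune: float, max_per_col: int):
    """Threshold + per-column top-R pruning (csc in, csc out), as production
    MCL implementations do to keep the flow matrix sparse."""
    m = m.tocsc()
    m.data[m.data < prune] = 0.0
    m.eliminate_zeros()
    counts = np.diff(m.indptr)
    if (counts > max_per_col).any():
        for j in np.flatnonzero(counts > max_per_col):
            lo, hi = m.indptr[j], m.indptr[j + 1]
            seg = m.data[lo:hi]
            # hard cap by index: a value threshold cannot shrink a column of
            # equal entries (symmetric spokes), so drop all but the largest R
            drop = np.argpartition(seg, seg.size - max_per_col)[
                :seg.size - max_per_col]
            seg[drop] = 0.0
        m.eliminate_zeros()
    return m


def _mcl_iterate_sparse(A, inflation: float, expansion: int, max_iter: int,
                        tol: float, prune: float = 1e-7,
                        max_per_col: int = 300) -> tuple["object", bool]:
    """Flow iteration with pruning, as production MCL does, so that large
    hub-and-spoke components stay tractable (the dense matrix power is
    cubic).  Entries below ``prune`` — and, in overfull columns, everything
    outside the ``max_per_col`` largest entries — are dropped after each
    step; the surviving flow is renormalized, which accelerates convergence
    toward the natural attractors without changing which ones win."""
    import scipy.sparse as sp

    n = A.shape[0]

    def colnorm(m):
        s = np.asarray(m.sum(axis=0)).ravel()
        s[s == 0] = 1.0
        return m @ sp.diags(1.0 / s)

    def square_pruned(m):
        blocks = []
        step = 2048
        for lo in range(0, n, step):
            b = _prune_columns((m @ m[:, lo:lo + step]).tocsc(),
                               prune, max_per_col)
            blocks.append(b)
        return sp.hstack(blocks, format="csc") if len(blocks) > 1 else blocks[0]

    M = colnorm(A.tocsc())
    for _ in range(max_iter):
        P = M
        for _ in range(expansion - 1):
            P = square_pruned(P)
        P = colnorm(P)
        P.data **= inflation
        P = _prune_columns(colnorm(P), prune, max_per_col)
        P = colnorm(P)
        delta = abs(P - M).max()
        M = P
        if delta < tol:
            return M, True
    return M, False


def mcl_cluster(graph: nx.Graph, inflation: float = 1.5, expansion: int = 2,
                max_iter: int = 200, tol: float = 1e-6,
                dense_max: int = 1500) -> tuple[list[list[int]], bool]:
    """Markov clustering: expansion (matrix power) alternating with inflation
    (elementwise power + column renormalization) until the flow matrix is
    stable.

    Run independently per connected component (flow cannot cross components);
    components larger than ``dense_max`` use a pruned sparse iteration.
    Attractors are nodes retaining flow on their own column; attractors linked
    by residual flow form one cluster, and every other node joins the cluster
    of the attractor holding most of its column mass (ties to the smallest
    node id).  Returns (clusters, converged).
    """
    import scipy.sparse as sp

    clusters: list[list[int]] = []
    converged = True
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        k = len(nodes)
        if k == 1:
            clusters.append(nodes)
            continue
        index = {u: i for i, u in enumerate(nodes)}
        if k <= dense_max:
            A = np.zeros((k, k))
            for u, v, data in graph.subgraph(comp).edges(data=True):
                w = data.get("weight", 1.0)
                A[index[u], index[v]] = w
                A[index[v], index[u]] = w
            np.fill_diagonal(A, np.maximum(np.diag(A), 1e-12))
            M, ok = _mcl_iterate_dense(A, inflation, expansion, max_iter, tol)
            diag = np.diag(M)
        else:
            rows, cols, vals = [], [], []
            for u, v, data in graph.subgraph(comp).edges(data=True):
                w = data.get("weight", 1.0)
                iu, iv = index[u], index[v]
                rows.append(iu); cols.append(iv); vals.append(w)
                if iu != iv:
                    rows.append(iv); cols.append(iu); vals.append(w)
            A = sp.csc_matrix((vals, (rows, cols)), shape=(k, k))
            M, ok = _mcl_iterate_sparse(A, inflation, expansion, max_iter, tol)
            M = M.tocsc()
            diag = M.diagonal()
        converged = converged and ok
        eps = 1e-6
        attractors = [i for i in range(k) if diag[i] > eps]
        if not attractors:
            clusters.append(nodes)
            continue
        # attractor systems: attractors connected by residual flow
        parent = list(range(k))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x: int, y: int) -> None:
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[max(rx, ry)] = min(rx, ry)

        att_set = set(attractors)
        dense = isinstance(M, np.ndarray)
        att_idx = np.asarray(attractors)
        if dense:
            att_block = M[np.ix_(att_idx, att_idx)]
        else:
            att_block = np.asarray(M[att_idx][:, att_idx].todense())
        for x in range(len(attractors)):
            for y in range(x + 1, len(attractors)):
                if att_block[x, y] > eps or att_block[y, x] > eps:
                    union(attractors[x], attractors[y])
        if dense:
            att_cols = M[att_idx, :]
        else:
            att_cols = np.asarray(M[att_idx].todense())
        assignment: dict[int, list[int]] = {}
        for i in range(k):
            if i in att_set:
                root = find(i)
            else:
                best = attractors[int(np.argmax(att_cols[:, i]))]
                root = find(best)
            assignment.setdefault(root, []).append(i)
        for members in assignment.values():
            clusters.append(sorted(nodes[i] for i in members))
    clusters.sort(key=lambda c: c[0])
    return clusters, converged


# -- OTUs ------------------------------------------------------------------


@dataclass
class OTU:
    otu_id: str
    class_label: str
    phylum: str
    types: list[UniqueSequenceType]
    counts: dict[str, int]
    representative: str
    shared: bool

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def make_otus(clusters: list[list[int]], types: list[UniqueSequenceType],
              class_label: str = "", phylum: str = "",
              id_offset: int = 0) -> list[OTU]:
    """Aggregate clusters of unique types into OTUs.

    The representative is the longest member sequence (the canonical of the
    longest type), ties broken lexicographically; per-sample counts sum the
    member multiplicities.  ``shared`` is set when counts are nonzero in two
    or more samples.
    """
    otus = []
    for idx, cluster in enumerate(clusters):
        members = [types[i] for i in cluster]
        counts: dict[str, int] = {}
        for t in members:
            for sample, c in t.multiplicity.items():
                counts[sample] = counts.get(sample, 0) + c
        rep = min((t.canonical for t in members),
                  key=lambda s: (-len(s), s))
        otus.append(OTU(
            otu_id=f"OTU{id_offset + idx:05d}",
            class_label=class_label,
            phylum=phylum,
            types=members,
            counts=counts,
            representative=rep,
            shared=sum(1 for c in counts.values() if c > 0) >= 2,
        ))
    return otus


def partition_otus(otus: list[OTU]) -> tuple[list[OTU], list[OTU]]:
    """Split into (shared, unique): shared OTUs occur in >= 2 samples."""
    shared = [o for o in otus if o.shared]
    unique = [o for o in otus if not o.shared]
    return shared, unique


def write_otu_table(otus: list[OTU], samples: list[str], path) -> None:
    """TSV: one row per OTU with class, phylum, representative, shared flag
    and per-sample read counts."""
    with open(path, "w") as fh:
        cols = "\t".join(samples)
        fh.write(f"otu_id\tclass\tphylum\tshared\trepresentative\t{cols}\n")
        for o in otus:
            counts = "\t".join(str(o.counts.get(s, 0)) for s in samples)
            fh.write(f"{o.otu_id}\t{o.class_label}\t{o.phylum}\t"
                     f"{int(o.shared)}\t{o.representative}\t{counts}\n")


def write_representative_fasta(otus: list[OTU], path) -> None:
    with open(path, "w") as fh:
        for o in otus:
            fh.write(f">{o.otu_id} class={o.class_label} shared={int(o.shared)}\n"
                     f"{o.representative}\n")


def cluster_class(types: list[UniqueSequenceType], class_reference: str,
                  threshold: float = 99.5, inflation: float = 1.5,
                  max_edit_fraction: float = 0.35
                  ) -> tuple[list[list[int]], ClassAlignment, bool]:
    """Full clustering of one class: align, pair, score, graph, MCL.

    Returns (clusters as type-index lists, the class alignment, converged).
    Types flagged unalignable become singleton clusters.
    """
    aln = align_class(types, class_reference, max_edit_fraction)
    ei, ej, ev = class_edges(aln, threshold=threshold)
    identities = [(int(i), int(j), float(v)) for i, j, v in zip(ei, ej, ev)]
    graph = build_similarity_graph(len(types), identities,
                                   node_weights=[t.total for t in types],
                                   threshold=threshold)
    for i in aln.excluded:
        graph.remove_node(i)
    clusters, converged = mcl_cluster(graph, inflation=inflation)
    clusters += [[i] for i in aln.excluded]
    clusters.sort(key=lambda c: c[0])
    return clusters, aln, converged
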