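"""Dereplication, reference-guided alignment, identity rules, MCL, OTUs."""

import numpy as np
import pytest

from phylosym.clustering import (ClassAlignment, align_sequences,
                                 build_similarity_graph, candidate_pairs,
                                 cluster_class, dereplicate, make_otus,
                                 mcl_cluster, pairwise_identities,
                                 pairwise_identity, partition_otus)


class FakeRead:
    def __init__(self, read_id, sequence, sample_id="s1"):
        self.read_id = read_id
        self.sequence = sequence
        self.sample_id = sample_id


class TestDereplicate:
    def test_identical_reads_merge(self):
        types = dereplicate([FakeRead("a", "ACGTACGT"),
                             FakeRead("b", "ACGTACGT", "s2")])
        assert len(types) == 1
        assert types[0].total == 2
        assert types[0].multiplicity == {"s1": 1, "s2": 1}

    def test_prefix_reads_merge_to_longest(self):
        types = dereplicate([FakeRead("a", "ACGTACGT"),
                             FakeRead("b", "ACGTAC")])
        assert len(types) == 1
        assert types[0].canonical == "ACGTACGT"

    def test_non_prefix_reads_stay_separate(self):
        types = dereplicate([FakeRead("a", "ACGTACGT"),
                             FakeRead("b", "ACGTACGA")])
        assert len(types) == 2

    def test_planted_haplotypes_recovered(self, rng):
        bases = np.array(list("ACGT"))
        haplos = ["".join(rng.choice(bases, 60)) for _ in range(10)]
        reads = [FakeRead(f"r{i}_{j}", h, f"s{j % 3}")
                 for i, h in enumerate(haplos) for j in range(4)]
        types = dereplicate(reads)
        assert len(types) == 10
        assert sorted(t.canonical for t in types) == sorted(haplos)


class TestIdentity:
    def make_alignment(self, rows, starts, ends):
        rows = np.asarray(rows, dtype=np.uint8)
        return ClassAlignment(columns=[("ref", i) for i in range(rows.shape[1])],
                              rows=rows,
                              starts=np.asarray(starts), ends=np.asarray(ends),
                              sequences=["" for _ in range(rows.shape[0])])

    def test_identical_rows_are_100(self):
        row = np.tile([1, 2, 3, 4], 50)
        aln = self.make_alignment([row, row], [0, 0], [199, 199])
        assert pairwise_identity(aln, 0, 1) == 100.0

    def test_one_mismatch_in_200_columns_is_exactly_99_5(self):
        row_a = np.tile([1, 2, 3, 4], 50)
        row_b = row_a.copy()
        row_b[100] = 1 if row_b[100] != 1 else 2
        aln = self.make_alignment([row_a, row_b], [0, 0], [199, 199])
        assert pairwise_identity(aln, 0, 1) == 99.5

    def test_terminal_gap_excluded_internal_mismatch_counted(self):
        """10-column 5' terminal gap on row b, 150 compared columns, one
        internal mismatch: 149/150."""
        row_a = np.tile([1, 2, 3, 4], 40)[:160]
        row_b = row_a.copy()
        row_b[:10] = 0          # terminal gap
        row_b[80] = 4 if row_b[80] != 4 else 3
        aln = self.make_alignment([row_a, row_b], [0, 10], [159, 159])
        assert pairwise_identity(aln, 0, 1) == pytest.approx(100 * 149 / 150)

    def test_internal_one_sided_gap_counts_as_difference(self):
        row_a = np.tile([1, 2, 3, 4], 25)
        row_b = row_a.copy()
        row_b[50] = 0           # internal deletion
        aln = self.make_alignment([row_a, row_b], [0, 0], [99, 99])
        assert pairwise_identity(aln, 0, 1) == pytest.approx(99.0)

    def test_no_overlap_is_nan(self):
        row_a = np.array([1, 2, 3, 4, 0, 0, 0, 0], dtype=np.uint8)
        row_b = np.array([0, 0, 0, 0, 1, 2, 3, 4], dtype=np.uint8)
        aln = self.make_alignment([row_a, row_b], [0, 4], [3, 7])
        assert np.isnan(pairwise_identity(aln, 0, 1))


class TestBitSlicedEdges:
    def test_matches_byte_level_identities_on_random_alignments(self, rng):
        """Dual route: the packed bitwise edge finder must agree exactly with
        the per-column byte comparison on every pair."""
        from phylosym.clustering import class_edges
        ref = "".join(rng.choice(list("ACGT"), 300))
        arr = np.frombuffer(ref.encode(), np.uint8)
        bases = np.frombuffer(b"ACGT", np.uint8)
        seqs = []
        for _ in range(40):
            s = int(rng.integers(0, 60))
            L = int(rng.integers(150, 220))
            seq = arr[s:s + L].copy()
            k = int(rng.integers(0, 4))
            for _ in range(k):
                seq[int(rng.integers(seq.size))] = bases[int(rng.integers(4))]
            seqs.append(seq.tobytes().decode())
        aln = align_sequences(sorted(set(seqs)), ref)
        n = aln.n_rows
        iu, ju = np.triu_indices(n, 1)
        byte_vals = pairwise_identities(aln, iu, ju)
        expected = {(int(i), int(j)): v
                    for i, j, v in zip(iu, ju, byte_vals)
                    if not np.isnan(v) and v >= 99.5}
        ei, ej, ev = class_edges(aln, threshold=99.5)
        got = {(int(i), int(j)): v for i, j, v in zip(ei, ej, ev)}
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)


class TestAlignment:
    def test_identical_sequences_identical_rows(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 300))
        seq = ref[40:240]
        aln = align_sequences([seq, seq], ref)
        np.testing.assert_array_equal(aln.rows[0], aln.rows[1])
        assert aln.ref_start_column(0) == 41

    def test_planted_indel_reproduced(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 300))
        clean = ref[40:240]
        deleted = clean[:100] + clean[101:]
        aln = align_sequences([clean, deleted], ref)
        # the deleted base shows as a single internal one-column gap near the
        # planted position (within a repeat run the exact column is ambiguous)
        span = aln.rows[1][aln.starts[1]:aln.ends[1] + 1]
        gaps = np.flatnonzero(span == 0)
        assert len(gaps) == 1
        assert abs(int(gaps[0]) + int(aln.starts[1]) - (40 + 100)) <= 3
        assert (aln.rows[0] != 0).sum() == 200
        assert pairwise_identity(aln, 0, 1) == pytest.approx(100 * 199 / 200)

    def test_unalignable_sequence_flagged(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 300))
        junk = "".join(rng.choice(list("ACGT"), 200))
        aln = align_sequences([ref[40:240], junk], ref)
        assert aln.excluded == [1]


class TestGraphAndMCL:
    def test_threshold_is_inclusive(self):
        g = build_similarity_graph(2, [(0, 1, 99.5)])
        assert g.has_edge(0, 1)
        g2 = build_similarity_graph(2, [(0, 1, 99.4)])
        assert not g2.has_edge(0, 1) or 0 == 1

    def test_disconnected_edges_stay_separate(self):
        g = build_similarity_graph(4, [(0, 1, 99.9), (2, 3, 99.9)])
        clusters, converged = mcl_cluster(g)
        assert converged
        assert clusters == [[0, 1], [2, 3]]

    def test_singleton_self_loop(self):
        g = build_similarity_graph(1, [])
        clusters, _ = mcl_cluster(g)
        assert clusters == [[0]]

    def test_two_cliques_with_weak_bridge_split(self):
        """Two 4-cliques joined by one minimal-weight edge resolve into two
        clusters; verified against an explicit dense iteration of the same
        8x8 system written out independently below."""
        edges = [(i, j, 100.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j, 100.0) for i in range(4, 8) for j in range(i + 1, 8)]
        edges.append((3, 4, 99.5))
        g = build_similarity_graph(8, edges)
        clusters, converged = mcl_cluster(g)
        assert converged
        assert clusters == [[0, 1, 2, 3], [4, 5, 6, 7]]

        # independent explicit iteration (expansion 2, inflation 1.5)
        A = np.zeros((8, 8))
        for i, j, w in edges:
            A[i, j] = A[j, i] = w
        np.fill_diagonal(A, 100.0)
        M = A / A.sum(0)
        for _ in range(200):
            M = M @ M
            M /= M.sum(0)
            M = M ** 1.5
            M /= M.sum(0)
        left = set(np.flatnonzero(M[:, 0] > 1e-6)) | {0}
        right = set(np.flatnonzero(M[:, 7] > 1e-6)) | {7}
        assert left <= {0, 1, 2, 3} and right <= {4, 5, 6, 7}

    def test_cluster_invariant_to_node_numbering(self):
        edges = [(0, 1, 99.8), (1, 2, 99.7), (3, 4, 99.9)]
        g1 = build_similarity_graph(5, edges)
        perm = {0: 4, 1: 3, 2: 2, 3: 1, 4: 0}
        g2 = build_similarity_graph(5, [(perm[i], perm[j], w)
                                        for i, j, w in edges])
        c1, _ = mcl_cluster(g1)
        c2, _ = mcl_cluster(g2)
        mapped = sorted(sorted(perm[i] for i in c) for c in c1)
        assert mapped == c2


class TestOTUs:
    def make_types(self):
        reads = [FakeRead("a", "ACGTACGTAA", "s1"), FakeRead("b", "ACGTACGTAA", "s1"),
                 FakeRead("c", "ACGTACGTCC", "s2"), FakeRead("d", "TTTTACGTAC", "s1")]
        return dereplicate(reads)

    def test_counts_and_partition(self):
        types = self.make_types()
        otus = make_otus([[0, 1], [2]], types, "cls", "phy")
        by_id = {o.otu_id: o for o in otus}
        assert sum(o.total_reads for o in otus) == 4
        shared, unique = partition_otus(otus)
        assert all(sum(1 for c in o.counts.values() if c) >= 2 for o in shared)
        assert all(sum(1 for c in o.counts.values() if c) == 1 for o in unique)

    def test_representative_is_longest_then_lexicographic(self):
        reads = [FakeRead("a", "ACGTACGT"), FakeRead("b", "ACGTACGTAA"),
                 FakeRead("c", "AAAAACGTAC")]
        types = dereplicate(reads)
        otus = make_otus([list(range(len(types)))], types)
        assert otus[0].representative == "AAAAACGTAC"  # tie on length: lexicographic


class TestEndToEndClustering:
    def test_planted_well_separated_clusters_recovered(self, rng):
        """Planted clusters of radius <= 0.5% separated by >= 2% come back
        exactly as the graph components / MCL clusters."""
        ref = "".join(rng.choice(list("ACGT"), 400))
        centers = []
        arr = np.frombuffer(ref.encode(), np.uint8).copy()
        for c in range(6):
            mutant = arr.copy()
            pos = rng.choice(400, 25, replace=False)  # ~6% apart pairwise
            mutant[pos] = np.frombuffer(b"ACGT", np.uint8)[
                (np.searchsorted([65, 67, 71, 84], mutant[pos]) +
                 rng.integers(1, 4, 25)) % 4]
            centers.append(mutant)
        reads = []
        labels = []
        for ci, center in enumerate(centers):
            for j in range(8):
                seq = center[50:250].copy()
                if j % 2:  # one substitution = 0.5% radius
                    p = int(rng.integers(0, 200))
                    seq[p] = np.frombuffer(b"ACGT", np.uint8)[int(rng.integers(4))]
                reads.append(FakeRead(f"r{ci}_{j}", seq.tobytes().decode(),
                                      f"s{j % 3}"))
                labels.append(ci)
        types = dereplicate(reads)
        clusters, aln, converged = cluster_class(types, ref)
        assert converged
        # map each type back to its planted center and require exact recovery
        type_center = {}
        for t in types:
            src = labels[[r.read_id for r in reads].index(t.read_ids[0])]
            type_center[types.index(t)] = src
        got = sorted(sorted(type_center[i] for i in c) for c in clusters)
        assert all(len(set(c)) == 1 for c in got)
        assert len(clusters) == 6

    def test_read_conservation(self, small_run):
        res = small_run
        assert sum(o.total_reads for o in res.otus) == res.n_kept

    def test_shared_unique_tallies_match_ground_truth(self, fidelity_run):
        """Planted occupancy predicts shared OTUs: a planted taxon whose
        error-free reads survive QC in two or more samples must surface in a
        shared OTU (error-free reads of one taxon are mutually >= 99.5%
        identical regardless of window, so they cannot be split apart)."""
        res = fidelity_run
        ref_seq = res.truth.reference_sequences
        from collections import defaultdict
        occupancy = defaultdict(set)
        for read in res.kept_reads:
            taxon = res.truth.read_to_otu[read.read_id]
            if read.sequence in ref_seq[taxon]:  # error-free payload
                occupancy[taxon].add(read.sample_id)
        expected_shared_taxa = {t for t, ss in occupancy.items() if len(ss) >= 2}
        got_shared_taxa = set()
        for o in res.shared_otus:
            for t in o.types:
                got_shared_taxa.update(res.truth.read_to_otu[r] for r in t.read_ids)
        assert expected_shared_taxa <= got_shared_taxa
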