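"""Quality trimming, demultiplexing, classification and the four-rule filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylosym.preprocess import (ClassAssignment, NaiveBayesClassifier, Read,
                                 classify_read, demultiplex, filter_reads,
                                 locate_start, trim_low_quality_ends)
from phylosym.simulate import synthesize_references


def brute_force_trim(errs, max_error):
    """Oracle: scan every subwindow for the longest one whose end bases and
    mean satisfy the threshold."""
    n = len(errs)
    best = (0, 0)  # (length, start)
    for i in range(n):
        for j in range(i, n):
            window = errs[i:j + 1]
            if window[0] <= max_error and window[-1] <= max_error \
                    and np.mean(window) <= max_error:
                if j - i + 1 > best[0]:
                    best = (j - i + 1, i)
    return best


class TestTrim:
    def test_clean_read_unchanged(self):
        read = Read("r", "A" * 50, np.full(50, 0.001))
        assert trim_low_quality_ends(read).sequence == read.sequence

    def test_hopeless_read_becomes_empty(self):
        read = Read("r", "A" * 30, np.full(30, 0.02))
        assert len(trim_low_quality_ends(read)) == 0

    def test_bad_flanks_trimmed_to_middle_ninety(self):
        errs = np.concatenate([np.full(5, 0.05), np.full(90, 0.001),
                               np.full(5, 0.05)])
        read = Read("r", "ACGTG" * 20, errs)
        trimmed = trim_low_quality_ends(read)
        assert trimmed.sequence == read.sequence[5:95]
        assert brute_force_trim(errs, 0.005) == (90, 5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        errs = rng.choice([0.001, 0.003, 0.01, 0.05], size=n)
        read = Read("r", "A" * n, errs)
        trimmed = trim_low_quality_ends(read)
        length, start = brute_force_trim(errs, 0.005)
        assert len(trimmed) == length
        if length:
            assert trimmed.sequence == read.sequence[start:start + length]


class TestDemultiplex:
    PRIMER = "GGATTAGATACCC"

    def reads(self, seqs):
        return [Read(f"r{i}", s, np.full(len(s), 0.001))
                for i, s in enumerate(seqs)]

    def test_exact_prefix_assigned_and_stripped(self):
        payload = "ACGTACGTACGT"
        reads = self.reads(["ACGT" + self.PRIMER + payload])
        out = demultiplex(reads, {"s1": "ACGT"}, self.PRIMER)
        assert out[0].sample_id == "s1"
        assert out[0].sequence == payload
        assert len(out[0].error_probs) == len(payload)

    def test_single_mismatch_removed(self):
        reads = self.reads(["ACGA" + self.PRIMER + "ACGTACGT",
                            "ACGT" + self.PRIMER[:-1] + "A" + "ACGTACGT"])
        assert demultiplex(reads, {"s1": "ACGT"}, self.PRIMER) == []

    def test_ambiguous_barcodes_rejected(self):
        # with primer GGG, barcode "ACG" + primer is a prefix of "ACGG" + primer
        with pytest.raises(ValueError):
            demultiplex([], {"s1": "ACG", "s2": "ACGG"}, "GGG")

    def test_planted_clean_counts_recovered(self, fidelity_run):
        truth = fidelity_run.truth
        expected_demux = sum(1 for v in truth.expected_rule.values()
                             if v != "demux")
        assert fidelity_run.n_demultiplexed == expected_demux


class TestClassifier:
    @pytest.fixture(scope="class")
    @staticmethod
    def refs():
        return synthesize_references(20, 4, seed=1)

    def test_reference_self_classification(self, refs):
        clf = NaiveBayesClassifier(refs)
        rng = np.random.default_rng(0)
        for taxon in refs[:8]:
            label, phylum, conf = clf.classify(taxon.sequence, 100, rng)
            assert label == taxon.class_label
            assert phylum == taxon.phylum
            assert conf >= 99.0

    def test_random_reads_have_low_confidence(self, refs):
        """i.i.d. random reads sit between classes: bootstrap confidence
        hovers near chance and falls below the 70% filter in most cases."""
        clf = NaiveBayesClassifier(refs)
        rng = np.random.default_rng(1)
        below = 0
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 150))
            _, _, conf = clf.classify(seq, 100, rng)
            below += conf < 70.0
        assert below >= 70

    def test_noisy_reads_classified_to_source(self, refs):
        clf = NaiveBayesClassifier(refs)
        rng = np.random.default_rng(2)
        correct = 0
        n = 100
        for i in range(n):
            taxon = refs[i % len(refs)]
            seq = np.frombuffer(taxon.sequence.encode(), np.uint8).copy()
            hits = rng.random(seq.size) < 0.01
            seq[hits] = np.frombuffer(b"ACGT", np.uint8)[
                rng.integers(0, 4, int(hits.sum()))]
            label, _, _ = clf.classify(seq.tobytes().decode(), 50, rng)
            correct += label == taxon.class_label
        assert correct >= 95

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            NaiveBayesClassifier([])

    def test_classify_read_wrapper(self, refs):
        read = Read("r", refs[0].sequence, np.full(len(refs[0].sequence), 0.001))
        a = classify_read(read, refs, seed=0)
        assert isinstance(a, ClassAssignment)
        assert a.class_label == refs[0].class_label


class TestLocate:
    @pytest.fixture(scope="class")
    @staticmethod
    def reference():
        rng = np.random.default_rng(5)
        return "".join(rng.choice(list("ACGT"), 1100))

    def test_exact_placement_at_851(self, reference):
        read = Read("r", reference[850:1050], np.full(200, 0.001))
        assert locate_start(read, reference) == 851

    def test_off_window_placement_at_900(self, reference):
        read = Read("r", reference[899:1050], np.full(151, 0.001))
        assert locate_start(read, reference) == 900

    def test_unalignable_read_unplaced(self, reference):
        rng = np.random.default_rng(6)
        read_seq = "".join(rng.choice(list("ACGT"), 200))
        read = Read("r", read_seq, np.full(200, 0.001))
        assert locate_start(read, reference) is None

    def test_noisy_reads_located_within_one_column(self, reference):
        rng = np.random.default_rng(7)
        ok = 0
        n = 200
        for _ in range(n):
            start = int(rng.integers(0, 800))
            seq = np.frombuffer(reference[start:start + 200].encode(),
                                np.uint8).copy()
            hits = rng.random(200) < 0.01
            seq[hits] = np.frombuffer(b"ACGT", np.uint8)[
                rng.integers(0, 4, int(hits.sum()))]
            read = Read("r", seq.tobytes().decode(), np.full(200, 0.01))
            got = locate_start(read, reference)
            ok += got is not None and abs(got - (start + 1)) <= 1
        assert ok >= 0.99 * n


class TestFilter:
    _counter = 0

    def make(self, length, conf, start, cls="Clostridia", phylum="Firmicutes"):
        TestFilter._counter += 1
        read = Read(f"r{TestFilter._counter}", "A" * length,
                    np.full(length, 0.001))
        assign = ClassAssignment(read.read_id, cls, phylum, conf, start)
        return read, assign

    def test_boundary_semantics(self):
        # 149 nt, high confidence, good window: removed as short
        r1, a1 = self.make(149, 99, 851)
        # 200 nt, confidence exactly 71, start 851: kept (strictly > 70)
        r2, a2 = self.make(200, 71, 851)
        # confidence exactly 70 fails the strict rule
        r3, a3 = self.make(200, 70, 851)
        # start 857 is inside the inclusive bacterial window; 858 is not
        r4, a4 = self.make(200, 99, 857)
        r5, a5 = self.make(200, 99, 858)
        result = filter_reads([r1, r2, r3, r4, r5], [a1, a2, a3, a4, a5])
        assert [r.read_id for r in result.kept] == [r2.read_id, r4.read_id]
        assert result.removed == {"short": 1, "low_confidence": 1,
                                  "wrong_region": 1, "chloroplast": 0}

    def test_first_violated_rule_wins(self):
        # short AND chloroplast: counted under (i) only
        read = Read("r", "A" * 100, np.full(100, 0.001))
        assign = ClassAssignment("r", "Chloroplast", "Cyanobacteria", 99, 851)
        result = filter_reads([read], [assign])
        assert result.removed["short"] == 1
        assert result.removed["chloroplast"] == 0

    def test_archaeal_window_used_for_archaea(self):
        read = Read("r", "A" * 200, np.full(200, 0.001))
        assign = ClassAssignment("r", "Methanobacteria", "Euryarchaeota", 99, 846)
        result = filter_reads([read], [assign])
        assert len(result.kept) == 1

    def test_filter_idempotent(self, small_run):
        res = small_run
        again = filter_reads(res.kept_reads, res.kept_assignments,
                             archaea_window=res.config.window,
                             bacteria_window=res.config.window)
        assert len(again.kept) == len(res.kept_reads)
        assert sum(again.removed.values()) == 0

    def test_planted_removal_counts_recovered_exactly(self, fidelity_run):
        assert fidelity_run.removal_counts == \
            fidelity_run.truth.expected_removal_counts()

    def test_chloroplast_filter_removes_over_99_percent(self, fidelity_run):
        res = fidelity_run
        kept_ids = {r.read_id for r in res.kept_reads}
        contam = res.truth.contaminant_reads
        surviving = len(contam & kept_ids)
        assert surviving <= 0.01 * len(contam)
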