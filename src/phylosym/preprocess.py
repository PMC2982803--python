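"""Amplicon read QC and taxonomic assignment.

Stages mirror a standard pyrotag workflow: quality end-trimming at a 0.5%
per-base error threshold, exact barcode+primer demultiplexing (mismatching
prefixes are discarded, matching ones stripped), word-frequency naive-Bayes
classification to taxonomic class with bootstrap confidence, location of each
read's start column on its class reference, and a four-rule quality filter:

(i)   shorter than 150 nt (after prefix stripping),
(ii)  class bootstrap confidence not above 70%,
(iii) start position outside the accepted reference window for its domain,
(iv)  chloroplast origin.

Each removed read is tallied under the first rule it violates, so the
accounting is deterministic and sums to the number of removed reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "Read",
    "ClassAssignment",
    "FilterResult",
    "trim_low_quality_ends",
    "demultiplex",
    "NaiveBayesClassifier",
    "classify_read",
    "locate_start",
    "filter_reads",
    "read_fastq",
    "write_sample_fasta",
    "write_assignment_tsv",
]


@dataclass
class Read:
    """An amplicon read with per-base error probabilities (from Phred scores)."""

    read_id: str
    sequence: str
    error_probs: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.error_probs = np.asarray(self.error_probs, dtype=float)
        if len(self.sequence) != self.error_probs.size:
            raise ValueError("sequence and error vector lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ClassAssignment:
    read_id: str
    class_label: str
    phylum: str
    confidence: float            # percent, 0-100
    start: int | None            # 1-based reference alignment column


@dataclass
class FilterResult:
    kept: list[Read]
    kept_assignments: list[ClassAssignment]
    removed: dict[str, int]

    def to_json(self) -> str:
        return json.dumps({"kept": len(self.kept), "removed": self.removed,
                           "length_rule": "applied after barcode/primer stripping"},
                          indent=1)


# -- trimming --------------------------------------------------------------


def trim_low_quality_ends(read: Read, max_error: float = 0.005) -> Read:
    """Longest contiguous window whose end bases and mean error probability
    are both at or below ``max_error`` (leftmost window on ties; may be empty).
    """
    if len(read) == 0:
        raise ValueError("empty read")
    errs = read.error_probs
    n = errs.size
    valid = np.flatnonzero(errs <= max_error)
    if valid.size == 0:
        return Read(read.read_id, "", np.empty(0), read.sample_id)
    prefix = np.concatenate([[0.0], np.cumsum(errs)])
    best_len, best_start = 0, 0
    # O(v^2) over valid endpoints; reads are a few hundred bases at most
    for i in valid:
        if n - i <= best_len:
            break
        js = valid[valid >= i]
        means_ok = (prefix[js + 1] - prefix[i]) <= max_error * (js - i + 1)
        good = js[means_ok]
        if good.size:
            j = int(good.max())
            if j - i + 1 > best_len:
                best_len, best_start = j - i + 1, int(i)
    if best_len == n:
        return read
    return Read(read.read_id,
                read.sequence[best_start:best_start + best_len],
                errs[best_start:best_start + best_len],
                read.sample_id)


# -- demultiplexing --------------------------------------------------------


def demultiplex(reads: list[Read], barcode_map: dict[str, str],
                forward_primer: str) -> list[Read]:
    """Assign reads to samples by exact barcode+primer prefix and strip it.

    Reads lacking an exact match to any registered prefix are dropped.  An
    ambiguous barcode set (one full prefix a prefix of another) is a
    configuration error.
    """
    prefixes = {barcode + forward_primer: sample
                for sample, barcode in sorted(barcode_map.items())}
    keys = sorted(prefixes)
    for a, b in zip(keys, keys[1:]):
        if b.startswith(a):
            raise ValueError(
                f"ambiguous barcodes: prefix {a!r} shadows {b!r}")
    out = []
    for read in reads:
        for prefix, sample in prefixes.items():
            if read.sequence.startswith(prefix):
                k = len(prefix)
                out.append(Read(read.read_id, read.sequence[k:],
                                read.error_probs[k:], sample))
                break
    return out


# -- classification --------------------------------------------------------


class NaiveBayesClassifier:
    """Word-frequency naive-Bayes taxonomic classifier with bootstrap support.

    Features are k-mer occurrences; per class, the probability that a k-mer is
    present in a member sequence is estimated with add-half smoothing,
    ``(n_with_kmer + 0.5) / (n_refs + 1)``.  A read scores each class by the
    summed log probabilities of its k-mers; confidence is the percentage of
    bootstrap subsamples (``floor(W/k)`` of the read's ``W`` k-mers, drawn with
    replacement) that agree with the full-read assignment.
    """

    def __init__(self, references, k: int = 8):
        references = list(references)
        if not references:
            raise ValueError("empty reference set")
        self.k = k
        self.classes = sorted({t.class_label for t in references})
        self.phylum_of = {}
        for t in references:
            self.phylum_of.setdefault(t.class_label, t.phylum)
        counts = np.zeros((4 ** k, len(self.classes)))
        n_refs = np.zeros(len(self.classes))
        for t in references:
            ci = self.classes.index(t.class_label)
            n_refs[ci] += 1
            ids = self._kmer_ids(t.sequence)
            counts[np.unique(ids), ci] += 1
        self.log_p = np.log((counts + 0.5) / (n_refs + 1.0)).astype(np.float32)

    _CODES = None

    @classmethod
    def _char_codes(cls) -> np.ndarray:
        if cls._CODES is None:
            codes = np.full(256, -1, dtype=np.int64)
            for i, b in enumerate(b"ACGT"):
                codes[b] = i
            cls._CODES = codes
        return cls._CODES

    def _kmer_ids(self, sequence: str) -> np.ndarray:
        codes = self._char_codes()[np.frombuffer(sequence.encode(), dtype=np.uint8)]
        if codes.size < self.k:
            raise ValueError(f"sequence shorter than k={self.k}")
        win = np.lib.stride_tricks.sliding_window_view(codes, self.k)
        powers = 4 ** np.arange(self.k - 1, -1, -1)
        ids = win @ powers
        return ids[win.min(axis=1) >= 0]

    def classify(self, sequence: str, n_bootstrap: int = 100,
                 rng: np.random.Generator | None = None
                 ) -> tuple[str, str, float]:
        """Returns (class, phylum, bootstrap confidence percent)."""
        rng = np.random.default_rng() if rng is None else rng
        ids = self._kmer_ids(sequence)
        if ids.size == 0:
            # read of ambiguous bases: arbitrary class at zero confidence
            return self.classes[0], self.phylum_of[self.classes[0]], 0.0
        scores = self.log_p[ids]                   # (W, C)
        best = int(np.argmax(scores.sum(axis=0)))
        m = max(1, ids.size // self.k)
        draws = rng.integers(0, ids.size, (n_bootstrap, m))
        boot = scores[draws].sum(axis=1)           # (B, C)
        agree = (np.argmax(boot, axis=1) == best).mean()
        label = self.classes[best]
        return label, self.phylum_of[label], 100.0 * float(agree)


def classify_read(read: Read, references, k: int = 8, n_bootstrap: int = 100,
                  seed: int | None = None,
                  classifier: NaiveBayesClassifier | None = None,
                  class_exemplars: dict[str, str] | None = None
                  ) -> ClassAssignment:
    """Classify one read and locate its start on the class exemplar.

    Building the classifier is the expensive part; pass a prebuilt
    ``classifier`` (and ``class_exemplars``) when processing many reads.
    """
    if classifier is None:
        classifier = NaiveBayesClassifier(references, k=k)
    rng = np.random.default_rng(seed)
    label, phylum, conf = classifier.classify(read.sequence, n_bootstrap, rng)
    start = None
    if class_exemplars and label in class_exemplars:
        start = locate_start(read, class_exemplars[label])
    return ClassAssignment(read.read_id, label, phylum, conf, start)


def _refine_start(sequence: str, reference: str, start0: int,
                  edit_distance: int, radius: int = 3) -> int:
    """Prefer a gapless placement when it ties the optimal edit distance.

    Unit-cost alignment cannot distinguish one mismatch from one indel, so a
    substitution at a read's first base can produce a spurious leading-gap
    alignment shifted by one column.  Conventional scoring (gap open costlier
    than mismatch) resolves this toward the gapless placement; we emulate that
    by scanning placements near the reported start and taking the leftmost
    whose Hamming distance equals the optimal edit distance."""
    L = len(sequence)
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    lo = max(0, start0 - radius)
    hi = min(len(reference) - L, start0 + radius)
    for s in range(lo, hi + 1):
        if int((seq != ref[s:s + L]).sum()) == edit_distance:
            return s
    return start0


def locate_start(read: Read, class_reference: str,
                 max_edit_fraction: float = 0.35) -> int | None:
    """1-based reference column of the read's first base under the best
    semi-global alignment to the class reference; None when the alignment is
    too poor to place the read (it then fails the position filter)."""
    if not read.sequence:
        return None
    res = edlib.align(read.sequence, class_reference, mode="HW",
                      task="locations")
    if res["editDistance"] > max_edit_fraction * len(read.sequence):
        return None
    start0 = _refine_start(read.sequence, class_reference,
                           int(res["locations"][0][0]), res["editDistance"])
    return start0 + 1


def locate_start_multi(read: Read, class_references: list[str],
                       max_edit_fraction: float = 0.35) -> int | None:
    """Start column from the best-matching member of a coordinate-consistent
    class reference set.

    Aligning against the closest class member instead of a single exemplar
    keeps the placement unambiguous: against the closest member the only
    differences are sequencing errors, so an indel-shifted alignment can
    essentially never tie the straight one.  All references must share the
    exemplar's coordinate system (equal lengths, no indels among them)."""
    if not read.sequence:
        return None
    best = None
    best_start = None
    best_ref = None
    for ref in class_references:
        res = edlib.align(read.sequence, ref, mode="HW", task="locations")
        d = res["editDistance"]
        if best is None or d < best:
            best = d
            best_start = int(res["locations"][0][0])
            best_ref = ref
            if best == 0:
                break
    if best > max_edit_fraction * len(read.sequence):
        return None
    return _refine_start(read.sequence, best_ref, best_start, best) + 1


# -- filtering -------------------------------------------------------------


def filter_reads(reads: list[Read], assignments: list[ClassAssignment],
                 min_length: int = 150, min_confidence: float = 70.0,
                 archaea_window: tuple[int, int] = (844, 850),
                 bacteria_window: tuple[int, int] = (851, 857),
                 chloroplast_class: str = "Chloroplast",
                 archaeal_phyla: frozenset = frozenset({"Euryarchaeota",
                                                        "Crenarchaeota"})
                 ) -> FilterResult:
    """Apply the four quality rules in order; each removed read is counted
    under the first rule it violates.

    Kept reads satisfy: length >= min_length, confidence strictly above
    min_confidence, start inside the (inclusive) window for their domain, and
    a non-chloroplast class.
    """
    by_id = {a.read_id: a for a in assignments}
    kept: list[Read] = []
    kept_assign: list[ClassAssignment] = []
    removed = {"short": 0, "low_confidence": 0, "wrong_region": 0,
               "chloroplast": 0}
    for read in reads:
        a = by_id[read.read_id]
        window = archaea_window if a.phylum in archaeal_phyla else bacteria_window
        if len(read) < min_length:
            removed["short"] += 1
        elif not (a.confidence > min_confidence):
            removed["low_confidence"] += 1
        elif a.start is None or not (window[0] <= a.start <= window[1]):
            removed["wrong_region"] += 1
        elif a.class_label == chloroplast_class:
            removed["chloroplast"] += 1
        else:
            kept.append(read)
            kept_assign.append(a)
    return FilterResult(kept, kept_assign, removed)


# -- file interfaces -------------------------------------------------------


def read_fastq(path) -> list[Read]:
    """Load FASTQ with Phred+33 qualities into Read objects."""
    from Bio import SeqIO
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        q = np.array(rec.letter_annotations["phred_quality"], dtype=float)
        out.append(Read(rec.id, str(rec.seq), 10.0 ** (-q / 10.0)))
    return out


def write_sample_fasta(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id} sample={read.sample_id}\n{read.sequence}\n")


def write_assignment_tsv(assignments: list[ClassAssignment],
                         sample_of: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample\tclass\tphylum\tconfidence\tstart\n")
        for a in assignments:
            start = "" if a.start is None else str(a.start)
            fh.write(f"{a.read_id}\t{sample_of.get(a.read_id, '')}\t"
                     f"{a.class_label}\t{a.phylum}\t{a.confidence:.1f}\t{start}\n")
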