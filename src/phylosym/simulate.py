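"""Synthetic amplicon datasets with host-structured community signal.

The generator plants a known host tree, evolves per-OTU relative abundances
along it, and emits barcoded amplicon reads with a configurable error model,
so that every downstream stage (demultiplexing, classification, clustering,
character coding, tree search) can be tested against ground truth.

Model sketch
------------
*Host tree*: a species-level topology (Newick) whose leaves are replaced by
the requested number of individuals per species.  Species-level branch
lengths are scaled by ``divergence_scale**2`` so that a branch's length equals
the Brownian-motion variance accumulated across it (in squared log10-abundance
units); individual terminal branches get a negligible epsilon length because
individual variation is modelled as i.i.d. noise, not drift.

*Profiles*: each OTU's log10 abundance starts at a Gaussian root state and
performs Brownian motion along the species tree; presence/absence toggles as a
Poisson process whose rate also scales with effective branch length, so a
zero-divergence tree carries no species signal of any kind.  Individuals add
i.i.d. Gaussian noise (``within_sigma``) to their species' log-abundances.
Frequencies below a detection floor are set to exactly zero and profiles are
renormalized to sum to one.

*Reads*: ``barcode + primer + window-of-reference`` with per-base substitution
probabilities encoded as Phred+33 qualities, uniform insertion/deletion rates,
a configurable fraction of chloroplast contaminants, planted quality-filter
violations (short reads, off-window starts, low-quality tails, corrupted
barcodes), and an optional technical replicate resequenced at a depth ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .treeops import PhyloTree, read_newick

__all__ = [
    "HostSpec",
    "ReferenceTaxon",
    "TrueProfile",
    "GroundTruth",
    "ReadRecord",
    "default_host_spec",
    "simulate_host_tree",
    "evolve_profiles",
    "synthesize_references",
    "class_exemplars",
    "generate_reads",
    "default_barcodes",
]

_BASES = np.array(list("ACGT"))

CHLOROPLAST_CLASS = "Chloroplast"
CHLOROPLAST_PHYLUM = "Cyanobacteria"

_PHYLUM_POOL = [
    ("Firmicutes", "Clostridia"),
    ("Bacteroidetes", "Bacteroidia"),
    ("Proteobacteria", "Gammaproteobacteria"),
    ("Actinobacteria", "Actinomycetia"),
    ("Verrucomicrobia", "Verrucomicrobiae"),
    ("Spirochaetes", "Spirochaetia"),
    ("Fusobacteria", "Fusobacteriia"),
    ("Tenericutes", "Mollicutes"),
]

DEFAULT_PRIMER = "AAACTCAAAGGAATTGACGG"


@dataclass(frozen=True)
class HostSpec:
    """Design of the simulated host panel and community divergence model.

    ``species`` lists (name, number of individuals); ``topology`` is a Newick
    string over the species names (branch lengths default to 1).
    ``divergence_scale`` is in log10-abundance units per unit branch length;
    ``within_sigma`` is the i.i.d. individual noise (log10 units);
    ``turnover_rate`` is the presence flip rate per unit effective branch
    length; ``detection_floor`` is the relative frequency below which an OTU
    is recorded as absent.
    """

    species: tuple[tuple[str, int], ...]
    topology: str
    divergence_scale: float = 1.0
    within_sigma: float = 0.3
    turnover_rate: float = 0.2
    detection_floor: float = 1e-5
    min_branch_length: float = 1e-6
    root_log_mean: float = -2.5
    root_log_sigma: float = 0.8

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species required")
        names = [name for name, _ in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if any(count < 1 for _, count in self.species):
            raise ValueError("each species needs at least one individual")
        for attr in ("divergence_scale", "within_sigma", "turnover_rate"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        tree = read_newick(self.topology)
        if tree.leaf_labels != set(names):
            raise ValueError("topology leaves must equal species names exactly")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{name}_{i + 1}" for name, count in self.species
                for i in range(count)]

    @property
    def species_map(self) -> dict[str, str]:
        return {f"{name}_{i + 1}": name for name, count in self.species
                for i in range(count)}


def default_host_spec(divergence_scale: float = 1.0, within_sigma: float = 0.3,
                      turnover_rate: float = 0.2) -> HostSpec:
    """Five great-ape-like host species with two individuals each."""
    return HostSpec(
        species=(("Homo", 2), ("Pan_troglodytes", 2), ("Pan_paniscus", 2),
                 ("Gorilla_gorilla", 2), ("Gorilla_beringei", 2)),
        topology=("((Homo:1,(Pan_troglodytes:1,Pan_paniscus:1):1):1,"
                  "(Gorilla_gorilla:1,Gorilla_beringei:1):1);"),
        divergence_scale=divergence_scale,
        within_sigma=within_sigma,
        turnover_rate=turnover_rate,
    )


@dataclass(frozen=True)
class ReferenceTaxon:
    taxon_id: str
    phylum: str
    class_label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.phylum or not self.class_label:
            raise ValueError("labels must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must be over ACGT")


@dataclass
class TrueProfile:
    sample_id: str
    frequencies: np.ndarray  # relative frequency per true OTU, sums to 1

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")
        self.frequencies = f


@dataclass
class ReadRecord:
    """A generated amplicon read: sequence plus per-base error probabilities."""
    read_id: str
    sequence: str
    error_probs: np.ndarray


@dataclass
class GroundTruth:
    """Everything the generator knows, for downstream recovery tests."""
    host_tree: PhyloTree | None
    species_map: dict[str, str]
    profiles: dict[str, np.ndarray]
    otu_ids: list[str]                      # community taxa, profile order
    read_to_otu: dict[str, str]
    read_to_sample: dict[str, str]
    contaminant_reads: set[str]
    corrupted_prefix_reads: set[str]
    true_start: dict[str, int]              # 1-based reference column
    clean_payload_length: dict[str, int]    # payload length surviving the trim
    expected_rule: dict[str, str]           # kept/short/wrong_region/chloroplast/demux
    n_substitutions: int
    n_baseline_bases: int
    barcode_map: dict[str, str]
    replicate_pair: tuple[str, str] | None = None
    class_exemplars: dict[str, str] = field(default_factory=dict)
    reference_sequences: dict[str, str] = field(default_factory=dict)

    def expected_removal_counts(self) -> dict[str, int]:
        counts = {"short": 0, "low_confidence": 0, "wrong_region": 0,
                  "chloroplast": 0}
        for rule in self.expected_rule.values():
            if rule in counts:
                counts[rule] += 1
        return counts

    def to_json(self) -> str:
        payload = {
            "host_tree": self.host_tree.to_newick() if self.host_tree else None,
            "species_map": self.species_map,
            "otu_ids": self.otu_ids,
            "profiles": {s: list(map(float, f)) for s, f in self.profiles.items()},
            "read_to_otu": self.read_to_otu,
            "read_to_sample": self.read_to_sample,
            "contaminant_reads": sorted(self.contaminant_reads),
            "corrupted_prefix_reads": sorted(self.corrupted_prefix_reads),
            "true_start": self.true_start,
            "clean_payload_length": self.clean_payload_length,
            "expected_rule": self.expected_rule,
            "barcode_map": self.barcode_map,
            "replicate_pair": list(self.replicate_pair) if self.replicate_pair else None,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# -- host tree -------------------------------------------------------------


def simulate_host_tree(spec: HostSpec, seed: int | None = None) -> PhyloTree:
    """Expand the species topology into the planted per-individual host tree.

    Species branch lengths are multiplied by ``divergence_scale**2`` (branch
    length = accumulated log10-abundance variance); individual terminal
    branches get the epsilon length.  Individuals of one species form a
    cherry (or caterpillar for >2), so species are monophyletic by
    construction.  Deterministic: the seed is accepted for interface symmetry.
    """
    del seed
    if sum(count for _, count in spec.species) < 4:
        raise ValueError("need at least 4 individuals for an unrooted tree")
    tree = read_newick(spec.topology)
    eps = spec.min_branch_length
    for _, _, data in tree.edges():
        base = data.length if data.length is not None else 1.0
        data.length = max(base * spec.divergence_scale ** 2, eps)
    counts = dict(spec.species)
    for leaf in list(tree.leaves()):
        name = tree.label_of(leaf)
        k = counts[name]
        if k == 1:
            tree._labels[leaf] = f"{name}_1"
            continue
        # species leaf becomes the root of a caterpillar of individuals
        del tree._labels[leaf]
        attach = leaf
        for i in range(k):
            child = tree.add_node(f"{name}_{i + 1}")
            tree.connect(attach, child, length=eps)
            if i < k - 2:
                nxt = tree.add_node()
                tree.connect(attach, nxt, length=eps)
                attach = nxt
            elif i == k - 2:
                pass  # last two individuals share the current attach node
    return tree


# -- profiles --------------------------------------------------------------


def evolve_profiles(tree: PhyloTree, n_otus: int, spec: HostSpec,
                    seed: int | None = None) -> list[TrueProfile]:
    """Evolve per-OTU relative abundances along the species tree.

    ``tree`` is accepted for interface completeness and consistency checks (its
    leaves must be the spec's sample ids); the Brownian process itself runs on
    the species topology so that conspecific individuals share a species-level
    state and differ only by the within-species noise.
    """
    if n_otus < 1:
        raise ValueError("n_otus must be at least 1")
    if tree.leaf_labels != set(spec.sample_ids):
        raise ValueError("tree leaves must match the spec's sample ids")
    rng = np.random.default_rng(seed)
    sp_tree = read_newick(spec.topology)
    scale2 = spec.divergence_scale ** 2
    ref = min(sp_tree.leaves(), key=sp_tree.label_of)
    root = next(iter(sp_tree.neighbors(ref)))
    x_root = rng.normal(spec.root_log_mean, spec.root_log_sigma, n_otus)
    present_root = np.ones(n_otus, dtype=bool)
    state: dict[int, tuple[np.ndarray, np.ndarray]] = {root: (x_root, present_root)}
    species_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    order = sp_tree.postorder(root)  # (node, parent); root last
    for node, parent in reversed(order):
        if parent is None:
            continue
        x_p, pres_p = state[parent]
        raw = sp_tree.branch(node, parent).length
        bl = (raw if raw is not None else 1.0) * scale2
        x = x_p + rng.normal(0.0, math.sqrt(bl), n_otus) if bl > 0 else x_p.copy()
        flips = rng.poisson(spec.turnover_rate * bl, n_otus)
        pres = np.where(flips % 2 == 1, ~pres_p, pres_p)
        state[node] = (x, pres)
        label = sp_tree.label_of(node)
        if label is not None:
            species_state[label] = (x, pres)

    profiles = []
    for sample in spec.sample_ids:
        species = spec.species_map[sample]
        x_sp, pres_sp = species_state[species]
        x = x_sp + rng.normal(0.0, spec.within_sigma, n_otus) \
            if spec.within_sigma > 0 else x_sp.copy()
        abund = np.where(pres_sp, 10.0 ** x, 0.0)
        total = abund.sum()
        if total == 0:
            abund[:] = 0.0
            abund[0] = 1.0
            total = 1.0
        freq = abund / total
        freq[freq < spec.detection_floor] = 0.0
        freq = freq / freq.sum()
        profiles.append(TrueProfile(sample_id=sample, frequencies=freq))
    return profiles


# -- references ------------------------------------------------------------


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability ``rate`` (to a different base)."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, hit.size)
        out[hit] = (out[hit] + shift) % 4
    return out


def synthesize_references(n_otus: int, n_phyla: int, seq_length: int = 400,
                          divergence: float = 0.04, seed: int | None = None,
                          n_chloroplast: int = 5,
                          class_divergence: float = 0.12) -> list[ReferenceTaxon]:
    """Labelled 16S-like reference sequences for the classifier and aligner.

    Each class descends from a class ancestor (itself derived from a shared
    master sequence at ``class_divergence``); community OTUs mutate their class
    ancestor at ``divergence`` so that within-class identity exceeds
    between-class identity.  The first taxon of each class *is* the unmutated
    ancestor and serves as the class exemplar for reference-guided alignment.
    A designated chloroplast class (phylum Cyanobacteria) is always appended
    for contaminant tests.
    """
    if not (n_otus >= n_phyla >= 1):
        raise ValueError("need n_otus >= n_phyla >= 1")
    if seq_length < 150:
        raise ValueError("seq_length must be >= 150 so reads can pass the length filter")
    if not (0 < divergence < 0.5):
        raise ValueError("divergence must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    master = rng.integers(0, 4, seq_length)
    phyla = [_PHYLUM_POOL[i % len(_PHYLUM_POOL)] if i < len(_PHYLUM_POOL)
             else (f"Phylum{i + 1:02d}", f"Class{i + 1:02d}")
             for i in range(n_phyla)]
    ancestors = {cls: _mutate(master, class_divergence, rng)
                 for _, cls in phyla}
    taxa: list[ReferenceTaxon] = []
    seen_first: set[str] = set()
    for i in range(n_otus):
        phylum, cls = phyla[i % n_phyla]
        if cls not in seen_first:
            seq = ancestors[cls]  # exemplar
            seen_first.add(cls)
        else:
            seq = _mutate(ancestors[cls], divergence, rng)
        taxa.append(ReferenceTaxon(f"T{i:04d}", phylum, cls,
                                   "".join(_BASES[seq])))
    chloro_anc = _mutate(master, 0.2, rng)
    for j in range(n_chloroplast):
        seq = chloro_anc if j == 0 else _mutate(chloro_anc, divergence, rng)
        taxa.append(ReferenceTaxon(f"C{j:04d}", CHLOROPLAST_PHYLUM,
                                   CHLOROPLAST_CLASS, "".join(_BASES[seq])))
    return taxa


def class_exemplars(references: list[ReferenceTaxon]) -> dict[str, str]:
    """First (ancestral) sequence of each class, used as the alignment guide."""
    out: dict[str, str] = {}
    for taxon in references:
        out.setdefault(taxon.class_label, taxon.sequence)
    return out


# -- reads -----------------------------------------------------------------


def default_barcodes(sample_ids: list[str], length: int = 4) -> dict[str, str]:
    """Deterministic barcodes with pairwise Hamming distance >= 2, so a single
    corrupted base can never alias one sample as another."""
    chosen: list[str] = []
    out: dict[str, str] = {}
    idx = 0
    alphabet = "ACGT"
    for sample in sample_ids:
        while True:
            cand = "".join(alphabet[(idx >> (2 * p)) & 3] for p in range(length))
            idx += 1
            if all(sum(a != b for a, b in zip(cand, prev)) >= 2 for prev in chosen):
                chosen.append(cand)
                out[sample] = cand
                break
            if idx > 4 ** length:
                raise ValueError("too many samples for barcode length")
    return out


def generate_reads(
    profiles: list[TrueProfile],
    references: list[ReferenceTaxon],
    depth_per_sample: int,
    error_rates: tuple[float, float, float] = (0.002, 0.0005, 0.0005),
    barcode_map: dict[str, str] | None = None,
    primer: str = DEFAULT_PRIMER,
    contaminant_fraction: float = 0.02,
    seed: int | None = None,
    window: tuple[int, int] = (51, 57),
    off_window_fraction: float = 0.03,
    off_window_range: tuple[int, int] = (30, 90),
    read_length: tuple[int, int] = (180, 220),
    short_fraction: float = 0.02,
    short_length: tuple[int, int] = (110, 149),
    bad_tail_fraction: float = 0.05,
    bad_tail_error: float = 0.02,
    bad_tail_length: int = 25,
    barcode_error_fraction: float = 0.02,
    replicate_of: str | None = None,
    replicate_depth_factor: float = 3.5,
) -> tuple[list[ReadRecord], GroundTruth]:
    """Emit barcoded FASTQ-style reads plus complete ground truth.

    Stochastic errors apply to the payload only; the barcode+primer prefix is
    either exact or corrupted wholesale (one substituted base) with probability
    ``barcode_error_fraction``, so the planted demultiplex outcome of every
    read is known.  ``replicate_of`` names a sample to resequence as an
    independent technical replicate (suffix ``R``) at
    ``replicate_depth_factor`` times the base depth.
    """
    sub_rate, ins_rate, del_rate = error_rates
    if not all(0 <= r < 1 for r in error_rates):
        raise ValueError("error rates must lie in [0, 1)")
    samples = [p.sample_id for p in profiles]
    replicate_pair = None
    plan: list[tuple[str, TrueProfile, int]] = [
        (p.sample_id, p, depth_per_sample) for p in profiles]
    if replicate_of is not None:
        base = next(p for p in profiles if p.sample_id == replicate_of)
        rep_id = replicate_of + "R"
        plan.append((rep_id, base, int(round(depth_per_sample * replicate_depth_factor))))
        samples = samples + [rep_id]
        replicate_pair = (replicate_of, rep_id)
    if barcode_map is None:
        barcode_map = default_barcodes(samples)
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("barcodes must be unique per sample")

    community = [t for t in references if t.class_label != CHLOROPLAST_CLASS]
    chloro = [t for t in references if t.class_label == CHLOROPLAST_CLASS]
    n_otus = len(community)
    for p in profiles:
        if p.frequencies.size != n_otus:
            raise ValueError("profile length must equal number of community taxa")
    if contaminant_fraction > 0 and not chloro:
        raise ValueError("contaminant_fraction > 0 requires chloroplast references")
    ref_codes = {t.taxon_id: np.frombuffer(t.sequence.encode(), dtype=np.uint8)
                 for t in references}

    rng = np.random.default_rng(seed)
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_of = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i

    reads: list[ReadRecord] = []
    read_to_otu: dict[str, str] = {}
    read_to_sample: dict[str, str] = {}
    contaminants: set[str] = set()
    corrupted: set[str] = set()
    true_start: dict[str, int] = {}
    clean_len: dict[str, int] = {}
    expected_rule: dict[str, str] = {}
    n_sub = 0
    n_base = 0
    win_lo, win_hi = window
    counter = 0

    for sample, profile, depth in plan:
        barcode = barcode_map[sample]
        prefix = barcode + primer
        n_contam = int(round(depth * contaminant_fraction))
        n_comm = depth - n_contam
        counts = rng.multinomial(n_comm, profile.frequencies)
        sources = [t for t, c in zip(community, counts) for _ in range(c)]
        if n_contam:
            picks = rng.integers(0, len(chloro), n_contam)
            sources += [chloro[i] for i in picks]
        order = rng.permutation(len(sources))
        # per-read structural draws, vectorized per sample
        n = len(sources)
        is_short = rng.random(n) < short_fraction
        lengths = np.where(
            is_short,
            rng.integers(short_length[0], short_length[1] + 1, n),
            rng.integers(read_length[0], read_length[1] + 1, n))
        off_win = rng.random(n) < off_window_fraction
        starts = np.where(
            off_win,
            rng.integers(off_window_range[0], off_window_range[1] + 1, n),
            rng.integers(win_lo, win_hi + 1, n))
        # off-window draws may land inside the window by chance; record reality
        bad_tail = rng.random(n) < bad_tail_fraction
        bad_prefix = rng.random(n) < barcode_error_fraction

        for j in order:
            taxon = sources[j]
            ref = ref_codes[taxon.taxon_id]
            start0 = int(starts[j]) - 1  # 0-based
            length = int(lengths[j])
            end0 = min(start0 + length, ref.size)
            payload = ref[start0:end0].copy()
            L = payload.size
            probs = np.full(L, sub_rate)
            tail = bool(bad_tail[j]) and L > bad_tail_length + 20
            # indels first (uniform rates), then per-base substitutions
            del_mask = rng.random(L) < del_rate if del_rate > 0 else np.zeros(L, bool)
            ins_mask = rng.random(L) < ins_rate if ins_rate > 0 else np.zeros(L, bool)
            first_kept = int(np.argmax(~del_mask)) if del_mask.any() else 0
            if del_mask.all():
                continue  # degenerate read, skip entirely
            if del_mask.any() or ins_mask.any():
                seq_parts: list[int] = []
                prob_parts: list[float] = []
                for i in range(L):
                    if not del_mask[i]:
                        seq_parts.append(payload[i])
                        prob_parts.append(probs[i])
                    if ins_mask[i]:
                        seq_parts.append(int(rng.integers(0, 4) + 0))
                        seq_parts[-1] = int(base_lut[seq_parts[-1]])
                        prob_parts.append(probs[i])
                payload = np.array(seq_parts, dtype=np.uint8)
                probs = np.array(prob_parts)
                L = payload.size
            if tail:
                probs[-bad_tail_length:] = bad_tail_error
            hits = rng.random(L) < probs
            if hits.any():
                codes = code_of[payload]
                shift = rng.integers(1, 4, int(hits.sum()))
                codes[hits] = (codes[hits] + shift) % 4
                payload = base_lut[codes]
            n_sub += int((hits & (probs == sub_rate)).sum())
            n_base += int((probs == sub_rate).sum())

            rid = f"R{counter:07d}"
            counter += 1
            seq = prefix + payload.tobytes().decode()
            if bad_prefix[j]:
                pos = int(rng.integers(0, len(prefix)))
                old = seq[pos]
                new = "ACGT"[(code_of[ord(old)] + int(rng.integers(1, 4))) % 4]
                seq = seq[:pos] + new + seq[pos + 1:]
            full_probs = np.concatenate([np.full(len(prefix), sub_rate), probs])
            reads.append(ReadRecord(rid, seq, full_probs))
            read_to_sample[rid] = sample
            read_to_otu[rid] = taxon.taxon_id
            if taxon.class_label == CHLOROPLAST_CLASS:
                contaminants.add(rid)
            start_col = start0 + first_kept + 1
            true_start[rid] = start_col
            clean = L - (bad_tail_length if tail else 0)
            clean_len[rid] = clean
            if bad_prefix[j]:
                corrupted.add(rid)
                expected_rule[rid] = "demux"
            elif clean < 150:
                expected_rule[rid] = "short"
            elif not (win_lo <= start_col <= win_hi):
                expected_rule[rid] = "wrong_region"
            elif rid in contaminants:
                expected_rule[rid] = "chloroplast"
            else:
                expected_rule[rid] = "kept"

    spec_like_map = {s: s.rsplit("_", 1)[0] if "_" in s else s for s in samples}
    truth = GroundTruth(
        host_tree=None,  # filled by the caller that owns the planted tree
        species_map=spec_like_map,
        profiles={p.sample_id: p.frequencies for p in profiles},
        otu_ids=[t.taxon_id for t in community],
        read_to_otu=read_to_otu,
        read_to_sample=read_to_sample,
        contaminant_reads=contaminants,
        corrupted_prefix_reads=corrupted,
        true_start=true_start,
        clean_payload_length=clean_len,
        expected_rule=expected_rule,
        n_substitutions=n_sub,
        n_baseline_bases=n_base,
        barcode_map=dict(barcode_map),
        replicate_pair=replicate_pair,
        class_exemplars=class_exemplars(references),
        reference_sequences={t.taxon_id: t.sequence for t in references},
    )
    return reads, truth


# -- file interfaces -------------------------------------------------------


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            q = np.clip((-10.0 * np.log10(np.maximum(read.error_probs, 1e-9))
                         ).round().astype(int), 0, 60)
            qual = "".join(chr(33 + int(x)) for x in q)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def write_reference_fasta(references: list[ReferenceTaxon], path) -> None:
    with open(path, "w") as fh:
        for taxon in references:
            fh.write(f">{taxon.taxon_id}\n{taxon.sequence}\n")


def write_taxonomy_tsv(references: list[ReferenceTaxon], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tphylum\tclass\n")
        for taxon in references:
            fh.write(f"{taxon.taxon_id}\t{taxon.phylum}\t{taxon.class_label}\n")


def write_manifest_tsv(species_map: dict[str, str], barcode_map: dict[str, str],
                       path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies\tbarcode\n")
        for sample in sorted(barcode_map):
            fh.write(f"{sample}\t{species_map.get(sample, sample)}\t"
                     f"{barcode_map[sample]}\n")
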