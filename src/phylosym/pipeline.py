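"""End-to-end pipeline: synthetic reads -> QC -> OTUs -> characters -> tree.

This module wires the stages together under a single seeded configuration so
that a whole in-silico experiment — community simulation, read generation,
quality filtering, 99.5% MCL OTU clustering, six-state ordered coding,
parsimony search with bootstrap, and comparison against the planted host
tree — is one reproducible function call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import characters, clustering, metrics, parsimony, preprocess, simulate
from .treeops import PhyloTree

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Study design for one synthetic experiment.

    Defaults describe the standard strong-signal condition: ten samples from
    five host species (two individuals each), 200 planted community OTUs over
    five bacterial phyla plus chloroplast contaminants, 5,000 reads per
    sample, and a 454-like error model (0.2% substitutions, 0.05% insertions
    and deletions per base).
    """

    host: simulate.HostSpec = field(default_factory=simulate.default_host_spec)
    n_otus: int = 200
    n_phyla: int = 5
    seq_length: int = 400
    ref_divergence: float = 0.04
    depth: int = 5000
    error_rates: tuple[float, float, float] = (0.002, 0.0005, 0.0005)
    contaminant_fraction: float = 0.02
    window: tuple[int, int] = (51, 57)
    off_window_fraction: float = 0.03
    short_fraction: float = 0.02
    bad_tail_fraction: float = 0.05
    barcode_error_fraction: float = 0.02
    primer: str = simulate.DEFAULT_PRIMER
    replicate_of: str | None = None
    k: int = 8
    n_class_bootstrap: int = 100
    trim_max_error: float = 0.005
    min_length: int = 150
    min_confidence: float = 70.0
    otu_threshold: float = 99.5
    inflation: float = 1.5
    bin_edges: tuple = characters.DEFAULT_BIN_EDGES
    n_starts: int = 10
    rearrangement: str = "spr"
    bootstrap_reps: int = 200
    bootstrap_starts: int = 1


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: simulate.GroundTruth
    n_raw_reads: int
    n_demultiplexed: int
    removal_counts: dict[str, int]
    kept_reads: list
    kept_assignments: list
    otus: list
    shared_otus: list
    unique_otus: list
    abundance: characters.AbundanceMatrix | None
    matrix: characters.CharacterMatrix | None
    search: parsimony.SearchResult | None
    bootstrap: parsimony.BootstrapResult | None
    best_tree: PhyloTree | None
    rf_to_planted: int | None
    species_supports: dict[str, float]

    @property
    def n_kept(self) -> int:
        return len(self.kept_reads)


def _spawn_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def run_pipeline(config: PipelineConfig | None = None,
                 seed: int | None = None) -> PipelineResult:
    cfg = config or PipelineConfig()
    s_prof, s_ref, s_reads, s_class, s_search, s_boot = _spawn_seeds(seed, 6)

    # -- simulate ---------------------------------------------------------
    host_tree = simulate.simulate_host_tree(cfg.host)
    profiles = simulate.evolve_profiles(host_tree, cfg.n_otus, cfg.host, s_prof)
    references = simulate.synthesize_references(
        cfg.n_otus, cfg.n_phyla, cfg.seq_length, cfg.ref_divergence, s_ref)
    reads, truth = simulate.generate_reads(
        profiles, references, cfg.depth,
        error_rates=cfg.error_rates,
        primer=cfg.primer,
        contaminant_fraction=cfg.contaminant_fraction,
        seed=s_reads,
        window=cfg.window,
        off_window_fraction=cfg.off_window_fraction,
        short_fraction=cfg.short_fraction,
        bad_tail_fraction=cfg.bad_tail_fraction,
        barcode_error_fraction=cfg.barcode_error_fraction,
        replicate_of=cfg.replicate_of,
    )
    truth.host_tree = host_tree

    # -- QC ---------------------------------------------------------------
    trimmed = []
    for rec in reads:
        read = preprocess.Read(rec.read_id, rec.sequence, rec.error_probs)
        t = preprocess.trim_low_quality_ends(read, cfg.trim_max_error)
        if len(t):
            trimmed.append(t)
    demuxed = preprocess.demultiplex(trimmed, truth.barcode_map, cfg.primer)

    classifier = preprocess.NaiveBayesClassifier(references, k=cfg.k)
    exemplars = simulate.class_exemplars(references)
    class_members: dict[str, list[str]] = {}
    for taxon in references:
        class_members.setdefault(taxon.class_label, []).append(taxon.sequence)
    rng = np.random.default_rng(s_class)
    assignments = []
    start_cache: dict[tuple[str, str], int | None] = {}
    for read in demuxed:
        label, phylum, conf = classifier.classify(
            read.sequence, cfg.n_class_bootstrap, rng)
        key = (label, read.sequence)
        if key in start_cache:
            start = start_cache[key]
        else:
            start = preprocess.locate_start_multi(read, class_members[label])
            start_cache[key] = start
        assignments.append(preprocess.ClassAssignment(
            read.read_id, label, phylum, conf, start))
    del start_cache
    filt = preprocess.filter_reads(
        demuxed, assignments,
        min_length=cfg.min_length, min_confidence=cfg.min_confidence,
        archaea_window=cfg.window, bacteria_window=cfg.window)

    # -- OTU clustering ---------------------------------------------------
    class_of = {a.read_id: (a.class_label, a.phylum) for a in filt.kept_assignments}
    by_class: dict[tuple[str, str], list] = {}
    for read in filt.kept:
        by_class.setdefault(class_of[read.read_id], []).append(read)
    otus: list[clustering.OTU] = []
    for (cls, phylum) in sorted(by_class):
        members = by_class[(cls, phylum)]
        types = clustering.dereplicate(members)
        for t in types:
            t.class_label = cls
        clusters, _, _ = clustering.cluster_class(
            types, exemplars[cls], threshold=cfg.otu_threshold,
            inflation=cfg.inflation)
        otus.extend(clustering.make_otus(clusters, types, cls, phylum,
                                         id_offset=len(otus)))
    shared, unique = clustering.partition_otus(otus)

    samples = sorted({r.sample_id for r in filt.kept})
    abundance = matrix = search = boot = best_tree = None
    rf = None
    species_supports: dict[str, float] = {}
    counts = characters.otu_count_table(shared, samples)
    if len(samples) >= 4 and counts.shape[1] >= 1 and (counts.sum(axis=1) > 0).all():
        abundance = characters.normalize(counts)
        matrix = characters.build_matrix(abundance, cfg.bin_edges)
        search = parsimony.heuristic_search(
            matrix, n_starts=cfg.n_starts,
            rearrangement=cfg.rearrangement, seed=s_search)
        best_tree = search.trees[0]
        planted = _restrict_tree(truth.host_tree, set(samples))
        if planted is not None:
            # drop non-host leaves (e.g. a technical replicate) before comparing
            comparable = _restrict_tree(best_tree, planted.leaf_labels)
            if comparable is not None:
                rf = metrics.rf_distance(comparable, planted)
        if cfg.bootstrap_reps > 0:
            boot = parsimony.bootstrap(
                matrix, n_reps=cfg.bootstrap_reps,
                n_starts=cfg.bootstrap_starts,
                rearrangement=cfg.rearrangement, seed=s_boot)
            species_groups: dict[str, set[str]] = {}
            for sample in samples:
                species_groups.setdefault(
                    truth.species_map.get(sample, sample), set()).add(sample)
            ref_sample = min(samples)
            for species, group in sorted(species_groups.items()):
                if 1 < len(group) < len(samples) - 1:
                    side = group if ref_sample not in group else set(samples) - group
                    species_supports[species] = boot.supports.get(
                        frozenset(side), 0.0)

    return PipelineResult(
        config=cfg, truth=truth,
        n_raw_reads=len(reads), n_demultiplexed=len(demuxed),
        removal_counts=filt.removed,
        kept_reads=filt.kept, kept_assignments=filt.kept_assignments,
        otus=otus, shared_otus=shared, unique_otus=unique,
        abundance=abundance, matrix=matrix,
        search=search, bootstrap=boot, best_tree=best_tree,
        rf_to_planted=rf, species_supports=species_supports,
    )


def _restrict_tree(tree: PhyloTree, keep: set[str]) -> PhyloTree | None:
    """Planted tree restricted to the observed samples (drops e.g. the
    technical replicate, which is not a leaf of the host tree)."""
    if tree is None:
        return None
    extra = keep - tree.leaf_labels
    if extra:
        keep = keep - extra
    if keep == tree.leaf_labels:
        out = tree.copy()
    else:
        out = tree.copy()
        for leaf in [n for n in out.leaves() if out.label_of(n) not in keep]:
            out.remove_node(leaf)
        # iteratively clean up dangling internal nodes
        changed = True
        while changed:
            changed = False
            for node in out.nodes:
                if out.label_of(node) is None and out.degree(node) <= 1:
                    out.remove_node(node)
                    changed = True
        out.suppress_degree_two()
    if out.n_leaves < 4:
        return None
    return out
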