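"""Order-of-magnitude character coding of community abundance tables.

Each feature (a shared OTU at species rank, or a phylum) becomes one standard
phylogenetic character per host sample, coded with one of six ordered states:
state 0 for absence, and states 1-5 binned by log10 relative frequency.  The
default bin edges are 1e-4, 1e-3, 1e-2 and 1e-1, with a boundary frequency
assigned to the higher state, so typical deep-sample frequencies spread across
the full state range; the edges are configuration, not dogma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "CharacterMatrix",
    "DEFAULT_BIN_EDGES",
    "otu_count_table",
    "phylum_count_table",
    "normalize",
    "code_states",
    "build_matrix",
    "read_phylip",
    "read_tsv",
    "write_tsv",
    "write_phylip",
    "write_nexus",
]

DEFAULT_BIN_EDGES = (1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class AbundanceMatrix:
    """Raw counts and normalized frequencies, samples x features."""

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    rank: str = "species"

    def __post_init__(self) -> None:
        f = self.frequencies.to_numpy()
        rowsum = f.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("frequencies must sum to 1 per sample")
        if ((self.counts.to_numpy() == 0) != (f == 0)).any():
            raise ValueError("zero counts must map to zero frequencies")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class CharacterMatrix:
    """Samples x characters of ordered integer states 0..5."""

    samples: list[str]
    characters: list[str]
    states: np.ndarray
    rank: str = "species"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.shape != (len(self.samples), len(self.characters)):
            raise ValueError("state matrix shape mismatch")
        if self.states.size and (self.states.min() < 0 or self.states.max() > 5):
            raise ValueError("states must lie in 0..5")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.samples,
                            columns=self.characters)


def otu_count_table(otus, samples: list[str], shared_only: bool = True
                    ) -> pd.DataFrame:
    """Per-sample read counts, one column per OTU (shared OTUs only by
    default, since single-sample OTUs carry no grouping information)."""
    use = [o for o in otus if o.shared] if shared_only else list(otus)
    data = {o.otu_id: [o.counts.get(s, 0) for s in samples] for o in use}
    return pd.DataFrame(data, index=list(samples), dtype=int)


def phylum_count_table(otus, samples: list[str]) -> pd.DataFrame:
    """OTU counts collapsed to phylum before normalization (all OTUs, not
    just shared ones: every classifiable read informs the phylum profile)."""
    table: dict[str, np.ndarray] = {}
    for o in otus:
        col = table.setdefault(o.phylum, np.zeros(len(samples), dtype=int))
        for i, s in enumerate(samples):
            col[i] += o.counts.get(s, 0)
    return pd.DataFrame(table, index=list(samples), dtype=int)


def normalize(counts: pd.DataFrame, depths: pd.Series | None = None,
              rank: str = "species") -> AbundanceMatrix:
    """Counts to relative frequencies: count / per-sample depth.

    ``depths`` defaults to the row sums; a sample with zero total reads is an
    error (its frequencies would be undefined).
    """
    counts = counts.astype(int)
    if depths is None:
        depths = counts.sum(axis=1)
    depths = depths.reindex(counts.index)
    if (depths <= 0).any():
        bad = list(depths.index[depths <= 0])
        raise ValueError(f"samples with zero depth: {bad}")
    freq = counts.div(depths, axis=0)
    # renormalize in case depths were provided and exceed the table's row sums
    freq = freq.div(freq.sum(axis=1), axis=0)
    return AbundanceMatrix(counts=counts, frequencies=freq, rank=rank)


def code_states(frequency, bin_edges=DEFAULT_BIN_EDGES):
    """Code frequencies into ordered states 0..5.

    State 0 iff the frequency is exactly 0; otherwise states 1..5 by log10
    bins, a boundary belonging to the higher state (so the top edge itself
    reaches state 5).  Accepts scalars or arrays.
    """
    edges = np.asarray(sorted(bin_edges), dtype=float)
    if edges.size != 5 - 1 or (np.diff(edges) <= 0).any():
        raise ValueError("need strictly monotonic bin edges for states 1..5")
    f = np.asarray(frequency, dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise ValueError("frequencies must lie in [0, 1]")
    states = np.where(f == 0, 0, np.digitize(f, edges, right=False) + 1)
    return states if states.ndim else int(states)


def build_matrix(table: AbundanceMatrix,
                 bin_edges=DEFAULT_BIN_EDGES) -> CharacterMatrix:
    """Character matrix from an abundance table: one ordered six-state
    character per feature.  Constant columns are retained (they simply add
    zero parsimony length).  Fewer than four samples cannot support an
    unrooted tree and is an error."""
    if len(table.samples) < 4:
        raise ValueError("need at least 4 samples for an unrooted tree")
    states = code_states(table.frequencies.to_numpy(), bin_edges)
    return CharacterMatrix(samples=table.samples,
                           characters=list(table.frequencies.columns),
                           states=states.astype(np.int8),
                           rank=table.rank)


def write_tsv(matrix: CharacterMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_tsv(path) -> CharacterMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CharacterMatrix(samples=[str(s) for s in df.index],
                           characters=[str(c) for c in df.columns],
                           states=df.to_numpy().astype(np.int8))


def read_phylip(path) -> CharacterMatrix:
    """Relaxed PHYLIP with contiguous 0-5 state rows."""
    with open(path) as fh:
        header = fh.readline().split()
        n, k = int(header[0]), int(header[1])
        samples, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, states = line.split()
            samples.append(name)
            rows.append([int(c) for c in states])
    if len(samples) != n or any(len(r) != k for r in rows):
        raise ValueError("PHYLIP dimensions do not match header")
    return CharacterMatrix(samples=samples,
                           characters=[f"c{i}" for i in range(k)],
                           states=np.array(rows, dtype=np.int8))


def write_phylip(matrix: CharacterMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.samples)} {len(matrix.characters)}\n")
        for i, sample in enumerate(matrix.samples):
            row = "".join(str(int(s)) for s in matrix.states[i])
            fh.write(f"{sample}  {row}\n")


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """NEXUS with a STANDARD datatype and an ordered-characters assumption."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.samples)} "
                 f"NCHAR={len(matrix.characters)};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="012345" MISSING=?;\n')
        fh.write("  MATRIX\n")
        for i, sample in enumerate(matrix.samples):
            row = "".join(str(int(s)) for s in matrix.states[i])
            fh.write(f"    {sample}  {row}\n")
        fh.write("  ;\nEND;\n\nBEGIN ASSUMPTIONS;\n")
        fh.write("  OPTIONS DEFTYPE=ORD;\nEND;\n")
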