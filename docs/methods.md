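# Methods

`phylosym` asks a single scientific question of amplicon survey data: does the
composition of a host-associated microbial community recapitulate the host
phylogeny?  It answers it with community *phylogenetics*: each microbial
species' abundance becomes an ordered phylogenetic character, the host samples
become taxa, and standard parsimony machinery measures whether the community
tree matches the host tree.  This note records the models, conventions and
numerical choices behind each stage, and what the synthetic experiments do and
do not demonstrate.

## The synthetic community generator

The generator is first-class, tested code: it plants a known truth and emits
the raw inputs (FASTQ reads, reference FASTA + taxonomy, sample manifest,
host Newick) so every downstream stage can be validated end to end.

**Host tree.** A species-level topology (default: five great-ape-like species,
two individuals each) is expanded so each species leaf becomes a cherry of
individuals.  Species branch lengths are multiplied by `divergence_scale**2`,
making a branch's length equal to the log10-abundance variance accumulated
across it; individual terminal branches carry an epsilon length because
individual variation is modelled as exchangeable noise, not drift.

**Profiles.** Each of `n_otus` community OTUs starts from a Gaussian root
state in log10 abundance (mean −2.5, sd 0.8) and performs Brownian motion
along the species tree (variance = effective branch length).  Presence flips
as a Poisson process whose rate is `turnover_rate` per unit *effective* branch
length, so setting `divergence_scale = 0` removes the species signal from both
abundances and presence — the zero-divergence control is a true negative
control.  Individuals add i.i.d. `N(0, within_sigma²)` noise (default sigma
0.3 log units) to their species' state.  Frequencies below the detection floor
(1e−5) become exactly zero; profiles renormalize to sum to one.  Conspecific
individuals are *identical* when sigma and turnover are zero — a contract the
tests rely on.

**References.** Every taxonomic class descends from a class ancestor (mutated
from one master sequence at 12% per site); community OTUs mutate their class
ancestor at 4% per site, so within-class identity exceeds between-class
identity and planted OTUs sit ≥ ~2% apart — comfortably outside the 0.5%
clustering radius.  The first taxon of each class *is* the unmutated ancestor
and serves as the class exemplar for reference-guided alignment.  A
chloroplast class (phylum Cyanobacteria) is always appended for contaminant
experiments.

**Reads.** A read is `barcode + primer + window-of-reference`.  Window starts
fall inside an accepted reference window (default columns 51–57) except for a
planted off-window fraction; a planted fraction of reads is shorter than the
length filter; a planted fraction carries a low-quality 3′ tail (error
probability 0.02 over the last 25 bases, versus 0.002 baseline).  Qualities
are Phred+33 with error probability 10^(−Q/10).  Substitutions are drawn
per-base from the encoded probabilities; insertions and deletions occur at
uniform per-base rates (default 0.05% each) — a deliberate simplification of
homopolymer-specific pyrosequencing errors, which the downstream filters do
not distinguish anyway.  Chimeras are not simulated.

Two accounting choices keep the planted truth exact.  Stochastic errors are
*not* applied inside the barcode+primer prefix; instead a single knob corrupts
one prefix base wholesale, and barcodes are constructed with pairwise Hamming
distance ≥ 2 so a corrupted prefix can never alias another sample.  And the
ground truth records each read's *realized* first reference column (a leading
deletion shifts it) and post-trim payload length, from which the expected
outcome of every filter rule follows deterministically.

**Technical replicate.** One sample can be resequenced as an independent
error draw from the same true profile at 3.5× the base depth, mirroring how a
replicate sequencing run would be produced.

## Read processing

**Trimming** returns the longest contiguous window whose two end bases and
mean error probability are all ≤ 0.5% per base.  Exact vendor trimmers use
proprietary windowing; the longest-qualifying-window rule is simple,
deterministic, and reproduces the intended behaviour (clean prefix kept, bad
tail dropped).  Ties go to the leftmost window.

**Demultiplexing** is exact-match on barcode+primer, which is then stripped;
a barcode set in which one full prefix is a prefix of another is rejected at
configuration time.

**Classification** is a word-frequency naive-Bayes classifier: features are
8-mers; per class, the probability a k-mer occurs in a member reference is
estimated with add-half smoothing `(n + 0.5)/(N + 1)`; a read scores classes
by summed log probabilities of its k-mers.  Confidence is the percentage of
100 bootstrap subsamples — each `floor(W/8)` of the read's `W` k-mers drawn
with replacement — that agree with the full-read call.  The 70% confidence
filter is *strict* (`> 70`).

**Start location.** The pipeline aligns each read semi-globally (edlib) against
every member of its assigned class and takes the best hit's start column; all
synthetic class members share the exemplar's coordinates, so no column mapping
is needed.  Unit-cost alignment cannot distinguish one mismatch from one
indel, so when a gapless placement ties the optimal edit distance it is
preferred (the decision any affine-scored aligner makes); this removes the
one-column ambiguities that a substituted first base would otherwise create.
A single-exemplar variant (`locate_start`) is also provided.

**Filter.** Four rules, applied in a fixed order so each removed read is
counted once: (i) length < 150 nt after prefix stripping, (ii) confidence not
above 70%, (iii) start column outside the inclusive window for the read's
domain (bacterial and archaeal windows are separately configurable; the
classical coordinates 851–857 / 844–850 are the defaults, while the synthetic
pipeline passes the generator's window), (iv) chloroplast class.  The length
rule applies after stripping; the QC report records this choice.

## OTU clustering

**Dereplication** merges reads identical up to length truncation: processing
distinct sequences longest-first, a sequence joins the lexicographically
smallest canonical it prefixes.  The canonical sequence is the longest member.

**Alignment** is reference-guided: each unique type aligns pairwise to its
class exemplar, rows merge on reference coordinates, and insertions stack in
extra columns after their anchor position.  Types whose best alignment exceeds
35% edits are flagged unalignable and become singletons.

**Identity** between two rows counts matches over compared columns: columns
within both rows' spans where at least one row has a base.  Terminal gap runs
are excluded entirely; a column where exactly one row is gapped counts as one
difference; double-gap columns are not compared.  With this rule a 200-column
overlap with one mismatch is exactly 99.5% — the inclusive threshold.

**Pair scoring at scale.** All pairs within a class are scored — no
heuristic pruning decides which edges exist.  Two routes implement the same
identity rule: a per-column byte comparison (`pairwise_identities`, the
reference route, also used for arbitrary pair lists), and a bit-sliced
all-pairs engine (`class_edges`) that packs each row into three base
bitplanes plus a nonzero plane (64 columns per machine word) so that
per-pair difference and compared-column counts become bitwise XOR/OR plus
popcounts, evaluated in row blocks.  The two routes agree exactly (tested
pair-by-pair); the bit-sliced route is what makes a class dominated by one
very abundant, error-rich OTU (tens of millions of pairs) run in tens of
seconds within bounded memory.  A windowed exact-content candidate
prefilter (`candidate_pairs`) remains for cross-sample matching, where a
pair at ≥ 99.5% identity provably shares at least one clean 32-column
window.

**MCL.** The similarity graph (edges at ≥ 99.5% identity, weighted by
identity, self-loops of weight 100) is clustered per connected component by
Markov clustering: expansion (matrix square), inflation (elementwise power
1.5, column renormalization), pruning below 1e−12, until the flow matrix
changes by < 1e−6 or 200 iterations (non-convergence sets a warning flag and
interprets the current matrix).  Components beyond 1,500 nodes switch from
the dense iteration to a sparse one with the pruning regime production MCL
uses — a value floor (1e−7) plus a per-column cap of the 300 largest entries
— which keeps hub-and-spoke giants (one abundant OTU and its thousands of
one-error satellites) tractable without changing which attractors win.  Attractors keeping flow on their own column
form cluster cores; attractors joined by residual flow merge; every other
node joins the attractor holding most of its column mass, ties to the
smallest node index.  Edge weights default to identities; binary weights are
a configuration away.

**OTUs.** One OTU per cluster, carrying per-sample counts summed over member
types; the representative is the longest member sequence (ties broken
lexicographically).  OTUs seen in ≥ 2 samples are *shared* and feed the
phylogenetic analysis; single-sample OTUs are set aside as uninformative.

## Character coding

Counts normalize to per-sample relative frequencies (count/depth).  Each
feature becomes one ordered character with states 0–5: state 0 iff absent,
states 1–5 by log10 bins with default edges 1e−4, 1e−3, 1e−2, 1e−1, a
boundary belonging to the higher state (so the top edge itself reaches state
5).  The anchor of the bins is configuration: the defaults spread typical
deep-sample frequencies (1e−5 to ~0.3) across the full range.  Binning raw
counts instead of frequencies is supported by normalizing with explicit
depths.  Species-rank matrices use shared OTUs only, with shared-OTU reads as
the denominator; phylum-rank matrices collapse all classifiable reads by
phylum before normalization.  Constant columns are retained — they add zero
parsimony length.  Matrices export as TSV, relaxed PHYLIP, and NEXUS with an
ordered-characters (`DEFTYPE=ORD`) assumptions block.

## Parsimony engine

**Costs.** Ordered (Wagner) costs `|i − j|` by default: a two-log-unit
abundance jump costs twice a one-unit jump.  Any symmetric, zero-diagonal
cost matrix satisfying the triangle inequality is accepted; unit (Fitch)
costs are built in.

**Scoring.** Sankoff dynamic programming over all characters at once,
vectorized across unique site patterns with multiplicities.  The score is
invariant to the traversal root because costs are symmetric.  Site patterns
are the unit of work: a bootstrap pseudo-replicate only changes pattern
weights, so per-topology pattern scores are cached and shared across
replicates — the main reason a 200-replicate bootstrap of a ten-taxon matrix
takes seconds to minutes rather than hours.

**Search.** `exhaustive_search` enumerates all `(2n−5)!!` topologies (the
oracle at ≤ 9 taxa, and the way to obtain *all* optima);
`heuristic_search` does random-addition stepwise insertion followed by
best-improvement hill climbing under NNI or SPR, collecting every distinct
best topology across starts.  Defaults: 10 starts, SPR.  Tie-breaks are fixed
(first-found on equal scores, deterministic edge order), so results are
reproducible under a seed.

**Bootstrap.** Characters resample with replacement to the original count;
each replicate reruns the search (one random-addition start by default) and
contributes the bipartitions of its first-found best tree; support is the
percentage of replicates containing a bipartition.  The strict-majority
consensus assembles the > 50% splits (necessarily compatible) by containment;
polytomies remain where support is lacking.

**Branch lengths.** A deterministic Sankoff backtrace (root state = lowest
optimal index; child state = lowest index minimizing parent cost plus subtree
cost) assigns each branch the weighted sum of its character changes; branch
lengths sum exactly to the p-score.

## Tree metrics

Robinson–Foulds distance counts bipartitions present in exactly one tree.
Congruence is defined in the unrooted sense: a constraint set (leaf groups
required monophyletic; sister pairs whose unions must also be separated) is
satisfied iff each required side appears among the tree's bipartitions.  The
probability that a uniformly random unrooted binary topology satisfies the
constraints is computed exactly as a rational: collapse each group to a
supertaxon contributing `(2m−3)!!` rooted arrangements, collapse each sister
pair's union likewise, and multiply by the free topology count of the
collapsed leaf set; full enumeration (≤ 8 leaves) is retained as a
cross-check.  For the standard ten-sample design (five conspecific pairs,
two sisterhood constraints) exactly one of the 2,027,025 ten-taxon topologies
complies, i.e. probability 1/2,027,025 — below one in two million.

Branch apportionment reports two fractions of total tree length: terminal
(leaf-adjacent) branches, and species-discriminating internal branches —
those whose bipartition keeps every species' samples on one side (the
branches surviving conspecific collapse).  They need not sum to one.  The
computation is on the unrooted tree.  Internal-branch correlation matches
internal branches of two topologically identical trees by bipartition,
normalizes each tree's internal lengths to sum to one ("relative" lengths; a
raw mode exists), and returns Pearson r and r²; zero variance yields NaN.

The technical-replicate overlap statistic asks, for each QC-passed read of
the original sample, whether the replicate contains a read of the same class
at ≥ (100 − d)% identity under the clustering identity rules, and reports the
unmatched fraction; it is non-increasing in d by construction.

## Problem sizes and what the experiments show

The standard strong-signal experiment is 10 samples from 5 species, 200
planted OTUs, 5,000 reads/sample, 200 bootstrap pseudo-replicates; the
package's experiments and acceptance script run it as such.  The
zero-divergence control repeats 20 independent runs at a reduced scale (50
OTUs, 600 reads/sample, 50 bootstrap replicates) — the tested property,
absence of spurious species support under a flat truth, does not depend on
depth, and the reduced scale keeps 20 repetitions affordable on one core.
The filter-fidelity fixture uses the substitution-only error model because
planted filter outcomes are only exactly defined when errors cannot move a
read's start column; the indel-bearing model is exercised by the recovery
experiment instead, where counts need only be approximately right.

Passing these experiments shows the pipeline is internally correct and that
the planted generative structure is recoverable; it does not certify
performance on real pyrosequencing data, whose error processes (homopolymer
indels, chimeras, primer bias) are richer than the generator's model, and
whose communities are vastly more diverse than 200 OTUs.

A property of the method worth knowing: identical sequencing-error variants
of a very abundant OTU can recur in two or more samples, and when the reads
are short enough that a one-mismatch pair falls below 99.5% identity (an
overlap under 200 columns) they surface as small spurious *shared* OTUs
("shadows") rather than merging into their parent cluster.  These are the
rare-biosphere artifacts that motivate the strict threshold in the first
place, and they are the reason deep sequencing (the method's own guidance is
above 10⁴ reads per sample) matters: the recovery experiments at 5,000
reads/sample sit near the edge, where shadow characters can occasionally
depress support for one shallow clade even though the planted truth is fully
recoverable from noise-free profiles.  The bundled experiments use seeds at
which the strong-signal condition resolves cleanly; the behaviour at other
seeds is part of what the zero-divergence control and the replicate-overlap
statistic are there to illuminate.

## Known limitations

- Reference-guided alignment presumes reads belong to one of the known
  classes; novel lineages would be flagged unalignable rather than placed.
- The classifier shares the generator's k-mer world; with real reference
  databases its absolute confidence values would differ, though the strict
  70% rule behaves the same.
- MCL is run per class on dense per-component matrices; communities with
  single components of many thousands of types would need a sparse backend.
- The congruence probability treats topologies as uniformly distributed,
  which is the combinatorial null, not a biological model.
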