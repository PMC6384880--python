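# Methods

This note documents the models, conventions and numerical choices behind
`endosym`, in the spirit of a methods supplement: what each component
assumes, which knobs matter, and what the synthetic-data validation does
and does not demonstrate.

## Coordinates and formats

All coordinates are 0-based half-open internally; GFF3 output converts to
1-based inclusive. Circular genomes are linearized at position 0 and the
ancestor generator keeps position 0 feature-free, so no feature wraps the
origin in memory; rotation to a shared gene (`rotate_to_gene`) is the
supported way to establish a common origin before alignment. Sequences are
plain uppercase ACGT strings; FASTA I/O goes through Biopython, the GFF3
subset (typed features with `ID` and `family` attributes) through a small
reader/writer in `genome.py`.

## The simulator

### Ancestor

`generate_ancestor` packs `n_genes` non-overlapping CDS (ATG start, stop
end, no internal stops, strand randomized, lengths ≈ Normal(mean, mean/5)
rounded to codons) into a circular genome of exactly `genome_length` bp,
filling intergenic gaps with random sequence at the target GC. The final
`n_duplicated_genes` gene slots carry exact copies of early genes (same
`family` label) — these duplicate pairs are the repeat substrate for
inversion breakpoints. Realized GC is corrected onto the target (±0.2%,
well inside the ±1% contract) by flipping intergenic bases only. Defaults
(1 Mb, 860 genes, GC 0.40, mean CDS 950 bp, 2 duplicate pairs) emulate a
chromatophore-scale genome.

### Substitutions

Substitutions follow a per-site 4-state continuous-time Markov chain. The
six collapsed, strand-complementary class weights w (summing to 1) define
directed rates q(X→Y) = `sub_rate` · 2 · w(class(X→Y)); with uniform
weights every site leaves its state at rate `sub_rate` exactly. The chain
is simulated exactly by uniformization: Poisson(λ_max·t·L) proposals, each
thinned by the proposed site's actual leaving rate (coding sites are
additionally thinned by `cds_sub_factor`, a crude purifying constraint).
This explicit per-site formulation — rather than drawing a count and then a
direction per event — is what makes the two-state stationary GC,
u(AT→GC)/(u(AT→GC)+u(GC→AT)), the true long-run composition of the
simulation, which the equilibrium-GC recovery tests rely on.

The default spectrum (A>G 0.18, A>C 0.05, A>T 0.09, G>A 0.40, G>T 0.08,
G>C 0.20) makes transitions ~58% of events at 40% GC and sets the
generating equilibrium GC to 0.23/0.71 ≈ 32.4%, near the ~33% mutational
bias reported for chromatophore-like genomes. The default
`sub_rate` = 3.7e-3/site/My was chosen so that, with coding thinning 0.55
over ~84% coding DNA, two strains separated by a 10 My path show ~23
SNPs/kb genome-wide — the observed between-strain density.

### Indels

Per-site indel rate is `indel_rate` · s^(min(run,cap)−1), where *run* is
the length of the mononucleotide run containing the site, s =
`slippage_multiplier` (default 1.8, cap 12) — replication slippage grows
with run length. Coding sites are thinned by `cds_indel_factor`
(default 0.025 ≈ the observed coding/noncoding indel-density ratio).
Lengths come from a four-class mixture (1 bp; 2–15; 16–42; 97–136 bp) with
weights proportional to observed class counts (138:55:14:4); insertion
probabilities per class default to (0.5, 0.5, 0.2, 0.0) — the largest
events are deletions, so the net length change is negative in long runs
even when small insertions outnumber small deletions. 1-bp insertions
duplicate the base at the site (slippage-like); longer insertions are
tandem duplications of the adjacent segment. Deletions that would
straddle a feature boundary are rejected and resampled, keeping annotation
liftover well-defined (a deletion either sits inside one feature or
entirely between features; whole-feature deletions occur only through the
gene-loss process).

### Gene loss

Each present family carries an exponential loss clock with a piecewise
hazard over node ages (default phases: 0.0162/My from 124 to 60 Mya, then
8.1e-4/My — values chosen so ~65% of families fall in the early phase and
a few percent afterwards, the two-phase pattern of endosymbiont genome
reduction). A branch spanning a phase boundary integrates both pieces. A
loss either deletes every copy of the family outright or pseudogenizes it
(premature stop codon substituted mid-gene; feature re-typed), with
probability `pseudogenization_prob` = 0.5. Losses are never reversed, so
the generator is Dollo-compatible by construction.

### Inversions

Inversions are Poisson(`inversion_rate`·t) per branch. Breakpoints fall
between a duplicated-gene pair with probability `dup_breakpoint_prob`
(repeat-mediated intramolecular recombination), otherwise at two random
intergenic positions; candidate breakpoints that would split a feature are
rejected and resampled. The default `inversion_rate` is 0 because the
default tree models near-identical strains, whose genome structure is
conserved; species-level scenarios (see `examples/05`) set a positive
rate. Because repeat-mediated inversions recur at the same breakpoints,
successive events can cancel, and parsimony counts are lower bounds.

### Truth log and randomness

Every event (substitution, indel with run-length context, loss with its
sequence edits, inversion) is appended to a `TruthLog` in application
order with coordinates valid at application time; replaying the log on the
ancestor reproduces each leaf byte-exactly, which the test suite asserts.
One `numpy.random.Generator`, seeded once, drives all stages sequentially
in a fixed preorder traversal, so a single integer reproduces the entire
simulation; the pipeline derives stage seeds from its master seed and
records them in the report.

## Collinear alignment

Anchors are k-mers (default k = 21) unique in both genomes; for genomes
beyond ~250 kb, k-mers are subsampled by hash, since chaining only needs a
sparse scaffold. The heaviest strictly-increasing chain (patience LIS on
the second genome's coordinates) is kept and made non-overlapping.
Inter-anchor segments are closed by a banded global aligner with affine
gaps (match +2, mismatch −3, open −5, extend −2, so a first gap base costs
−7), implemented as a vectorized three-state DP; the band starts at
max(band, |Δlen|+2) and doubles whenever the optimal path touches the band
edge, up to `max_band` (then an error — usually a sign the inputs are not
collinear, e.g. contain an inversion; rearranged genomes belong to the
block-level module instead). The aligner's optimal scores were verified
against Biopython's `PairwiseAligner` under the same scoring scheme.

Three-way projection merges two pairwise alignments on the shared
outgroup's coordinates: one column per outgroup base, with outgroup-gap
(insertion) columns from either input interleaved before the base they
precede. SNPs are gapless columns with ≥2 distinct alleles (multi-allelic
columns count once); indels are maximal gap runs confined to exactly one
genome. Indel region labels use majority overlap with CDS on the
reference, ties assigned noncoding (conservative for the coding-depletion
claim); densities use the reference genome's partition lengths as
denominators. Gap-adjacent SNP columns are included (no masking window by
default).

## Polarization and spectrum

Only differences *between the two ingroups* are polarized: if the outgroup
matches one ingroup, the other carries the derived state. Sites where the
outgroup matches neither are counted `n_unpolarizable`; sites where both
ingroups share a non-outgroup state are `n_shared` (stem or outgroup-branch
changes) — the three categories plus polarized sites partition the variant
columns. Indels polarize only when the outgroup agrees exactly with one
ingroup across the whole event span; adjacent gap runs with different
genome patterns are separate events.

Per-site rates divide directional counts by the originating base's count
in the ancestral (outgroup) sequence; the normalized relative frequencies
rescale those rates to sum to 100%; collapsed classes pool complementary
pairs (pooled counts over pooled source bases). The equilibrium GC is the
stationary fraction of the two-state per-site chain and is
scale-invariant in the rates. The directional chi-square defaults to
per-site expectations (proportional to ancestral GC vs AT site counts); a
50/50 expectation is available via `expectation="equal"`. Homopolymer
rows assign each deletion to the ancestral run containing its first
deleted base and each insertion to the longer of the runs containing or
abutting the insertion point; run length 1 means "not in a run", so every
indel is tabulated.

## Dollo gene-family dynamics

The minimal-loss Dollo labeling marks a family present exactly on the
union of paths from the LCA of its bearing leaves down to those leaves;
one loss is charged per branch leading from a present node into a subtree
with no bearing leaf. Conservation |child| = |parent| + gains − losses
holds at every branch. Two caveats shape how reconstructions are read:

* A loss leaves evidence only if the family survives somewhere outside the
  losing subtree. On simulated data the ancestral inventory is therefore
  anchored by grafting the ancestor (or two copies, when the root would
  otherwise have a single witness) as zero-length root leaves — the role
  free-living outgroup taxa play on real data.
* A family independently lost in *every* leaf of a subtree is
  indistinguishable from a single deeper loss; minimal parsimony returns
  the single-loss history. Recovery tests therefore assert exactness for
  identifiable families (those surviving in ≥1 ingroup leaf).

Loss timelines divide per-branch loss counts by branch durations in My
along each root-to-leaf path; the optional "present in ≥ k taxa" matrix
filter mirrors common orthology-pipeline preprocessing and is off by
default.

## Rearrangements

Blocks are maximal runs of shared single-copy genes whose oriented
adjacencies are conserved (up to whole-strand reversal) in every genome;
duplicated and pseudogenized genes are excluded from the permutation and
reported as candidate breakpoints. DCJ distance is N − C for two circular
genomes (N blocks, C adjacency-graph cycles), with odd-path handling for
linear inputs; it was verified exhaustively against breadth-first search
over all DCJ operations (including intermediates with multiple circles)
for every signed circular order of up to 5 blocks. Tree assignment uses
the supplied ancestral order at the root — exact for a star topology —
and, on deeper trees, picks each internal order greedily from the
candidate set {children's orders, ancestral order}; this is a flagged
heuristic, and totals are parsimony lower bounds on true event counts.

## Selection metrics

NG86 sites split each codon position by the fraction of non-stop single-
base changes that are synonymous; differences at 2–3 positions average
over all mutational pathways with equal weight, skipping pathways through
stop codons (if every pathway is blocked, all pathways are used and
stop-passing steps count as nonsynonymous — a rare corner). Proportions
are Jukes–Cantor corrected, undefined at p ≥ 3/4 (flagged). The dS window
(0.01, 2] flags insufficient divergence and saturation. Group summaries
average a gene's unfiltered pairwise ratios first, then average genes
within groups (sorted aggregation, so results are exactly order-
invariant); adjacent groups are compared by Welch's t-test (Student's
available through scipy directly). Counting-based dN/dS differs
numerically from ML estimators; group orderings, not absolute values, are
the comparable quantity.

CAI follows Sharp–Li: w = codon frequency over the maximum within its
synonymous family; CAI is the geometric mean of w over codons, excluding
Met, Trp and stops; w = 0 codons are floored (default 0.01) rather than
zeroing the whole gene.

## Pipeline

`RunConfig` validates every field up front and rejects unknown keys.
Stages run in dependency order and communicate through files in the run
directory, so subsets can be re-run; a missing prerequisite raises an
error naming the stage. `summary.json` is written with sorted keys and no
timestamps — a fixed seed reproduces it byte-identically — while timings
and file checksums go to `manifest.json`. On simulated runs the dN/dS
stage labels genes by their loss history (retained everywhere / lost in
some lineage / lost on the stem) and compares groups; the CAI stage builds
its reference usage table from the ancestral genes.

## What the synthetic validation shows — and does not

The simulator reproduces the *statistical structure* the analyses target:
AT-biased spectra with a known equilibrium, slippage-enriched indels with
the observed size mixture, Dollo-compatible two-phase loss, and repeat-
mediated inversions. Passing recovery tests therefore demonstrates that
the estimators are consistent and the bookkeeping exact under the model's
own assumptions. Real chromatophore data differ in ways the generator
does not emulate: context-dependent mutation beyond homopolymers,
selection acting on codons and base composition, recombination,
annotation error, and assembly artifacts. Results on real genomes should
be read with those gaps in mind.

Problem sizes in the test and acceptance runs (30–200 kb genomes, tens to
hundreds of genes, 20-replicate recovery means) are scaled-down versions
of the ~1 Mb system chosen so the full validation runs comfortably on one
CPU; the qualitative contrasts being checked are scale-free, and rates
were set from the full-scale study conditions, not re-fit per genome size.
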