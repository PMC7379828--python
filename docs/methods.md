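# Methods

## The assembly model

`isoforge` assembles transcripts from a condensed de Bruijn graph built
from accurate short reads, then reconstructs isoforms as edge paths using
three evidence channels of decreasing reliability and increasing range:
paired-end links (accurate, insert-range), long error-prone read paths
(noisy per base, transcript-range), and full-length (FL) read paths
(transcript-range, known to span whole mRNAs).

The model's key assumption is that long reads are only ever asked a
*combinatorial* question — which graph edges did this molecule traverse —
never a per-base one. Contig sequences always come from the short-read
graph, which is why adding 10%-error reads does not degrade per-base
accuracy of the output.

### Double-stranded graph

K-mers are counted canonically (lexicographic minimum of k-mer and
reverse complement) and every condensed edge has an explicit rc twin;
structural edits operate on the underlying canonical k-mer set and the
graph is re-condensed afterwards, so twin symmetry can never drift. This
models non-strand-specific libraries; a read from either strand aligns to
some orientation of the graph without special-casing. k must be odd to
exclude rc-palindromic k-mers. Circular components are broken at a
deterministic rotation; their twins are paired by constituent-k-mer set
since the two strands' break points need not coincide.

### Simplification

RNA-Seq coverage is too non-uniform for global coverage cutoffs, so tip
and bubble removal are *relative*: a tip (< 2k nt, dangling) is removed
only below `tip_cov_frac = 0.1` times the best alternative at its
junction; a bubble branch only below `bubble_cov_frac = 0.05` times the
parallel branch — comparable branches are kept as putative isoform
variation. The single absolute cut, `cov_abs_min = 2.0`, targets residual
error edges. These thresholds are deliberately permissive: at this
package's scale false edges are cheap (path extension simply never uses
them) while a lost isoform branch is unrecoverable.

### Long-read alignment (anchor and chain)

Exact `anchor_k = 15`-mers shared between read and edge sequences are
chained per edge with three safeguards that exist because splice-graph
edges share their terminal (k−1) nt with sibling edges:

1. chains are restricted to a consistent alignment diagonal (split at
   diagonal gaps > 20 nt), so context k-mers from a different part of the
   read cannot join a chain;
2. a candidate edge needs ≥ `min_anchors = 3` chained anchors of which at
   least one overlaps the edge's internal (non-context) region — for a
   short exon-skip edge that means an anchor actually spanning the
   junction;
3. consecutive candidates are stitched only when a connection (direct
   adjacency or ≤ `max_skip = 2` short intervening edges) inserts a
   nucleotide length consistent with the read-coordinate gap
   (tolerance 100 + 30% of the gap), so an unanchored stretch is never
   papered over with the wrong branch of a bubble.

The single best contiguous run (most chained anchors) becomes the read's
path; reads that anchor nowhere are dropped. Because twins are explicit
edges, scanning the forward read covers both strands, and aligning the
reverse complement provably yields the reversed twin path.

### Path extension

Seeds are unused edges in descending length order; each branch grows
rightward, then leftward via its twin. At each step:

- **Paired-end first.** Candidates are scored by link support from the
  last `pe_window = 3` path edges; the top candidate wins only with
  support ≥ `min_support = 5` and ≥ `dominance = 2.0` times the runner-up.
  PE additionally abstains when any candidate edge is shorter than
  `min_pe_edge_len = 100` nt: such naked junction edges are too short for
  individual mates to be placed on them, so link scores at exon-skip
  branch points are structurally biased toward the long alternative —
  precisely the place where phasing must come from long reads. This rule
  is this package's simplified stand-in for a full insert-size-aware
  paired-end scorer.
- **Long reads only if PE does not help.** R_P is built from the matching
  relation (a suffix of P is a prefix of R, or P occurs inside R) filtered
  by the longest common subpath: ≥ `l_min = 200` nt and ≥ `n_min = 2`
  edges, each capped at P's own size — without the cap a single-edge seed
  could never satisfy the filter and extension could never begin. Every
  candidate e with some R ∈ R_P matching P+e is selected; plural
  selections fork the path (budget `max_forks = 16` per seed), one copy
  per isoform branch. Subpath nt length counts each (k−1)-nt junction
  overlap once.

An edge may repeat in a path at most `max_edge_multiplicity = 4` times
(loop safety). Extension over seeds continues until every edge lies in at
least one path; each finished branch is recorded with its twin path so
the guarantee holds on both strands, and strand-collapsed deduplication
(a path is dropped when it — or its twin — is a contiguous sub-run of a
kept path) later keeps one representative per twin pair. FL paths skip
extension entirely and are added verbatim.

## The simulator

The generator emulates the statistical structure this method is sensitive
to, not sequencing chemistry:

- **Gene models**: 4–7 exons of 150–400 nt (uniform ACGT), 1–3 isoforms
  that always keep the first and last exon. Half of the ≥ 5-exon genes
  receive a "distant double-skip" structure — two 200 nt alternative
  exons flanking a 2000 nt shared exon, far beyond the 300 nt insert —
  the canonical case paired ends cannot phase.
- **Short pairs**: 2×100 nt, insert Normal(300, 30) truncated below at
  200 nt, substitution rate 0.001, random fragment strand. Fragments come
  from random-phase tiling of transcript copies rather than iid uniform
  starts: a real library sequences terminal fragments, and without them
  transcript ends would (almost surely) never reach the k-mer count
  threshold, making exact end-to-end recovery impossible in principle
  rather than in practice.
- **Long reads**: per-base iid substitutions/insertions/deletions
  (defaults 0.034/0.033/0.033, ≈ 10% combined — verified against an
  edit-distance oracle in the tests), 5'-biased truncation of up to 30%
  (incomplete cDNA synthesis), an `fl_fraction = 0.2` of reads spanning
  the whole transcript routed to the FL channel, random strand.

What the simulator does **not** model: homopolymer-dependent ONT error,
expression-level variation (abundance weights default to 1), sequence
similarity between genes (paralogs), introns/intergenic carry-over, and
quality-score realism. Passing tests therefore demonstrate the
graph/phasing machinery, not robustness to biased error profiles or to
near-identical paralogs — on real data the alignment safeguards above
matter more, and misassembly/duplication behaviour will be worse than the
clean-simulation numbers.

## The evaluator

Contigs are aligned to reference *transcripts* (not a genome): seeds are
shared 21-mers, chained colinearly per (contig, reference, orientation),
split into blocks at diagonal jumps > 30 nt, and each block is aligned
base-level with edlib. Splitting matters: a contig that skips or gains an
exon relative to a reference aligns as clean blocks, and the structural
difference is not miscounted as hundreds of substitution "mismatches".
Alignments below 90% aggregate identity or 50 nt are discarded.

- *X%-assembled*: an isoform counts when one contig's alignment covers
  ≥ X% of its bases (X ∈ {50, 95}); a gene counts via any isoform.
- *Database coverage*: distinct covered reference bases / total.
- *Duplication ratio*: total aligned contig bases / distinct covered
  reference bases (1.0 ideal; reported as absent when nothing aligns).
- *Misassemblies*: contigs whose best chains hit two different genes,
  each covering ≥ 30% of the contig.
- *Mismatches per contig*: substitution columns of each contig's best
  alignment, averaged over aligned contigs.

## Problem sizes and numerical choices

The shipped benchmark scenarios run on one CPU in well under a minute
each: single-gene scenarios use 30× short / 15× long coverage; the
multi-gene comparison uses 20 genes (~50 isoforms, ~80 kb of transcript),
30× short and 10× long coverage with fl_fraction 0.2. These sizes were
chosen as the smallest at which every phenomenon of interest (bubble
retention, distant-exon phasing, FL rescue, duplication accounting) is
exercised with comfortable statistical margin.

Tie-breaking is deterministic everywhere (ascending edge id; edge ids
assigned in canonical sequence order), so assembly output is
byte-reproducible for identical inputs regardless of read order. All
simulator randomness flows from a single seed per generator call.

Known limitations: no multi-k iteration or read error correction;
single-edge mate placement (no placement across junctions), which is why
the PE selector needs the short-candidate abstention rule; one contiguous
path per long read (no split alignments); evaluation in transcript space
is blind to intron retention against a genome.
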