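# Methods

This note records the models, conventions and design choices behind
`nacquant`, in the order data flows through the package.

## Reference model

Targets are extracted from a genome FASTA and a GTF annotation (1-based
inclusive on disk, converted to 0-based half-open at parse time; parsing goes
through gffutils with feature inference disabled, grouping `exon` features by
their `transcript_id`/`gene_id` attributes).  Two target families exist:

* **mature** — exon sequences spliced in transcript order, one target per
  transcript;
* **nascent** — the contiguous genomic sequence over the gene span (exons and
  introns), one per gene, named `<gene_id>-I` (suffix configurable).  This
  mirrors common nac-style t2g conventions.

Minus-strand targets are reverse-complemented so indexed sequences read 5'→3'
of the mRNA; mapping is strand-agnostic anyway through canonical k-mers.
Ambiguous bases (`N`) are retained in sequences; any k-mer window containing
a non-ACGT character contributes nothing downstream.  Annotation filtering
(biotype subsetting, de-duplication of overlapping genes) is left to the
user; overlapping genes simply yield overlapping nascent targets, whose
shared k-mers become multi-gene colors.

## Graph and index

The compact de Bruijn graph is **bidirected and node-centric**: a k-mer and
its reverse complement are one vertex, represented by the canonical form
(lexicographic minimum of the two); k must be odd so no k-mer is its own
reverse complement; edges are implied by (k−1)-overlap.  Unitigs are maximal
paths whose internal junctions are unique in both directions.  Two
consequences of these semantics are worth stating because they differ from a
single-stranded mental model: homopolymer self-loops (`AAA→AAA`) are branch
points and split unitigs, and two sequences can merge through a
reverse-complement overlap.  Unitig ids are assigned by lexicographic order
of the canonically-oriented unitig sequence, making serialization
reproducible.  The k-mer table is a plain hash map — minimizers, perfect
hashing and per-unitig color intervals are deliberate non-goals at desk
scale; colors are stored per k-mer.

The index carries: target sequences, the color table (canonical k-mer → set
of targets containing it in either orientation), the target-to-gene table
with mature/nascent status, the DFK store, and an equivalence-class table.
ECs are allocated dynamically — an integer id is created the first time a
read uses that target set — so EC ids are run-local; exports key ECs by
sorted target-name tuples for reproducibility.  The reserved D-list
pseudo-target id is `len(targets)`; it never appears in the t2g table and is
stripped before gene resolution.  Default k is 31 (tests use 5–21 on toy
data).

## DFK extraction

Against the target graph, each D-list sequence is scanned for **common
runs**: maximal stretches of consecutive k-mer start positions whose
canonical k-mer is in the graph (equivalently, shared sequences ≥ k bases).
For each run, the up-to-h consecutive k-mers immediately upstream and
downstream (h = `--d-list-overhang`, default 1) are canonicalized and stored
as DFKs.  Flank extension stops at the sequence boundary, at a non-ACGT
window, or at a k-mer already in the graph (such a k-mer cannot be a DFK;
by run maximality this only happens through canonicalization coincidences or
adjacent runs).  Runs never cross sequence records.  DFKs are uncolored and
kept apart from the color table; by construction they are disjoint from the
graph's k-mers.  The default D-list is the genome itself; splice-junction
sequences are not added to it (junction-spanning contigs contribute only
k−1 k-mers each, too few to matter).

**Flank capacity.**  On one side of a vertex there are |Σ| = 4 candidate
flanking k-mers.  If the side retains at least one in-graph continuation, at
most 3 candidates can be D-list-only, hence at most 2(|Σ|−1) = 6 DFKs per
vertex with both sides continued — a capacity that is tight (the test suite
constructs a branch-terminated single-k-mer unitig attaining exactly 6) and
consistent with the global size bound |DFKs| ≤ min(6·N_k, M_k).  Two
boundary cases, verified by the suite, sharpen the picture: a *free* side
(a tip, with no in-graph continuation) admits all 4 candidates, so an
isolated-k-mer unitig can carry 8; and the capacity is inherently
per-*vertex*, not per-unitig — a run can diverge from the graph at any
interior k-mer of a long unitig, so unitigs with many vertices can
accumulate more flanks than any fixed per-unitig constant.  Overhang
semantics: h means "the h consecutive flanking k-mers on each side"; DFK
sets are nested in h.

## Pseudoalignment and counting

A read's canonical k-mers are looked up in the color table; k-mers absent
from both colors and DFKs are skipped (absence is not evidence); the EC is
the intersection of the found color sets, empty intersection → unmapped.
One DFK hit anywhere in the read is fatal and short-circuits — unless
`--dfk-onlist` is set, in which case the read proceeds and the D-list
pseudo-target is added to its EC (a read with only DFK hits and no colored
k-mer gets the pure D-list EC and is flagged in the stats).  There is no
error-tolerant k-mer rescue; robustness to sequencing errors is statistical.

Records (barcode, UMI, EC, read count — a plain-text BUS analog) are merged
per (barcode, UMI) by **intersecting** their ECs' target sets, dropping the
UMI on an empty intersection.  A single-gene UMI is classified from its
targets' statuses: mature-only → M, nascent-only → N, both → A.  Multi-gene
UMIs are discarded, or, under `--mult`, contribute 1/|genes| per gene with
the status recomputed from that gene's own targets within the set (keeping
per-gene N/M/A semantics well defined).  No Hamming-distance UMI collapsing
is performed; barcodes can be restricted to an on-list before collapse.
Matrices are emitted as MatrixMarket with barcode and gene label files; sum
modes are cell = M+A, nucleus = N+A, total = N+M+A (so cell + nucleus − A =
total entrywise; a standard index has no N matrix and rejects
`--sum nucleus`).

## Synthetic data

The generator emulates a droplet experiment at desk scale.  Defaults — the
benchmark conditions used throughout the tests — are: 20 genes of 2–4 exons
(exons 150–350 bp, introns 100–300 bp) separated by intergenic spacers
(25% of the contig), 50 cells × 200 UMIs, 91-bp reads, origin mix
60% mature / 30% nascent / 10% intergenic molecules, one read per UMI, UMIs
unique per cell by construction, barcodes from a fixed synthetic on-list.
Each cell expresses a random subset of 8 genes: real count matrices are
sparse, and without zero truth entries the false-positive representation
would be degenerate (identically zero for any method).  Intergenic reads are
drawn from windows containing at least one intergenic base, so a fraction of
them straddle gene boundaries — exactly the reads the DFK filter exists for.

Ground truth per read is position-derived — spans an exon–exon junction → M,
covers intronic sequence → N, fully within one exon → A, any intergenic
base → filtered — with one refinement: a boundary read whose sequence also
occurs verbatim in the other molecule form of its gene (e.g. a junction read
overhanging by one base that happens to match the intron edge) carries no
read-level evidence either way and is truth-labelled A.  This is the k-mer
ambiguity vs read ambiguity distinction applied to the truth itself; the
check is a plain substring test against the gene's mature and nascent
sequences, independent of the k-mer machinery.  Truth matrices tally UMIs by
expected classification; filtered reads never enter them.

Sequencing errors are injected in three order-preserving passes — mismatches
first, then deletions, then insertions — each per-base independent.  A
mismatch substitutes uniformly among the 3 alternative bases, a deletion
removes the base, an insertion adds a uniform base after the position (the
per-event distributions are our choice; only the pass order is prescribed).
The error benchmark uses a 0.5% mismatch rate.  All randomness flows from a
single integer seed through one numpy generator per stage.

What the generator does *not* emulate — hence what passing tests do not show
about real data: PCR duplication and UMI collisions, barcode sequencing
errors, alternative splicing within a gene (one transcript per gene by
default), 3'-biased coverage, repeats and homology between genes, partially
processed intermediates, and empty droplets / ambient RNA.

## Evaluation metrics

For truth G_s (entries y_ij) and program output G_p (entries ŷ_ij) over
n cells × m genes, aligned by label:

* RMSE = √( Σ_ij (y_ij − ŷ_ij)² / nm )
* FPR = |{(i,j): y_ij = 0, ŷ_ij > 0}| / nm and FNR symmetric — note the
  denominator is the whole matrix, not the classical rate denominators;
* r_i = Pearson over all m genes of cell i;
* ρ*_i = Spearman over the gene pairs with (y_ij, ŷ_ij) ≠ (0,0).  The
  strict variant (genes nonzero in *both* matrices) is available as
  `spearman_mode="both-nonzero"`; the default follows the displayed
  definition rather than its prose paraphrase.  Ranks use average-rank ties.

Cells with fewer than 2 usable pairs or constant vectors are undefined (NaN)
and excluded from medians; their count is reported.  Top-N barcode selection
ranks by total UMI count with lexicographic tie-breaking.

## Numerical and degenerate-input choices

Non-ACGT windows are skipped everywhere (graph construction, coloring, run
finding, read mapping).  Reads shorter than k are unmapped, not errors.
Targets shorter than k are skipped with a warning.  An all-too-short target
set raises an empty-graph error.  `genes_per_cell` larger than `n_genes` is
clamped.  Matrices are dense float64 internally — adequate far beyond the
intended scale — and sparse only on disk.

## Known limitations

Single-threaded reference semantics; indexes are JSON with the graph and
colors rebuilt on load (cheap at this scale, unsuitable for mammalian
genomes); no EM transcript-abundance estimation; no probabilistic allocation
of ambiguous counts to N or M; no barcode error correction; GTF only (no
GFF3 dialects).
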