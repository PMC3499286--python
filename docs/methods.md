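# Methods

`capmap` models the computational pipeline of a full-length-enriched
cDNA / 5′-EST sequencing project: clustering single-pass 5′ reads,
assigning each clone to a strand-oriented genomic locus, classifying
coding content against reference proteins, estimating RNA editing from
cDNA/genome discordance asymmetry, and verifying the arithmetic of the
project's summary tables. This note records the models, the parameter
choices, and the numerical decisions behind each stage.

## Locus assignment

Alignments arrive as 12-column tabular records (query, subject, percent
identity, length, mismatches, gap opens, query start/end, subject
start/end, e-value, score); subject start > end encodes a minus-strand
hit. Internally all coordinates are 0-based half-open; conversion
happens only at format boundaries (BED is 0-based half-open, GFF3 and
the tabular dialect 1-based inclusive). A single convention avoids
off-by-one drift between modules.

For each query:

1. **Anchor.** Among that query's alignments with score > 100 *and*
   identity > 90% (both strictly), the highest-scoring one is anchored.
   Both thresholds are deliberately strict inequalities and are locked
   by boundary tests. Score ties break by identity, then alignment
   length, then smallest (subject, start) — an arbitrary but
   deterministic order.
2. **Extend.** Other alignments of the same query on the anchor's
   subject and strand are absorbed whenever their genomic distance to
   the current locus hull is strictly under 1 Mb (a plausible intron).
   The gap is measured against the *growing hull*, not the anchor, and
   absorption iterates to a fixpoint: introns are serial, and a
   one-pass rule would split long multi-exon genes. Alignments on other
   subjects are ignored — a locus is a single genomic region.
3. **Merge.** Per-query loci that overlap on the same chromosome and
   strand merge transitively (union hull, unioned member sets).
   Opposite-strand overlaps remain distinct loci. Intervals that merely
   abut (half-open touching) do not merge. The implementation is a
   sort-and-sweep per (chromosome, strand); tests compare it against an
   exhaustive pairwise union-find closure. Merging is idempotent and
   permutation-invariant, and no merged locus ever mixes strands.

Loci are tabulated per chromosome × strand with a separate
unplaced-scaffolds row (scaffold membership is a sequence-name prefix
convention), and locus density is reported in sliding windows (default
5 Mb window, 100 kb step, clipped at the chromosome end; a locus counts
in every window its interval intersects).

## Coding-content classification

The best protein alignment of a clone defines two trims:
`n_term_trim = pstart` and `c_term_trim = protein_length − pend`
(0-based). The clone carries a **full-length CDS** iff both trims are
strictly below 10 aa; it carries a **start codon** iff the N-terminal
trim alone passes. The start-codon rule is the N-terminal half of the
full-length rule by construction — the criterion is otherwise
underdetermined — and is locked by tests at the 9/10 boundary.

The ORF finder scans the three forward frames only (clones are cloned
unidirectionally, so the sense strand is known), requires ATG and an
in-frame stop within the sequence (ORFs running off the 3′ end do not
count), and reports the longest peptide excluding the stop. A clone is
**non-coding** when no ORF exceeds 30 aa (strictly). Per locus, the
member with the longest ORF (ties: longer sequence, then id) represents
the locus; proteins matched by two or more representatives flag
putative duplications, and within each such group representatives with
shorter ORFs than the group maximum are marked as likely pseudogenes or
assembly artefacts.

## Editing estimation

For each clone the single alignment covering the largest fraction of
the cDNA (ties: higher identity) defines the compared region. The
pairing is taken in transcribed-strand orientation — minus-strand loci
contribute the reverse complement of their genomic segment, applied
exactly once. A discordant column counts only when the 5 columns on
each side are gap-free exact matches; this flank rule suppresses
alignment-edge and indel artefacts, and counts are monotone
non-increasing in the flank width.

A-to-I editing is read by sequencers as G, producing A(genome)→G(cDNA)
discordance; polymorphism and sequencing error are direction-symmetric.
The reported editing fraction is the excess-asymmetry estimator

    f = (n_AG − n_GA) / (n_AG + n_GA)

with the raw totals always echoed, so any alternative summary can be
recomputed. `f` lies in [−1, 1], is 0 under label symmetry, and the
flank-survival factor cancels in the ratio, which is what makes the
estimator insensitive to the flank width under a uniform background.
The 3′-UTR comparison (longest-ORF end to the first run of ≥ 8 A,
taken as the polyA tail) reports per-clone mismatch counts and the
aggregate mismatch rate, an upper bound on genome draft error since it
includes polymorphism and editing.

## EST processing

A read is kept iff it contains a contiguous run of **more than 100**
bases each with Phred quality ≥ 10 — the run boundary is strict
(exactly 100 is discarded). Low-complexity masking lowercases
homopolymer runs ≥ 12 and dinucleotide repeats ≥ 8 units; masked bases
are excluded from clustering seeds but still vote in consensus.

The clusterer is an explicit greedy stand-in for a production
assembler: single-linkage over ungapped overlaps ≥ 40 bp at ≥ 95%
identity, seeded by shared unmasked 16-mers (probes at every position
against an index strided at 16, guaranteeing a seed for any shared
exact stretch ≥ 31 bp on any diagonal). Once two reads share a
component, further links between them are skipped, so the link graph is
a spanning forest and member offsets propagate consistently; consensus
is a per-column majority vote. It produces structurally faithful
contigs (members, consensus offsets) for downstream logic and makes no
claim to reproduce any production assembler's output on real data; the
40 bp / 95% defaults are knobs, not claims.

Clone selection takes each contig's 5′-most member (minimal consensus
offset; ties to the longer read, then id). Re-run incrementally, a
newly 5′-most member is *appended* with reason `upstream_update` —
prior picks stay, mirroring a sequencing pipeline where selected clones
are already in progress. Singlets are added only when their assigned
gene has no counterpart among contig picks.

The closed-form miss probability `(1 − f)^n` gives the chance a
transcript at expression frequency `f` is absent from `n` cloned
transcripts; at `f = 6×10⁻⁵` and `n = 10,000` it is 0.5488, i.e. a
transcript rarer than 0.006% of the pool is more likely missed than
sampled.

## Gene and GO rollups

A similarity hit assigns a gene only when its score is strictly above
50; per (query, species) the best-scoring gene wins, ties to the
smaller gene id. Rollups count unique genes, genes without a
homolog-group id, and unique homolog groups (a group counts once
regardless of how many genes map to it). GO classification counts
redundantly: each query adds 1 to *every* term its gene maps to within
a namespace, queries without terms are omitted, and an aggregation view
folds terms below a floor (default 1000) into "Others". Only direct
gene→term links are counted; no propagation up the ontology graph is
attempted.

## The synthetic data generator

The generator emulates the study conditions end to end and ships a
ground-truth ledger (per-read source gene, truncation offset, editing
and polymorphism sites, expression frequencies) for parameter-recovery
tests. Defaults, with rationale:

| parameter | default | rationale |
|---|---|---|
| `full_length_prob` | 0.75 | the enrichment level of 5′-cap-selected libraries: about three-fourths of clones retain the start codon |
| `truncation_geometric_p` | 0.01 | geometric overhang (mean 100 nt) beyond the start-codon region for truncated clones |
| `polymorphism_rate` | 0.002 | cDNA-vs-reference differences stay below the ~0.4% level a draft-genome comparison tolerates |
| `seq_error_rate` | 0.001 | post-filter single-pass read accuracy |
| `editing_rate` | 5×10⁻⁴ per A | editing sites are rare relative to polymorphism |
| `expression_law` | Zipf exponent 1.0 | typical transcriptome rank-frequency decay; `rare_gene_freq` can pin one gene to an exact frequency for detection experiments |
| `read_length` | 800 nt | a 5′ read long enough to traverse the CDS of the simulated genes (60–200 aa) |

Genes are single-isoform, 1–4 exons (introns 200–1000 bp), with a
30–80 nt 5′-UTR, a stop-free random CDS, and a 100–200 nt 3′-UTR kept
free of ≥ 7-base A runs so the polyA-tail detector cannot fire inside
it. Duplicated genes are placed on a different sequence than their
template and diverge only silently: UTR substitutions at 3% plus
synonymous codon substitution in the CDS, so ORF lengths and proteins
are preserved while every CDS-spanning alignment strictly prefers its
own locus (without this, equal-scoring anchors would collapse both
copies onto one locus). Pseudogenes are such copies with a premature
stop at one-third of the CDS, giving truncated ORFs relative to the
template.

**Truncation model.** Non-full-length clones model incomplete
first-strand synthesis: the 5′ truncation always removes the start
codon region (start plus first 10 codons) before adding a geometric
overhang. No truncation-length distribution is established for such
libraries; this memoryless choice is a stand-in, but the floor is a
modelling commitment — it is what makes the library's start-codon
fraction equal its full-length enrichment level, which is precisely
what the enrichment percentage of a real library measures.

**Editing and polymorphism.** Editing sites are A positions on the
transcript, at least 6 apart and 5 from the ends, so every injected
site passes the 5-base flank rule in the noiseless limit (estimator
recall 1). Edited sites are constitutively edited. Polymorphisms ride
the read haplotype (breed vs. reference differences), substitute to a
uniform random other base (hence a symmetric A↔G background), and are
kept out of editing-site flank windows so the two signals stay
separable in recovery tests.

What the generator does **not** emulate: alternative splicing (one
isoform per gene), chemistry-specific error profiles (errors are
uniform substitutions; qualities are flat), heterozygosity (polymorphic
alleles are fixed in the reads), internal priming and chimerism, and
genome-scale repeat families. Passing recovery tests therefore
demonstrates the algorithms' correctness under their stated
assumptions, not robustness to every artefact of real libraries.

## The aligner used in tests

The pipeline consumes alignments from the tabular format; for
self-contained runs a naive k-mer-seeded (k = 20), ungapped, x-drop
extended matcher generates them, with score 2·matches − 3·mismatches.
It handles substitution-level divergence only (no gaps) — adequate for
the generator's reads, not a general aligner. Ungapped extension can
overrun an exon boundary by a few chance-matching bases, so locus hulls
may exceed true gene spans by single-digit base counts; recovery tests
therefore assert locus/gene identity by overlap, not exact span
equality. Protein hits come from the same extension logic over the
three forward-frame translations (seed k = 6 aa).

## Report accounting

Summary tables must satisfy: ESTs in contigs + singlets = total (per
library and in totals), mapped ≤ sequenced, forward + reverse = total
per chromosome row, and every totals row equals its recomputed column
sum. The one exception is the per-library loci column, whose published
total deduplicates loci shared between libraries and is therefore not a
column sum. Transcriptions of the published per-library and
per-chromosome tables ship with the package as TSV fixtures; they
exercise the accounting layer only — the pipeline never claims to
regenerate them from data.

## Problem sizes in the test suite

The suite runs simulations of 5–50 genes on 0.1–0.7 Mb toy genomes with
150–10,000 reads, 1000-instance randomized oracle comparisons for the
merge closure, and 100–400 seeded replicates for the stochastic
estimator checks; the whole suite completes in well under a minute of
CPU. Sizes were chosen so that every stochastic tolerance (binomial or
replicate-based 3-standard-error bands) is comfortably resolved.

## Known limitations

- The clusterer's offset propagation assumes a consistent layout; with
  heavily chimeric reads, conflicting diagonals would be silently
  resolved by the spanning forest rather than reported.
- The editing estimator's background symmetry assumption fails under
  strand-biased error processes, which the generator does not model.
- `merge_loci` treats member sets as opaque; it does not re-check that
  a merged member's own alignments span the union hull.
- The excess-asymmetry formula is this package's choice of summary for
  the editing counts; the raw counts are always reported so other
  summaries remain computable.
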