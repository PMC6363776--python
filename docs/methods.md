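# Methods

`lncrep` implements, as a reusable and tested pipeline, a decision procedure
for building cell-type-specific catalogues of long non-coding RNAs (lncRNAs)
from bulk RNA-seq-derived inputs, together with replicate-consensus
open-chromatin maps from ATAC-seq peak calls and a cross-cell-type isoform
correspondence analysis. Read-level processing (alignment, transcript
assembly, quantification, coding-potential scoring, peak calling) is out of
scope: the pipeline consumes their outputs — assembled transcript models
(GTF), transcript × replicate FPKM tables, per-transcript coding-potential
scores in [0, 1], and per-replicate peak intervals (BED/narrowPeak).

## Coordinate model

All internal coordinates are 0-based half-open; GTF's 1-based closed
coordinates are converted exactly at the I/O boundary, so interval lengths
are always `end − start` and a single convention holds everywhere. Loci are
displayed in that convention (`chrom:start-end`, length `end − start`).
Strand is `+`, `-` or unknown (`.`). The TSS is the single 5′-most
transcribed base; requesting the TSS of a strand-unknown transcript is a
contract error rather than a guess. Chromosome names are used verbatim; a
namespace mismatch between inputs is reported as a warning with the
symmetric difference of names.

## Repertoire construction

A transcript enters the lncRNA repertoire of a cell type when it passes, in
order:

1. **Length** — spliced length (sum of exon lengths) ≥ 200 bp, inclusive.
   The criterion applies to spliced length, not genomic span, because
   "lncRNA length" conventionally means transcript length.
2. **Expression** — FPKM ≥ 1 in at least one replicate *and* at least two
   replicates with non-null (strictly positive) FPKM. Both counts are
   configurable so 2-replicate designs remain expressible; the defaults
   reproduce the 3-replicate rule.
3. **Coding potential** — CPAT-style score strictly below 0.44. The cutoff
   is exclusive: published cutoff semantics label scores at or above the
   cutoff as coding, and the tie resolves conservatively toward dropping.
4. **Proximity** — transcripts lying closer than 1 kb (span gap; 0 when
   overlapping) to a protein-coding gene on the same strand are removed.
   Strand-unknown transcripts are tested against genes on *both* strands —
   this is exactly the non-stranded-library case, where orientation of
   unannotated monoexonic transcripts cannot be inferred. Opposite-strand
   overlaps are retained; without that, overlapping-antisense lncRNAs could
   not exist.
5. **TSS open chromatin / monoexonic rule** — the TSS base is intersected
   with the consensus peak set; monoexonic transcripts without a peak on
   their TSS are discarded (they are indistinguishable from transcriptional
   background), while multiexonic transcripts are kept regardless, because
   polyadenylated sequencing under-represents 5′ exons and a missing first
   exon must not eliminate a spliced transcript. For strand-unknown
   transcripts either span endpoint may be the true start, so a peak
   containing either endpoint base counts as TSS support; this keeps
   unannotated monoexonic intergenic transcripts representable in
   non-stranded libraries, which the procedure requires.
6. **Major isoform** — one transcript per locus: the highest mean FPKM
   across replicates, ties broken by greater spliced length, then
   lexicographically smaller transcript id (a total order; output is
   byte-deterministic). Mean rather than maximum is used because a single
   noisy replicate should not decide the representative isoform.
7. **Novelty** — with assembler class codes present, codes `-`/`x`/`u`
   (unknown intergenic, opposite-strand exonic overlap) mark novel
   transcripts; any other code is *annotated* iff the biotype is a long
   non-coding class (`lncRNA`, `antisense`, `non_coding`), and otherwise
   the transcript is not a lncRNA candidate and leaves the set (counted).
   Without class codes, a reference annotation is required and a transcript
   is annotated iff its intron chain exactly matches a reference
   non-coding transcript on the same strand (monoexonic: ≥ 50% reciprocal
   span overlap with a reference monoexonic non-coding transcript).

The filter order is fixed as listed. Nothing in the procedure mandates a
particular order, so each stage's drop count is recorded in the repertoire
provenance and `input = output + Σ drops` always holds, making any
re-ordering dispute auditable from the numbers.

## Positional classification

Each accepted lncRNA receives exactly one category relative to
protein-coding genes:

- **overlapping antisense** — span intersects a coding gene on the
  opposite strand (highest precedence);
- **divergent** — no overlap; nearest opposite-strand coding gene within
  the neighbourhood window lies on the lncRNA's 5′ side (head-to-head);
- **convergent** — same, on the 3′ side (tail-to-tail);
- **intergenic** — nearest coding gene farther than the window on either
  strand.

The neighbourhood window defaults to 1 kb, the same constant as the
proximity filter, so the four categories tile all cases: same-strand
neighbours within 1 kb were already removed, and strand-unknown survivors
are necessarily beyond the window, hence intergenic. Orientation is decided
from which side of the lncRNA the opposite-strand gene lies, not from
promoter-to-promoter distance, and distances are span gaps (0 = overlap).
With qualifying genes on both sides the nearer wins; an exact tie resolves
to divergent, promoter sharing being the biologically salient case. Note
that flipping all strands *without* mirroring coordinates swaps
divergent and convergent — the true symmetry of the scheme is reflection
(strand flip plus coordinate mirror), and the tests assert exactly that.

## Open-chromatin consensus, partition, annotation

Within each replicate, peaks separated by less than 100 bp are merged
(strict inequality: a 100-bp gap stays split). A condition's consensus is
computed from the merged union of all replicates' peaks: a candidate region
is retained iff it overlaps (≥ 1 bp) at least one peak from *every*
replicate. "Present" means ≥ 1 bp overlap — the default semantics of the
interval-intersection tooling this kind of analysis uses; no
reciprocal-overlap fraction is imposed. Union regions keep per-region
support bookkeeping simple and match per-region peak counting; an
intersection mode returning the base-level core covered by every replicate
is available (`mode="intersection"`), and is the form in which consensus
coverage is provably anti-monotone in the number of replicates. The <100-bp
merge applies both within replicates and to the pooled candidates.

Cross-condition specificity is decided per consensus peak against the
*other condition's replicate peak sets*, not its consensus: overlapping
none of them makes the peak condition-specific; overlapping all of them,
common; overlapping only some, excluded from the stringent partition and
reported separately. Per side, `specific + common + excluded = consensus`
always holds and is verified at reporting time.

Feature annotation assigns one label per peak at the peak midpoint with
precedence promoter > exon > TTS/3′UTR ("others") > intron > intergenic.
The promoter window is strand-oriented `[TSS − 1000, TSS + 100)`; the TTS
window mirrors it downstream of the TTS. Midpoint assignment (single label)
keeps feature percentages summing to 100. TSS profile matrices report, per
TSS and per bin, the fraction of the bin covered by peaks, strand-oriented
so upstream is always left.

## Isoform correspondence and specificity

Two repertoires are compared by transcript matching: a pair is accepted
when (i) the shared *exonic* length is at least 90% of each transcript's
spliced length — reciprocal, against each side, since "reciprocal" implies
both, and exonic rather than span overlap because span overlap would let
intron-containing matches pass trivially; (ii) exon counts are equal; and
(iii) each pair of exons, matched by rank (valid because counts are equal),
differs by at most 50 bp for internal exons and 500 bp for the outermost
exons (per exon, both boundaries — outer exons have ragged ends, splice
sites are precise). A transcript with several accepted partners keeps the
one with maximal summed reciprocal overlap and is flagged `ambiguous`: the
deterministic stand-in for manual curation, surfaced for review rather than
silently resolved. Matching is greedy on that score with id tie-breaks, so
the result is symmetric in the two repertoires.

Specificity levels: a matched transcript is *same gene, same isoform*; an
unmatched transcript whose gene corresponds to a gene in the other
repertoire is *same gene, specific isoform*; the rest are *specific gene*.
Gene correspondence — needed for the middle level but not defined by
transcript matching alone — is transcript-match-or-locus-overlap (≥ 1 bp on
compatible strands).

When one repertoire comes from a non-stranded library, the stranded side
first sets aside its unannotated monoexonic transcripts lying within 1 kb
of a coding gene on any strand (harmonization): the non-stranded side could
never have kept such transcripts, so comparing them would bias the
specificity estimate. They remain in the repertoire; they are only excluded
from the comparison, and the exclusion count is logged.

Protein-coding transcripts are compared with the same machinery after the
expression filter only (the lncRNA-specific filters do not apply to them);
transcript- and gene-level specific fractions are reported per side.

## Synthetic data generator

The generator emulates the targeted study design: two cell types, three
RNA-seq replicates each, three vs two ATAC-seq replicates, stranded A and
(by default in the `paper_like` fixture) non-stranded B. Loci are placed
sequentially with ≥ 8 kb spacing so that each planted lncRNA's category is
determined solely by its own anchor gene: divergent anchors sit at a
700–950 bp gap (within the 1-kb window but far enough that the two TSS
peaks can never merge under the peak model's bounded jitter), convergent
anchors at 250–950 bp, antisense lncRNAs inside an opposite-strand gene
with ≥ 700 bp between the two TSSs. Expression is log-normal FPKM
(log10 mean 0.7, sd 0.5, floored at 1.5 for active transcripts) with
multiplicative per-replicate noise (log10 sd 0.15) and dropout (p = 0.03);
coding scores are Beta-distributed around 0.12 (non-coding) and 0.85
(coding) with a 2% misclassification rate; ATAC peaks are 200 ± 20 bp wide,
centred on active TSSs with ±10 bp uniform start jitter and 2% replicate
dropout. Noise, condition-specific and deliberately partial peaks live in a
reserved coordinate region with 2-kb spacing so they can never interact
with TSS peaks or each other. Every knob is independently zeroable
(`SimulationSpec.zero_noise()`), so each filter can be tested in isolation.
Where the emulated study fixes a value (replicate counts, thresholds,
library strandedness) the default is that value; remaining magnitudes
(locus sizes, expression scale, peak width) are one-time choices of
realistic scale for annotation-level simulation.

Decoy transcripts violating exactly one rule each (short, under-expressed,
single-non-null, coding-like score, same-strand proximal, monoexonic
without TSS peak, wrong biotype) are planted per cell type and labelled
with the rule they violate, so recovery tests can attribute failures.

Ground-truth semantics: truth repertoires, categories, novelty,
correspondence pairs and specificity levels are the *planted intent* —
noise degrades the pipeline's recovery of them, and at zero noise recovery
must be exact (the definitive end-to-end test). Truth consensus peaks and
partition classes are derived from the *realized* peak intervals, which a
correct implementation reproduces exactly at any noise level. The
generator does not simulate reads or sequence content: coding scores are
simulated rather than computed from sequence (scores are pipeline inputs),
expression noise is independent across transcripts (no shared library-size
factors), and peak geometry is idealized (no overlapping peak complexes).
Passing recovery tests therefore demonstrates correctness of the decision
procedure, not robustness to every artefact of real sequencing data.

## Problem sizes and determinism

The bundled fixtures are deliberately small: `tiny` (1 chromosome, ~20
coding genes, 12 lncRNAs) for unit tests and `paper_like` (2 chromosomes,
~100 coding genes, 60 lncRNAs across all four categories, 3 vs 2 ATAC
replicates, non-stranded B) for end-to-end and sweep tests — annotation-
scale simulations that keep the whole suite in seconds while exercising
every code path, including the non-stranded monoexonic discard and the
harmonization rule. All randomness flows from one seeded NumPy generator;
placement is integer-based and FPKM values are written at fixed precision,
so a fixed seed reproduces byte-identical files across platforms.

## Known limitations

- Strand assignment for multiexonic transcripts is taken from the GTF
  strand field (the assembler's splice-site inference); the package does
  not re-derive it from sequence.
- Gene-level correspondence by locus overlap can conflate genuinely
  distinct overlapping genes; the pair table and ambiguity flags expose
  the evidence for review.
- Feature annotation is midpoint-based by construction; peaks spanning a
  feature boundary receive the midpoint's label only.
- The brute-force per-base oracle used in tests is limited to ≤ 10-kb toy
  chromosomes; correctness at genome scale rests on the interval-sweep
  algorithms it validates.
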