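# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic corpus does and does not emulate, and the design
decisions taken where more than one reasonable convention exists.

## Coordinates and transcript models

All internal coordinates are 0-based half-open on an explicit strand;
GTF/GFF3 (1-based inclusive) is converted at the I/O boundary. A transcript
is an ordered chain of non-overlapping exons separated by ≥ 1 nt introns;
unstranded records are rejected because every comparison downstream
(classification, splice-site typing, end clustering, sequence extraction) is
strand-aware. The intron chain — the ordered (donor, acceptor) pairs — is
the identity of a splice structure: two transcripts with equal chains are
the same splice form regardless of their end positions.

## Gene loci and isoform categories

Loci are the connected components of the exon-overlap graph (≥ 1 bp,
same chromosome and strand, single linkage). This is implemented as a sweep
over sorted exons and verified in tests against an explicit union-find
closure of the pairwise relation.

Categories: *known* requires an exact intron-chain match (mono-exon
transcripts instead require both ends within a tolerance, default 50 nt, of
a mono-exon reference transcript — the annotation gives no splice sites to
compare, so ends are all there is); *novel_of_annotated* requires ≥ 1 bp
same-strand exonic overlap; everything else, including antisense-only
overlap, is *novel_locus*. End positions never affect "known": end variation
is measured separately as aTSS/aTTS, otherwise every alternative-promoter
isoform would spuriously become a novel isoform.

## AS event detection

Events are enumerated over unordered transcript pairs within a locus and
deduplicated by (type, anchor coordinates), with inclusion/exclusion
transcript sets accumulated across pairs. The five rules:

- **IR** — an intron of one form lies strictly inside an exon of the other
  (strict: the exon must extend past both splice sites).
- **ES** — ≥ 1 consecutive internal exons of one form are spanned by a
  single intron of the other whose boundaries equal the outer boundaries of
  the flanking introns.
- **A5SS / A3SS** — two introns share exactly one boundary; the type is
  assigned in transcript orientation (donor = 5′ splice site). The variable
  region between the two differing boundaries must be contiguous exon in
  the shorter-intron form. This coverage condition is essential: without
  it, every exon-skipping pair would additionally fire the donor- and
  acceptor-shift rules through its spanning intron, and the five types
  would not be disjoint.
- **MXE** — two non-overlapping internal exons, one per form, with equal
  outer flanking splice sites, each absent from the other form. Exclusivity
  is required within the pair only.

The detector is validated two ways: exhaustively against an independently
written base-level-coverage oracle on hundreds of random loci, and by exact
(precision = recall = 1) recovery of planted events on the synthetic corpus.

Dominant-splice-site ties break toward the 5′-most site in transcript
orientation; offsets are signed in transcript orientation (negative =
upstream). Intron boundary dinucleotides are read on the transcript strand,
canonical meaning GT..AG at the DNA level.

## Differential splicing

rMATS-style read-level modelling is out of scope; the stand-in is
transparent: PSI = inc/(inc+exc) per sample, a two-sided Fisher exact test
on the 2×2 inclusion/exclusion table per sample pair, BH correction across
events within a pair, and a call at q < 0.05 with |ΔPSI| ≥ 0.1 (both
configurable). Events with zero coverage in either sample are skipped for
that pair. Calibration is checked on a null simulation at 1000× junction
coverage, where the exact test's discreteness is negligible and the
rejection rate at 0.05 sits within Monte-Carlo error of nominal; at low
coverage the test is conservative, which is the standard behaviour of
Fisher's test, not a defect.

## Ends and poly(A) sites

End clustering is 1-D single linkage with a 50 nt default tolerance (the
choice is a compromise between TSS "wobble" in long-read data and genuinely
alternative promoters; it is reported in output headers). A gene uses
alternative starts/ends when it has ≥ 2 clusters.

The poly(A) tail rule is numeric: some 30-base window of the 3′
soft-clipped read segment must contain at least eight adenines and at most
one non-A base ("less than two" read strictly). Windows slide over the clip
by default; an anchored mode (single window at the clip start, adjacent to
the cleavage site) is available since the rule's anchoring is ambiguous.
Segments shorter than 30 nt are evaluated as-is — this is where the ≥ 8 A
condition binds, since a full 30-base window with ≤ 1 non-A necessarily has
≥ 29 A. The implementation is compared exhaustively with a literal
restatement of the rule over all 4⁸ 8-nt tails and 10⁴ random 60-nt tails.

Cleavage sites are the strand-adjusted boundary after the last aligned
base; per gene, sites within 24 nt (common 3′-end-seq practice) collapse to
their modal position. Composition profiles cover −50..+10 in transcript
orientation with rows normalised over A/C/G/T. Motif discovery is replaced
by k-mer enrichment: windows 50 nt upstream of each site, background from
seeded mononucleotide-preserving shuffles (or an explicit window set),
one-sided binomial tests, BH, ranked by (p, fold).

## lncRNA identification

Candidates are restricted to novel-locus transcripts (no same-strand
overlap with known gene models — novel isoforms of coding genes, e.g.
intron-retaining forms with broken ORFs, would otherwise leak through the
ORF filter). Filters: length ≥ 200 nt, longest ATG-initiated ORF ≤ 100 aa,
coding score < 0.5. A garbled secondary length clause in the originating
protocol (< 350 nt) is exposed as an optional filter, off by default.

The coding score replaces external classifiers with one transparent
logistic model over three classic features: log ORF length (aa), ORF
coverage of the transcript, and the Fickett TESTCODE statistic computed
with the standard published position-asymmetry and composition lookup
tables. The weights (intercept −8, 1.5·ln(aa+1), 3·coverage,
3·(Fickett−0.95)) were fixed once so that long transcript-covering
codon-structured ORFs score near 1 and short ORFs in unstructured sequence
near 0; on labelled synthetic sequences (codon-structured vs
mononucleotide-shuffled) the score separates with AUC ≈ 1. This is a
deliberately simple score — it is not a re-implementation of CPAT or PLEK
and has not been calibrated on real plant transcripts.

Positional classes are assigned with precedence sense_overlapping > lncNAT
> intronic > lincRNA. Targets: host gene for the three overlap classes,
nearest coding gene within 100 kb for lincRNAs; correlation is Pearson on
log2(FPKM+1) with the ±0.6 threshold.

## Expression

FPKM uses library sizes defaulting to column sums. PCA treats samples as
observations of log2(FPKM+1)-transformed, feature-centered data; component
signs are fixed by making the largest-magnitude loading positive, so scores
are fully deterministic, and the implementation is tested against a direct
eigendecomposition of the covariance. Profile clustering is k-means (k = 5
default) on row-z-scores with a fixed seed and 10 restarts; labels are
renumbered by descending cluster size with ties broken by smallest member
id, making the numbering invariant to row order. The no-replicate design
(single library per tissue) rules out dispersion-based DEG testing, so DEG
is a fold-change rule: |log2((a+1)/(b+1))| ≥ 1 and max(a,b) ≥ 1 FPKM,
with the union over sample pairs reported. Term enrichment is the classic
hypergeometric tail with BH — no term-graph decorrelation — and is labelled
as such in outputs.

## Domains

Domain tables are inputs (in real use, Pfam/hmmscan output as TSV).
Comparison is by multiset of domain names — presence-level, not
coordinate-level. Note a structural fact: against a max-cardinality
reference a *pure* gain is impossible (a strict superset isoform would
itself be selected as reference), so `classify_domain_change` takes an
explicit reference and `select_reference_isoform` (most domains → longest
ORF → smallest id) is only the default when none is designated.

## Synthetic corpus

The generator emulates the input structure of a multi-tissue long-read
survey: ~200 multi-exon genes on 2 chromosomes (exons 100–300 nt, terminal
exon 350–450 nt to hold a 250 nt 3′ UTR, introns 120–500 nt, GT..AG
boundaries), one planted feature per gene at rate 0.12 per kind
(IR/ES/A3SS/A5SS/MXE/aTSS/aTTS; splice-site shifts 4–20 nt, end shifts
200 nt), coding exon content built from biased codons so Fickett has
signal, 12 lincRNAs in intergenic gaps and 8 antisense lncNATs over host
3′ UTRs with all ORFs mutated below 90 aa, three error-free FLNC reads per
isoform carrying 30 nt pure-A tails, the TCTGT signal written at −30..−10
upstream of 70% of cleavage sites and an A-rich 0..+10 downstream bias, a
7-sample FPKM matrix with 5 planted lncRNA profile clusters, exact-r
(Gram–Schmidt) lncRNA–target correlations at ±0.8 (65% positive), ~30%
strongly differential genes, and per-isoform domain tables with planted
loss/gain/both changes (rates 0.35/0.15/0.15 among two-isoform genes).

Deliberate simplifications, hence what passing does and does not show:
each gene carries at most one planted feature, so feature *co-occurrence*
(e.g. AS genes also using aTSS/aTTS, prominent in real data) is absent by
construction and the coupling table is exercised structurally, not
distributionally; reads are error-free and exactly aligned (real FLNC
reads carry residual errors and alignment wobble, so real-data recall will
be below the 1.0 achieved here); expression noise is Gaussian in log space
without count overdispersion; lncRNA sequence is random DNA with broken
ORFs, not biologically derived noncoding sequence. Sizes (200 genes, 3
reads/isoform, 7 samples) were chosen so the full corpus builds in about a
second and the complete pipeline runs in a few seconds while every planted
category still has ≥ 20 instances.

## Determinism

A single integer seed drives corpus generation, k-means, background
shuffles and the null simulations; generation and the full pipeline are
byte-identical across reruns with the same configuration. Output tables
use fixed column orders, explicit sorts and a fixed float format.
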