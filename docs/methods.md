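# Methods

## Problem and model

FGFR2's last exon (E18) encodes the receptor's C-terminal tail, which
attenuates kinase signalling. Genomic alterations that remove E18 —
rearrangements breaking in intron 17 (I17), copy-number gains restricted
to exons 1–17, E18 splice-acceptor mutations and nonsense/frameshift
mutations in the proximal E18 coding sequence — converge on a truncated,
constitutively signalling receptor. The pipeline decides, per tumour
sample and from four independent evidence lines (structural variants,
copy number, small variants, RNA splice junctions), whether such a
truncating alteration is present, and provides the enrichment statistics
used to contrast co-driver landscapes between truncated, fully amplified
and hotspot-mutant samples.

## Coordinates, gene models and phases

Internal coordinates are 0-based half-open; GTF I/O converts to/from the
1-based inclusive dialect, BEDPE input stays 0-based. Exon and intron
indices are 1-based in transcript order, so "I17" is the intron between
exons 17 and 18 on either strand. One canonical transcript represents
each gene: the longest total CDS, ties broken by lexicographic transcript
id (determinism matters more than the particular rule; no isoform set is
maintained). Protein length is CDS/3 − 1, counting the stop codon in the
CDS. Exon phases are cumulative CDS length mod 3; the first coding exon
starts at phase 0 and phases chain across the transcript. Phase
arithmetic is length-based throughout — no genome sequence is read.

## Rearrangement classification

Each breakpoint pair is annotated against the gene models (intron, exon
or intergenic; supporting-read orientation recorded relative to the
annotated gene's coding strand) and assigned exactly one RE type, with the
rules evaluated in a fixed order because several can apply at once:

1. **unresolved** — the upstream (gene-of-interest) side is supported by
   antisense reads, or the junction is a single breakend;
2. **internal** — both breakends lie within the gene of interest;
3. **intergenic space** — the partner side falls outside any coding gene
   (non-coding genes count as intergenic for frame purposes);
4. **out-of-strand** — a sense-supported upstream side joined to an
   antisense-supported partner;
5. frame evaluation — **in-frame fusion** when the phase offered by the
   upstream side equals the phase expected by the downstream side, else
   **frame-unknown**.

"Both exons in frame" is implemented as splice-phase compatibility: the
end phase of the upstream junction exon equals the start phase of the
downstream one. Codon-completeness of each exon alone is *not* required —
phase compatibility is the standard fusion-frame definition and
reproduces canonical I17 fusions as in-frame. The stricter reading
(additionally requiring whole-codon exons) is available via
`require_codon_complete=True`. For exonic breakends the phase at the
break is the exon start phase plus the within-exon CDS offset, mod 3;
breaks in untranslated exon parts make the frame unpredictable
(frame-unknown). The classification backbone is the partner encoding the
longer protein; a sole coding partner wins, ties break lexicographically.

The RE allele frequency is junction ploidy divided by the total gene copy
number at the gene of interest, clamped to [0, 1]; the concrete quotient
is this package's definition (recorded in output metadata) since only the
use of junction-ploidy estimates is prescribed upstream. A sample is
DNA-level E18-truncated when any non-unresolved RE with its
gene-of-interest breakend in the last intron or last exon has allele
frequency strictly > 0.15. With several REs per sample each gets its own
frequency and the sample-level call is the disjunction.

## Copy-number rules

E1–E17 and E18 summaries over segment profiles are length-weighted means
of the segments overlapping those exons (the summary statistic is this
package's choice). Boundary semantics follow the printed inequalities
exactly: strict `>` for the absolute-CN (> 5, difference > 2) and
log₂-ratio (> 0.3) rules, inclusive `≥` for the cell-line rule (≥ 2) and
the panel rule (≥ 80 % of targets at CN ≥ 4 + median ploidy). A partial
E1–E17 call additionally requires a segment breakpoint inside the last
intron, detected with a ±1 bp tolerance as a coordinate-dialect guard.
The panel rule's "differential gain" margin for the E18 target is not
quantified upstream; the default is simply E18 below the amplification
threshold while ≥ 80 % of E1–E17 targets pass, with the margin
configurable (`e18_margin`).

## Mutations

Hotspot lists are configuration data defaulting to FGFR2
Ser252/Cys382/Asn549/Lys659 and FGFR3 Arg248/Ser249/Tyr373/Lys650
(missense only — a nonsense change at a hotspot position is not a
hotspot). E18-truncating nonsense/frameshift mutations partition into
proximal (residues 768–783) and distal (784–821); frameshifts are
assigned by their first altered residue. HGVS-p strings ("p.N549K",
"N549K", "p.Asn549Lys", "p.E769*", "S799fs") and explicit
(position, ref, alt) triplets classify identically. The E18
splice-acceptor window defaults to the two intronic bases preceding E18
plus its first exonic base and is resolved at annotation time; whether
upstream splice-donor variants should also count is unknown, so only
acceptor-window variants are flagged.

## RNA evidence

Junction usage is per-acceptor fraction of unique, non-duplicate reads
from the E17 donor; zero donor reads propagate as *undefined*, never as
0. The RNA-level truncation call sums usage over the RE-derived acceptor
classes (fusion partner, intergenic pseudoexon, transposon) and requires
strictly > 15 %; alternative last exons C3/C4 are truncation-like and can
be added to the evidence classes, while C2 overlaps the proximal
canonical C terminus and is treated as full-length-like. Chimeric reads
are discarded when multi-aligned, duplicated or mapping to
mitochondrial/immunoglobulin/HLA partners, and breakpoints survive with
more than two supporting reads. E18 loss compares E18 normalised to the
median of E1–E17 against the minimum normalised value among normal
samples. Composite FGFR expression normalises each receptor by its cohort
geometric mean on the linear scale (pseudocount 0.01 on zeros,
configurable) and sums over FGFR1–4; "high" means strictly > 3. The scale
on which that threshold was originally applied is not stated, so both the
score scale and the flag threshold are configurable. High-C3-usage
outliers use Z-score normalisation with a one-sided upper-tail normal
p < 0.01; a constant usage vector yields no flags and a warning.

## Integration

Category precedence is E18_TRUNCATED > FL_AMP > HOTSPOT > WT, making the
categories mutually exclusive. Distal truncating mutations are recorded
as annotations but never trigger the truncated category (functionally
they showed limited transforming potential). A sample carrying both an
in-frame fusion and a full-length amplification stays E18_TRUNCATED with
the dedicated FUSION_PLUS_AMP subgroup (amplification acts as a modifier,
mirroring the trial re-analysis subgrouping); non-canonical REs
co-occurring with amplification keep their RE subgroup. How samples with,
e.g., both a hotspot mutation and partial amplification were originally
handled is not stated; the precedence above is this package's documented
choice. DNA and RNA thresholds (RE allele frequency; E17 junction
frequency) are independent evidence lines and are never combined into one
score. Printed-precision arithmetic uses decimal half-up rounding: two
decimals for incidences (percent of assayed samples), one for
within-class fractions — verified against all printed values. ΔT/ΔC is
the ratio of mean (last − first) tumour volumes of treated versus control
animals; a non-growing control arm yields an undefined ratio rather than
a sign flip.

## Enrichment statistics

The proportion Z-test is the pooled two-proportion test with a one-tailed
upper p; a degenerate pooled proportion (0 or 1) returns p = 1 with a
warning. The focal comparison is the category versus the union of the
other two altered categories (the within-altered contrast); a
`vs_all` mode contrasts against all other samples including WT, since the
original contrast is ambiguous. Fisher's exact test (category versus WT)
computes the two-sided p by point-probability summation — the sum of
hypergeometric probabilities of tables no more probable than the observed
one, with a 1 + 1e−7 relative guard against floating-point ties — which
is the common two-sided convention (documented because conventions
differ). The odds ratio is the cross-product, with +0.5 added to all
cells iff any cell is zero (Haldane–Anscombe), and the 95 % CI is the
normal approximation on log OR (Woolf). BH correction is applied within
each (test family × category) gene list, matching per-panel correction.

## Synthetic cohorts

The generator emulates the *statistical structure* of the cohort inputs
at the call/count level: no reads, no sequence. The toy genome is one
chromosome with an 18-exon, 821-aa FGFR2-like gene (2,466 nt CDS, exon 17
ending at phase 1, a 6-kb I17 hosting the alternative last exon C3, C2/C4
annotated on non-coding transcripts), a 974-aa partner with one
phase-compatible and one incompatible intron, a shorter and a
minus-strand partner, a non-coding gene and an intergenic tract. Planted
alteration kinds are drawn from a mixture whose default gives in-frame
fusions the largest RE share and leaves 30 % wild-type, with enough mass
in every class to exercise each rule on a few-hundred-sample cohort. RE
allele frequencies are drawn clear of the 0.15 threshold (passing:
U(0.30, 0.95); failing, 15 % of REs: U(0.04, 0.10)) so planted truth is
unambiguous; copy numbers use a diploid baseline with Gaussian noise
(σ = 0.12, truncated at 0) and amplification levels U(6.5, 12); junction
counts are multinomial at depth 200 over C1/C3/C4/partner acceptors; the
driver matrix draws each gene independently with probability
sigmoid(logit(baseline 0.1) + planted log OR of the sample's category).
All randomness flows from one root `SeedSequence` split into named child
streams (sv, cn, mut, junction, expression, drivers), so adding a
generator does not perturb existing streams and a fixed seed reproduces
the bundle byte-identically.

What passing tests on these cohorts show — and what they do not: they
verify the decision rules, thresholds, arithmetic and statistical
calibration end to end, but the generator plants alterations well away
from decision boundaries and contains none of the messiness of real
data (breakpoint uncertainty, subclonality near thresholds, segmentation
noise at exon resolution, multi-RE samples, panel target dropout).
Recovery rates of 100 % are statements about rule correctness, not about
sensitivity on real tumours.

## Problem sizes and numerics

The cohort-scale checks use 1,000-sample cohorts, 1,000 random gene pairs
for the frame oracle, all 2×2 tables with n ≤ 60 against an
exact-integer enumeration oracle, 200 null replicates and 300 OR = 3
replicates (n = 2,000 each) for calibration — sizes at which every check
is stable across seeds yet the whole suite runs in well under a minute.
Usage fractions sum to 1 within 1e−12; the Fisher tie guard is relative
(1 + 1e−7); CI coverage is asserted within ±0.02 of nominal.

## Known limitations

Single canonical transcript per gene (which FGFR2 isoform anchored the
original exon numbering is unknown; the toy model is a generic 18-exon
gene). No derivative-chromosome reconstruction: complex, chained REs are
classified per junction, so a multi-breakpoint event that ultimately
restores an in-frame fusion is seen only as its parts. No breakpoint or
fusion discovery from reads, no segmentation from coverage, no
genomic-to-protein consequence annotation; inputs arrive at the
call/count level. The exact upstream definition of junction "ploidy" is
not specified; any consistently scaled junction-support measure works
with the same threshold semantics.
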