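# Methods

This note documents the models, conventions and numerical choices behind
`svscape`, what the synthetic data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Coordinates and variant model

All internal arithmetic is 0-based half-open; VCF I/O converts to and from
1-based coordinates. Because VCF pads deletions with the base before the
event, the 0-based start of a deleted interval equals the numeric POS
value, which keeps overlap arithmetic free of off-by-one cases. An
insertion is a point event: for genomic intersections (CDS assignment,
decile lookup, telomere distance) it occupies a single anchor base
`[pos, pos+1)`, while all size-based computations use its `svlen`. The
analyzed size range is 20 bp–50 kb split into "large indels" (20–49 bp)
and SVs (≥ 50 bp); multi-allelic records, breakends and inversions are
out of scope — the classifier is defined only for INS/DEL sequence
context.

Variant filters retain records with QUAL ≥ 5, svlen ≥ 20 bp and
type-specific read support (deletions ≥ 20 %, insertions ≥ 5 %). The QUAL
direction is deliberately "retain high-QUAL": it is the only reading under
which filtering shrinks a callset. Filtering is idempotent.

## Repeat classification

The extended local allele is 5× the variant size: 2× reference flank each
side, with the variant as the central 20 %. At contig edges flanks are
clipped and the variant region is tracked explicitly rather than
recomputed as "central 20 %", so clipped alleles classify correctly.
Deletions are classified from the reference allele (the deleted sequence
in context), insertions from the ALT allele.

**Built-in tandem detector.** For each candidate period p (1–500),
positions with `s[i] == s[i-p]` are matches; maximal-scoring segments
under the scoring 2·match − 7·mismatch with score ≥ 50 and identity ≥ 80 %
become annotations (period, modal unit as motif, copy number, purity).
Segments are extracted with a Kadane-style maximal-segment scan over
match/mismatch runs, which trims flanking noise that a purity-greedy merge
would absorb. Harmonics are suppressed: a candidate at period p is dropped
when ≥ 50 % of it is already covered by a smaller-period call (a
p-periodic array is trivially np-periodic). The detector tolerates
substitutions but not indels — a deliberate trade: on the generator's
pure planted arrays it is an exact oracle, and real data should flow in
through the Tandem Repeats Finder adapter instead. The scoring parameters
mirror the TRF recommended set (2 7 7 80 10 50 500).

**Built-in element matcher.** Exact 15-mers shared with a library
consensus (either orientation) seed hits; seeds on one alignment diagonal
are chained across gaps ≤ 50 bp and kept at ≥ 80 % identity.
`consensus_fraction` is the fraction of the canonical element covered by
the chain. Like the tandem detector it is substitution-tolerant only;
RepeatMasker `.out` files can replace it via the adapter, with
class/family strings mapped onto {SINE, LINE, DNA, LTR, Retroposon,
Other}.

**Decision rule.** Tandem classes are evaluated first: coverage of the
variant region (union of annotations, clipped to the region) per class;
the winner needs ≥ 75 %, ties break toward the larger-period class.
Otherwise mobile-element families are tried at the same 75 % bar, and a
variant containing ≥ 75 % of a whole canonical element is `complete`, else
`fragment`. Everything else is NONREP. Tandem-before-interspersed
precedence and the union (rather than per-annotation) coverage reading are
our choices; both are stated here because the procedure admits either.
Classification of an insertion equals that of its reverse complement by
construction (both detectors are strand-symmetric up to motif naming).

Homopolymer-labelled variants are flagged and excluded from all downstream
modules by default (long-read homopolymer error enrichment); a toggle
re-admits them.

## Cohort landscape

Sharedness: private (1 carrier), polymorphic (> 1 and < 50 % of
individuals), major (≥ 50 % but not all), shared (all); private takes
precedence at tiny n. Geography: focal-only / focal-absent / global by the
carriers' focal flags. Spread (focal-only variants only): private /
community-specific / widespread / shared-across-all-communities.

Reciprocal overlap between deletions is min(shared/len_a, shared/len_b).
Insertions are point-like, so their "overlap" is defined as the size ratio
min(svlen)/max(svlen) gated on anchors within 200 bp — the same window the
benchmarking criteria use. Novelty bands on the best single annotation:
high (> 80 %], moderate [50–80 %], low (0–50 %), none (0); high + moderate
count as annotated; "50–80 %" is read as the closed interval [0.50, 0.80].
A variant absent from the optional coordinate-mapping table (the lift-over
surrogate) is UNMAPPED and excluded from the annotated/unannotated
dichotomy.

Callset merging is single-linkage clustering on the matching criteria
(type, RO ≥ 0.5, breakpoints ≤ 200 bp) with the highest-QUAL member as
representative — a deliberately simple surrogate for graph-based SV
mergers, adequate for jitter at the tens-of-bp scale. Benchmarking matches
greedily one-to-one by descending overlap (the multi-match policy is
otherwise undefined); recall of an empty truth set is reported as NA.

Discovery curves add individuals in random order (default 10 permutations,
seeded) and report the mean cumulative count with a least-squares fit of
count = a + b·ln(n). The final value is permutation-invariant; the curve
is monotone by construction.

Telomere profiles bin each variant by min(pos, L − pos) into 500 kb
windows and average counts across chromosome arms; the optional smoother
is LOESS (statsmodels lowess, span 0.75) on log(count + 1).

Large-CNV regions: calls with p > 10⁻⁴ or length ≤ 50 kb are excluded
(the length bound is enforced as a filter with a warning, not an error,
since read-depth callers routinely emit smaller events), then
single-linkage merged at RO > 0.5; regions are classed
singleton/polymorphic/major by carrier count and genes are reported only
under full containment in the region span.

## Constraint

CDS assignment wins over non-CDS (any CDS bp hit); non-CDS is the gene
span padded ± 2 kb minus CDS; a variant touching genes in several deciles
counts once in the lowest (most constrained) decile. Region sizes use
merged interval unions per decile so shared exons are not double-counted.
Densities are count/bp; per-type densities are normalized to their
decile-10 value (decile 10 ≡ 1.0). Whether the ± 2 kb pad belongs in the
non-CDS denominator is ambiguous in prose descriptions of this analysis;
it is included here, consistent with counting variants in the pad.

## STR toolkit

Canonical motifs: the lexicographic minimum over all rotations of the
motif and of its reverse complement; all 2p representations collapse to
one class. Significant expansions require, conjunctively: period ≥ 3 bp,
gain ≥ 10 units, gain ≥ 50 % of the reference element, reference element
< 1 kb.

Diploid genotyping applies each haplotype's phased INS/DEL set to the
local reference (conflicting same-position edits on one haplotype are an
error), maps the site boundaries through the edits, and extracts a ± 50 bp
window; the longer consensus is `allele_A`. Period and motif come from the
built-in tandem detector on allele_A. On planted expansions allele lengths
are exact; the ≤ 2 bp acceptance slack absorbs boundary effects when an
edit sits exactly on a window boundary.

Cross-community variability uses one-way fixed-effects ANOVA (closed-form
sums of squares, F = MS_between/MS_within, upper-tail F p-value) with both
alleles of an individual entering as independent observations — a known
pseudo-replication, kept deliberately to mirror the standard field
procedure; the permutation-test cross-check in the suite shows the
practical consequence is small at the simulated scales. Zero within-group
variance with equal means returns F = 0, p = 1. Per-community SDs are
min–max normalized across communities ([0, 1]; all-zero for constant
rows); the normalization formula is our choice, as is the average-linkage
Euclidean clustering contract for heatmap ordering (presentation-only,
never asserted in tests).

## Population structure

Bray–Curtis on binary presence: 1 − 2·|shared|/(|A| + |B|); zero-variant
samples get dissimilarity 1 and a warning. PCOA is classical scaling
(B = −½·J·D²·J, eigendecomposition); coordinates use positive eigenvalues
only and percent variance divides by the sum of positive eigenvalues —
Bray–Curtis is a semi-metric, so negative eigenvalues occur and including
them would make "percent of variance" ill-defined.

WC84 F_ST computes per-locus variance components a (among populations),
b (among individuals within populations), c (within individuals) for
two-allele diploid data and combines them as θ̂ = Σa / Σ(a+b+c) across
loci. Missing genotypes are excluded per locus; loci monomorphic across a
pair, or with fewer than two genotyped individuals in either group, are
skipped. The locus subset takes up to 10,000 loci with cohort carrier
frequency strictly above 10 %, uniformly without replacement (all
qualifying loci, with a warning, when fewer qualify). A "haploid" fallback
treats each individual's presence bit as a homozygous genotype for
presence-only matrices; results are flagged with the mode used.

## Synthetic data generator

The generator defines the study conditions for every test. Defaults: four
focal communities of 8 diploid individuals plus a 6-sample outgroup;
Balding–Nichols divergence θ = 0.10; ancestral frequencies uniform on
[0.05, 0.95]; 40 % of variants focal-only, 10 % outgroup-only, 10 planted
single-carrier private variants; two 500 kb chromosomes; 40 genes spread
evenly over LOEUF deciles 1–10 (spans 4–8 kb, 2–4 CDS exons). Mobile
element consensus lengths track the characteristic family sizes (SINE-like
280 bp, retroposon-like 2 kb, LINE-like 6 kb) so insertion-size peaks
appear where a practitioner expects them. Variant classes are planted as:
whole-unit expansions/contractions at planted STR/TR/homopolymer arrays,
full-consensus insertions ("complete"), internal consensus slices
(30–55 %, "fragment"), and random non-repetitive sequence (rejection
sampled so no chance array passes the detector thresholds — the planted
class, not the detector, defines truth). Planted repeats are mismatch-free
by default; an optional substitution rate ≤ 5 % roughens them. Telomere
enrichment, when enabled, places 60 % of TR arrays within the terminal
10 % of each chromosome — a scaled analogue of sub-telomeric TR
enrichment on real chromosomes.

Genes do not overwrite the backbone, so variant placements may fall inside
gene spans (populating CDS/non-CDS/intergenic contexts) while planted
arrays are mutually exclusive with everything. Genotypes are binomial
draws from the community frequency; variants that draw no carriers are
redrawn (they would be unobservable in a joint callset), which slightly
tilts realized frequencies upward at low p — irrelevant at the simulated
frequencies but worth knowing. Fixed seed ⇒ byte-identical FASTA, VCF and
truth tables.

What the generator does **not** emulate: sequencing reads and their error
profiles (no FASTQ/BAM), linkage and recombination, mutation-rate
heterogeneity, nested or decayed repeats, indel-containing arrays, sex
chromosomes, somatic CNVs, and contamination. Passing tests therefore
demonstrate correctness of the analysis layer on clean planted truth, not
detector robustness on real noisy alleles — that is what the TRF and
RepeatMasker adapters are for.

## Problem sizes and determinism

The classifier-recovery conditions use 500 planted variants per class
(STR, TR, SINE-complete, SINE-fragment, LINE-complete,
retroposon-complete, non-repetitive) on four 1.2 Mb chromosomes; FST
recovery uses 2 × 30 diploids at 10,000 Balding–Nichols loci; STR
genotyping recovery uses 200 sites; ANOVA calibration uses 5,000 null
simulations of 4 × 10 observations. These sizes give comfortable
statistical resolution for the asserted tolerances while keeping a full
run in the minutes range on one CPU. All randomness flows from explicit
seeds; pipeline outputs embed the config hash and seed, contain no
timestamps, and are byte-identical across re-runs.

## Known limitations

The built-in detectors are not indel-tolerant and do not decompose nested
repeats; the element matcher requires exact 15-mer seeds, so diverged
element copies (> ~7 % substitution) can be missed — use the adapters for
real data. The insertion reciprocal-overlap definition (size ratio gated
at 200 bp) is a convention, not a standard; comparisons against annotation
sets built with a different convention will shift the moderate/low
boundary. WC84 on presence-derived dosages inherits whatever biases the
upstream genotyper has. The CNV module classifies merged regions but does
not model copy-number dosage beyond deletion/duplication labels.
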