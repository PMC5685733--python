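# Methods

`sermir` reimplements, as a tested and fully seedable pipeline, the
analysis of circulating small RNAs in serum of a rectal-cancer cohort:
raw 50-bp small-RNA reads are trimmed, collapsed and aligned;
sequences are annotated hierarchically (mature miRNA loci first, an
ncRNA database second); miRNA-assigned sequences are classified into
the isomiR taxonomy; spike-in calibrators drive between-sample
normalization; and the normalized matrices feed moderated differential
expression, Cox survival screening and reference-gene selection for
qPCR validation. Because the raw data of such studies is rarely
re-distributable, a synthetic-data module generates reads and cohort
metadata with the statistical structure the analysis assumes, so every
stage can be validated against known ground truth.

## Read model and processing

Reads are 50-bp single-end: an RNA insert followed by a ligated 3'
adapter (Illumina small-RNA style, default
`AGATCGGAAGAGCACACGTCT`), then fixed post-adapter bases.

**Trimming.** The earliest read position whose suffix matches an
adapter prefix (overlap >= 3 nt, mismatch rate <= 0.1) is the cut
point; this is the longest-suffix rule used by standard adapter
trimmers. Inserts shorter than 10 nt are dropped (`too_short`);
untrimmed reads are retained so that long inserts whose adapter is
fully read-through are not biased against. The 10-nt floor keeps the
~13-nt degradation-fragment peak.

**Collapsing.** Trimmed reads are collapsed to unique sequences with
per-sample counts; all downstream work is per unique sequence.

**Calibrator matching.** Unique sequences identical to a spike-in are
counted for it; sequences within edit distance 2 (edlib) are counted
as variants of the closest calibrator — ties go to the lowest
calibrator index, deterministically — and withheld from genomic
annotation. This mirrors the observation that spike-ins appear with
synthesis/degradation variants.

**Alignment.** The aligner is an exact-substring search over the toy
genome (both strands) with a bounded 3' soft-clip: a sequence is
placed where it matches perfectly, or perfectly except for at most 3
trailing bases (the clipped tail is the non-templated-addition
candidate). Clipping is greedy template-first — the smallest clip with
a perfect hit wins — so a tail base that matches the genomic template
is always treated as templated. Internal mismatches are never
tolerated; at most 10 placements are reported (leftmost first,
flagged saturated beyond that). A scoring aligner would add nothing
because downstream rules only consume perfect cores and short 3'
tails; full-genome-scale indexing is explicitly out of scope.
Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted on read.

## Annotation cascade and counting

Sequences are assigned to every mature-miRNA locus that any alignment
overlaps by >= 1 base on the same strand (htseq-style interval
overlap, not sequence identity to the mature FASTA — the mature
sequence only defines canonical ends for isomiR offsets). Sequences
untouched by the miRNA stage are matched against the ncRNA database by
exact sense-strand substring containment; one entry can host many
fragment variants. Multi-assigned counts are duplicated per feature
rather than split, so a read over two paralogous loci contributes to
both. For the class-composition summary, multi-class sequences are
resolved by a declared priority
(miRNA > scRNA > tRNA > snoRNA > snRNA > rRNA > Y-RNA > lncRNA).

Library size for cpm is the total count of aligned biological
sequences; calibrators are spike-ins, not library content, and are
excluded so cpm stays comparable when the spike ratio varies.

## IsomiR classification

A miRNA-assigned sequence is described relative to the canonical
mature ends of its locus: a signed 5' offset (positive = trimmed,
negative = templated extension), 3' trimming or templated tailing, and
the clipped tail as non-templated addition (NTA). Offsets beyond +/-5
nt (5') or 5 nt (3' trim/tail) reject the sequence as an unrelated
hairpin fragment rather than an isomiR — a window in line with
SeqBuster-like tools. NTA is capped at 3 nt by the aligner's clip
bound. Reads with internal mismatches never align and therefore never
produce a record, implementing the rule that mismatched variants are
discarded as possible sequencing errors while 3'-NTA variants are
kept. Multi-locus sequences are classified independently at each
locus. Labels use lower case for trimmed bases and upper case for
tailed bases, rendered in the RNA alphabet (`3p:gu`, `3p:GU`,
`nta:AU`, `5p:a`); mature totals include NTA isomiRs.

Type composition is computed over unique isomiRs — distinct
(mature, label) pairs, canonical excluded — with a multi-modification
record counted once per type it carries.

## Calibrator TMM normalization

Between-sample factors are the weighted trimmed mean of M-values
(Robinson & Oshlack 2010) computed on the full calibrator count
matrix: reference column by the 75th-percentile rule, M-values trimmed
30% and A-values 5% (the published defaults; only the function, not
its parameters, is prescribed by the study design), precision-weighted
mean, factors rescaled to geometric mean 1. Cells with a zero count in
either sample are excluded from the M/A computation. The implementation
reproduces edgeR's `calcNormFactors(method="TMM")` to ~1e-10 on random
matrices (cross-checked in the test suite) and is additionally verified
against an independent brute-force implementation of the formula.
Factors estimated on the calibrators are applied to the biological
matrices through the effective library size:
`cpm = count / (library_size * factor) * 1e6`.

Calibrator QC reports the cross-sample CV per calibrator (flag
threshold 0.2) and flags samples whose calibrator cpm total deviates
from the cohort median by more than 1.5 in log2.

## Differential expression

Two contrasts are built from the patient table: **metastasis** —
patients sampled before any treatment, M1 vs M0 (53 patients at the
default cohort: 43 + 10); **treatment** — serum after preoperative
chemoradiotherapy (CRT-only; surgery-containing regimens excluded) vs
serum before treatment, with M1-at-diagnosis patients removed
(27 vs 43). Expression filters follow the stated wording literally:
"at least" is inclusive (cpm >= threshold), "more than" is strict
(fraction > 0.5, cpm > 100); the ncRNA contrast requires expression in
every included sample.

Counts are voom-transformed (Law et al. 2014): log2-cpm with a 0.5
count and +1 library offset; lowess (span 0.5) of
sqrt(residual sd) on mean log2 count; per-observation weights are the
interpolated sd at the fitted log-count to the power -4. Per-feature
weighted least squares is followed by empirical-Bayes variance
moderation (Smyth 2004): the prior is fitted by moment matching on
log s^2 (trigamma inversion by Newton iteration), posterior variances
are the df-weighted blend, and moderated t uses the augmented degrees
of freedom. Setting the prior df to 0 recovers the ordinary weighted
t-test exactly (tested). BH adjustment uses the standard step-up
procedure. The design is intercept + group; age/sex covariates can be
supplied but are off by default, and the significance cut-off for
counting discoveries is BH-adjusted p < 0.05.

## Survival screening

Features passing the conservative filter (cpm > 100 in > 50% of
samples) are each fit in a Cox proportional-hazards model — expression
(median-dichotomized by default, ties at the median to "low", the
cutpoint recorded; a continuous log2-cpm mode is available) plus age,
sex and metastasis status. Fitting uses lifelines' `CoxPHFitter`
(Efron tie handling, Newton precision tightened to 1e-9, verified
against brute-force partial-likelihood maximization to 1e-6 on toy
data). Monotone-likelihood fits are flagged (runaway coefficient);
per-feature failures are recorded and the screen continues. Wald
p-values of the expression term are Bonferroni-corrected over the
features tested — this expression-term p in the metastasis-adjusted
model is the package's reading of a "significance across the four
groups" display, and the choice is recorded here because the display
convention is ambiguous. Significant features get four-group
(expression x metastasis) Kaplan-Meier curves; KM curves use the
product-limit estimator with a log-rank test across groups. The
baseline-hazard route to a survival curve (Breslow) is deliberately
not used as a KM substitute, since the two estimators differ at event
times; KM is tested against a hand-rolled product-limit oracle
instead.

## NormFinder and qPCR

NormFinder (Andersen et al. 2004) operates on log2 expression after
removing per-sample effects (column centering across genes; results
are invariant to adding a constant to any sample). Within each of the
two groups, gene-level means and variances are estimated with the
centering-induced coupling inverted (variance floor 1e-12; with only
two genes the raw variance is used). The between-gene spread of group
differences (tau^2) shrinks each gene's difference toward zero, and
the stability value is |shrunken difference| + its posterior standard
error — small only for genes that are both unshifted and quiet.
Reference candidates must additionally be highly expressed
(mean cpm >= 100 by default) and clearly non-DE (BH-adjusted p > 0.5);
the top 3 by stability are returned.

The qPCR chain: dCt = Ct(target) − geometric mean of the control-miRNA
Cts per (sample, replicate) — the geometric mean of the Ct numbers, a
literal reading, with an arithmetic-mean option; the two differ
negligibly for Cts in a narrow range. RQ = 2^(−dCt), averaged over
cDNA-synthesis duplicates; fold change is the ratio of group mean RQs;
the unpaired equal-variance t-test runs on dCt (log scale), not RQ,
which is log-normal.

## The synthetic-data generator

**Reference.** A random genome with 20 mature loci (21–23 nt; two
matures planted at two loci each to exercise multi-mapping; ~30% on
the minus strand), 35 ncRNA entries (5 per class across scRNA, lncRNA,
rRNA, tRNA, snoRNA, snRNA, Y-RNA; 34–90 nt, planted in the genome so
their fragments align), and ten distinct 22-nt calibrators absent from
the genome. The base immediately downstream of every mature 3' end is
forced to C so that A/U non-templated tails are unambiguous by
construction. The study does not publish calibrator sequences or
concentrations, so they default to arbitrary distinct equimolar
22-mers.

**Cohort.** Marginals default to the 96-patient table (stage
0/I/II/III/IV = 1/13/38/23/21; 53 before / 43 after treatment; 53
male / 43 female; M1 = stage IV = 21, split 10 before / 7 after-CRT /
4 after-other so the two contrasts have their published sizes 53 and
43 vs 27). T/N/sex/age match marginal counts only — no joint
TNM-stage consistency is modelled. Survival is exponential per stage
with hazards derived from 5-year survival defaults (0.95 / 0.90 /
0.75 / 0.60 / 0.12 for stages 0–IV, in line with published
rectal-cancer rates), administrative censoring uniform on 60–108
months; 22% of M0 patients are marked as developing later metastasis.

**Reads.** Class mixture defaults to miRNA 0.35, scRNA 0.28, lncRNA
0.15, tRNA 0.06, rRNA 0.05, Y-RNA 0.05, snoRNA 0.04, snRNA 0.02.
ncRNA reads are full-length prefixes (29–33 nt) or degradation
fragments (10–16 nt, 45%), producing the 13/22/31-nt length modes.
Calibrators are spiked at a constant 5% of the library, equimolar,
with a 2% single-terminal-deletion variant rate. Planted expression
effects multiply a mature's abundance weight by 2^lfc in the affected
group (default: four miRNAs up and two down in M1; one miRNA up after
treatment, mirroring the single treatment-associated miRNA such a
study finds); because class fractions renormalize, other features
shift infinitesimally — negligible at the planted effect counts.

**IsomiR planting.** Each mature carries a fixed variant catalogue:
the canonical sequence plus single-modification variants whose
type counts are allocated deterministically in the ratios 32% 3'-trim
/ 39% NTA / 15% templated tail / 14% 5'-mod (15 variants per locus by
default, cycled over loci so each mature has every type). Deterministic
allocation — rather than a per-variant multinomial draw — makes the
unique-isomiR composition a planted constant, so composition recovery
tests measure the pipeline, not sampling noise. Reads then draw a
modification type per read from the profile mixture (canonical 30%)
and a variant uniformly within the (locus, type) pool; read-level
type fractions therefore match the mixture while unique-level
fractions match the planted allocation. NTA tails come from {A, U},
length 1–3, first base unequal to the genomic template base.
Multi-modification isomiRs (e.g. trimmed *and* tailed) are not
planted, though the classifier handles them; the generator's truth
labels are single-type by design.

All randomness flows from one master seed through per-sample derived
seeds (`numpy` SeedSequence); identical (config, seed) reproduce
byte-identical FASTQ and metadata.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sequencing errors beyond terminal
calibrator deletions, quality-score structure, ligation and GC bias,
true hairpin processing (variants are planted, not cut from
precursors), cross-mapping in a repetitive genome, batch effects, and
joint TNM-stage dependence. Results on real libraries depend on all of
these.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single CPU: the deep isomiR library uses one sample of 150,000 reads
(~5x10^4 miRNA reads, ~300 planted unique isomiRs); the calibrator
gradient uses 8 samples from 30,000 to 120,000 reads with a 20% spike
fraction, deep enough that counting noise cannot mask a normalization
error; DE operating characteristics use 10 seeds of 1,000 features
with 30 planted |lfc| = 1 effects at group sizes 43 vs 21 and
gamma-Poisson dispersion 0.2 (BCV ~0.45, a realistic serum value);
Cox recovery uses n = 300 with 20% censoring over 10 seeds; the
demonstration pipeline runs a proportionally scaled 24-patient cohort
at 4,000 reads per sample. Numerical details worth knowing: lowess
extrapolation is clamped to the trend's end values with a 1e-6 floor
on the predicted sqrt-sd; trigamma inversion iterates Newton to
1e-10 relative tolerance; TMM returns unit factors when all M-values
are below 1e-6 in magnitude; the dichotomizer refuses constant
vectors; and empty samples (zero aligned reads) abort matrix assembly
with the offending sample named.

## Known limitations

* The aligner and annotation are built for toy genomes (tens of kb);
  real hg38-scale work should delegate alignment to a dedicated
  aligner and feed its perfect-match placements into the same
  downstream rules.
* NormFinder's original R build is not bit-reproducible from its
  publication alone; this implementation follows the published model
  with pooled unbiased variance estimates and documents its shrinkage
  exactly (above), but printed stability values from other builds may
  differ in the second decimal.
* The mature count of a paralog family double-counts multi-locus
  reads by design (documented convention); comparisons across tools
  that fractionally split multi-mappers will differ.
* qPCR modelling covers dCt statistics only; amplification-efficiency
  correction and standard curves are out of scope.
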