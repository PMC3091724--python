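# Methods

## Problem and model

In a tumor/adjacent-normal/blood trio assayed on a genotyping array, two
complementary somatic signals are available per SNP: a change of zygosity
relative to blood (loss of heterozygosity, LOH) and a change of DNA dosage
(copy-number state, CN). Crossing them yields six states — LOH or retention,
each with CN loss, neutral, or gain. The diploid LOH class, CNNLOH, is the
signature of mitotic recombination or of nondisjunction followed by
reduplication: one parental allele is gone but total copy number stays 2, so
dosage-only methods miss it. The analysis classifies every informative SNP,
builds segments, tabulates the cohort, and asks whether gene expression fold
changes differ between cases with and without LOH over a gene, within each
CN class.

Assumptions: tumors are treated as pure (the emulated study micro-dissected
tumor cells), genotypes are unphased and strandless, and sex chromosomes are
excluded throughout to avoid hemizygosity artifacts.

## LOH calling

LOH is observable only where blood is heterozygous. The caller applies the
paired-zygosity rule directly: blood AB + tumor homozygous → LOH; blood AB +
tumor AB → retention; anything else → undefined. Discordant homozygotes
(blood AA, tumor BB) indicate genotyping error, not biology; they are left
undefined and tallied in a QC record. No smoothing or HMM is applied at this
stage — isolated retention calls inside LOH runs are propagated as called,
and any cleanup happens at segmentation, keeping each stage auditable.

## CN calling

Per-SNP log2 ratios are smoothed by a centered boxcar mean over all SNPs
within ±50 kb on the same chromosome (window in base pairs, default
100 kb — chosen to resolve extended CN alterations at ~5.8 kb SNP spacing),
then classified to the nearest of five state centers log2(c/2):
−3.0, −1.0, 0.0, +0.585, +1.0 for states 0–4. State 0's center is a −3
floor rather than log2(0): arrays report roughly 10–15% residual signal over
homozygous deletions. Exact ties between two centers resolve toward the less
extreme state (state 2 if it is in the tie; between states 3 and 4, state 3),
so borderline evidence never inflates a call. The smoother and classifier
are deliberately minimal — a boxcar mean plus nearest-center rule — and the
window and centers are exposed as configuration.

## Six-state segments

A SNP has a defined six-state only when informative with a determinate LOH
call; everything else is undefined. Segments are maximal runs of equal-state
defined SNPs taken consecutively *among defined SNPs* per chromosome, with
endpoints at the run's first and last informative SNP. Interstitial
undefined SNPs therefore do not sever a run: they sit between segments with
undefined state. The stricter reading (undefined severs adjacency) is
available as `break_on_undefined`; the default was chosen because
uninformative SNPs carry no evidence for or against a state change, and a
27%-heterozygosity array would otherwise shatter every event into fragments.
The minimum segment size defaults to 1 informative SNP (`min_snps` filters
if desired). Count tables are computed from per-SNP states, not segment
spans, so a segment's weight is its informative-SNP count.

## Summary tables

Per-case rows count LOH-positive defined SNPs by CN group; per-arm rows pool
all cases. Display fractions are rounded half-up to two decimals. Footers
report: units whose rounded fraction is 0.00 (true zeros included); range
and median over unrounded fractions with zero-total units contributing 0;
and the pooled global average (sum of counts over sum of totals — not the
mean of per-unit fractions, which would overweight near-empty units). The
percent-of-cases-with-LOH statistic supports both an exact-zero and a
rounded-zero rule, because published tables use each in different places.

The package ships the reference ESCC cohort's published per-case (30 rows)
and per-arm (39 rows) count tables. Recomputing from these counts reproduces
the published pooled averages (0.19 / 0.70 / 0.11), the 15 / 3 / 2
zero-fraction footer, and 90% / 93% of cases with CNNLOH / gain-LOH. Two
printed cells do not recompute from their own counts and are asserted at the
recomputed value instead: the 8q gain fraction prints 0.74 but is
12,641/17,321 = 0.73, and the per-case CN=2 median prints 0.60 but
recomputes to ≈0.62 under every zero-handling rule tried (it is excluded
from assertions). The 4q row's printed counts (9,142 + 17,905 + 1,958) also
exceed its printed total of 28,105 by exactly 900; the printed 0.04 gain
fraction implies a gain count of 1,058, suggesting a digit typo. The counts
are shipped verbatim and totals are always recomputed as row sums.

## Expression integration

Log2 fold change is tumor minus matched-normal log2 expression (inputs are
already RMA-style normalized; normalization is not re-implemented). A probe
set in a case takes the state of the unique segment that fully contains its
reference region; partial overlap or a gap yields undefined for that case —
full containment is the conservative mapping when a gene straddles a
boundary. Eligibility requires ≥2 LOH-positive and ≥2 LOH-negative cases in
the CN class under test. The t-test is Student's pooled-variance (exposed
flag for Welch); zero-variance groups are flagged untestable and excluded
from significance counts rather than reported at p = 0. Significance is raw
p < 0.01 with no multiplicity correction, and the expected chance count is
⌊n × α⌋ (4,572 × 0.01 → 45). The ≥2-fold flag applies to the LOH group's own
tumor/normal fold change (≥2 or ≤0.5), inferred from the structure of the
published gene lists, where every listed LOH-group fold change satisfies it
while between-group ratios do not. Probe sets sharing a gene symbol are
tested independently, and SNP counts per probe set are computed from the
probe set's own reference region.

## Synthetic cohort generator

Defaults encode the emulated study conditions: 30 cases, 17 expression
pairs, 27% heterozygosity, 96% call rate, 5.8 kb mean SNP spacing, and
per-SNP log2-ratio noise sd 0.15 (the instrument's noise model is not
published; 0.15 is a typical mid-2000s array value and is exposed as a
parameter, not claimed to match the platform). The genome is 22 autosomes at
1/25 of human chromosome lengths (~115 Mb, ~19,900 SNPs), which keeps a
full-cohort run at seconds while preserving all densities and rates; the
p/q boundary sits at 40% of each chromosome. Events (0.8–2.5 Mb, 3–6 per
case, one case in ten quiet) cycle through the five somatic states; loss
plants c=1 and gain c=3 by default (c=0/c=4 configurable). Within an LOH
event the retained allele is drawn once per event — per-SNP redraws would
create impossible haplotype mosaics. NoCall overlays are independent across
tissues. A blood-vs-reference ratio track (diploid) is generated alongside
the tumor and adjacent-normal tracks so the blood/adjacent-normal control
comparison can be run on called CN states.

Expression: per-gene baselines ~ N(7, 1.2); normal and tumor each add
N(0, 0.3) noise; 30% of genes are designated affected and receive a ±2
log2 shift in tumor, in cases where the gene lies wholly inside an LOH
event. All randomness flows from one root seed through per-stage spawned
streams, so identical configurations are byte-identical.

What the simulation does **not** model: tumor impurity and subclonality,
GC waves and batch effects, genotyping error (beyond no-calls), linkage
disequilibrium, non-uniform SNP density, allele-specific expression.
Passing recovery tests therefore demonstrates correctness of the pipeline's
logic under clean clonal events, not performance on contaminated or noisy
clinical samples.

## Calibration experiments and problem sizes

The type-I experiment simulates 4,572 independent probe sets (the study
scale) with no effect, group sizes 2–8 of 17, and checks the significant
count against the central 99% binomial interval around 45.7. The power
experiment plants |log2 shift| = 2 at noise sd 0.3 with 3 vs 5 cases and
requires ≥90% recovery with correct direction. Six-state recovery and
boundary placement are scored on the default 30-case cohort over planted
events spanning ≥20 informative SNPs (smaller events are below the designed
resolution of a 100-kb window): ≥95% of informative SNPs must receive their
true state, and ≥90% of events must have both boundaries within 2
informative SNPs of truth. Measured values are comfortably inside all these
bounds (recovery ≈ 99.8%, boundaries 100% within 2, concordance ≈ 100%).

## Known limitations

- The CN caller is a minimal stand-in for production array segmentation
  (no HMM, no GC correction, no allele-specific CN); its state thresholds
  are nearest-center defaults exposed as configuration.
- Real cohorts have far higher CN/LOH heterogeneity than the planted-event
  model; absolute table values from simulation are not comparable to
  clinical cohorts — only the reference-count recomputations are.
- With 17 expression pairs, eligibility (≥2 vs ≥2) leaves many probe sets
  untested; this mirrors the design's own power limits.
- The undefined-SNP adjacency rule at segmentation is a documented choice;
  the alternative is one flag away and changes segment counts but not
  per-SNP state calls.
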