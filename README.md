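# cnnloh

Genome-wide integration of loss of heterozygosity (LOH) and copy-number (CN)
state in paired tumor / adjacent-normal / blood ("trio") SNP-array data, with
particular focus on **copy-number-neutral LOH (CNNLOH)** — loci that lose one
parental allele yet keep two DNA copies, typically through mitotic
recombination or nondisjunction with reduplication — and on how CNNLOH shifts
gene expression. The design emulates a 500K SNP-array + expression-array
study of esophageal squamous cell carcinoma: 30 trio cases, 17 of them with
paired tumor/normal expression profiles.

The pipeline is for cancer-genomics analysts who have paired genotype calls
and intensity log ratios and want segment-level LOH×CN annotation plus
LOH-conditioned differential expression, and for methodologists who want a
fully simulatable testbed for that analysis.

## Method

1. **LOH calling** — at each SNP heterozygous in blood (an *informative*
   SNP), a homozygous tumor call is LOH, a heterozygous call is retention; at
   all other SNPs the status is undefined.
2. **CN calling** — per-SNP log2 intensity ratios (tumor vs germline) are
   smoothed with a centered 100-kb boxcar and classified to the nearest of
   five state centers, log2(c/2) for c ≈ 0.25, 1, 2, 3, 4; state 2 is
   diploid, ≤1 loss, ≥3 gain.
3. **Six-state classification** — LOH status × CN group gives six states;
   LOH-positive diploid SNPs are CNNLOH. Maximal runs of equal-state
   informative SNPs form segments whose endpoints are informative SNPs;
   interstitial undefined SNPs do not break a run.
4. **Cohort tables** — per-case and per-arm counts of LOH SNPs by CN group,
   with fractions, ranges, medians and pooled global averages, and
   blood-vs-adjacent-normal CN concordance.
5. **Expression integration** — per-case log2 fold change (tumor − normal);
   each probe set takes the state of the unique segment fully containing its
   region; probe sets with ≥2 LOH+ and ≥2 LOH− cases in a CN class get a
   two-sided pooled-variance t-test on log2 fold changes (p < 0.01
   significant, no multiplicity correction), with group fold changes reported
   as 2^(mean log2fc) and an at-least-2-fold flag on the LOH group.

A synthetic cohort generator (`cnnloh.sim`) plants events of every somatic
state with recorded ground truth, so recovery, calibration and power are all
measurable.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_call_tracks.py
python analysis/03_segment.py
python analysis/04_summarize.py
python analysis/05_expression.py
python analysis/06_figure.py
```

prints, among other lines:

```
simulated 19868 SNPs x 30 cases; 122 planted events (74 with LOH); wrote results/cohort
919 segments over 148243 defined SNPs
blood vs adjacent-normal CN concordance: 100.00% identical; 100.00% / 100.00% diploid
reference cohort recomputation: global averages (0.19, 0.7, 0.11) | % cases with CNNLOH: 90 | % with gain-LOH: 93 | cases rounding to zero loss fraction: 15
CN neutral: 18 eligible probe sets, 7 significant at p<0.01 (7 also 2-fold; ~0 expected by chance)
null calibration: 48 of 4572 significant (expected 45 by chance)
power at planted |log2 shift| = 2, noise sd 0.3, 3 vs 5 cases: 97.7% (100.0% correct direction)
```

Reading: the simulated 30-case cohort yields 919 LOH/CN segments; the two
candidate germline controls (blood, adjacent normal) give identical CN calls,
so blood is a sound reference. The packaged reference cohort's printed
per-case counts recompute to pooled LOH fractions of 0.19 / 0.70 / 0.11 for
CN loss / neutral / gain — CNNLOH dominates — with 90% of cases showing
CNNLOH. In the expression stage the planted LOH-dependent shifts are
recovered (7 significant probe sets against ~0 expected by chance), the test
is calibrated under the null (48 significant of 4,572 at p < 0.01, ~45.7
expected), and power at the planted effect size exceeds 90%.

The same stages are available as a CLI (`cnnloh simulate | call-loh |
call-cn | segment | summarize | integrate-expression | plot | run-all`).

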