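# Methods

`epidiverge` implements a population-epigenomics workflow for bisulfite-count
data: calling differentially methylated regions (DMRs) between populations,
locating them in genomic features and testing their enrichment, linking them
to differential gene expression, and classifying their transgenerational
inheritance in a common-garden generation. A planted-truth simulator
generates every input the workflow consumes, so each stage can be validated
against known ground truth.

## The statistical model behind DMR calling

Input is per-CpG counts of methylated and unmethylated reads per sample
(Bismark coverage format). Sites are used only with per-sample coverage in
[4, 100], and a site enters a two-group comparison only when it passes that
filter in *every* sample of both groups (the strictest reading; it keeps the
test's inputs complete).

**Smoothing.** For each group, the methylation level at site *k* is the
weighted mean of raw group levels over all sites within ±250 bp (boxcar,
500 bp span). The weights are the *total coverage over both groups* at each
site, so both groups average the same sites with the same weights. This
matters: site-level baselines vary (CpG islands vs gene bodies, plus
biological site-to-site scatter), and if each group weighted sites by its own
realised coverage, that variation would leak into the smoothed group
difference and inflate the false-positive rate (we measured ≈0.062 instead
of the nominal 0.05). With shared weights the heterogeneity cancels exactly
from the difference.

**Wald test.** The statistic is the smoothed difference divided by its
standard error. Each site's raw group level `p̂ = Σm/Σn` has beta-binomial
variance

    Var(p̂) = p(1−p) · Σⱼ nⱼ(1 + (nⱼ−1)φ) / (Σⱼ nⱼ)²

with per-sample coverages `nⱼ` and intra-class dispersion φ. φ is estimated
per group by the method of moments — comparing the between-sample variance
of raw proportions with its binomial expectation — but the per-site estimate
has 1–2 degrees of freedom at this study's sample sizes and is useless
alone; we pool it per chromosome (mean of clipped per-site estimates) and
floor it at 10⁻³. The smoother's variance is then the weight-squared
combination of the per-site variances, and p-values are two-sided normal.
Measured site-level type-I error on null simulations is 0.044–0.051 at a
nominal 0.05.

**Regions.** A site is *significant* when p < 0.05 **and** its absolute
smoothed difference is at least `min_abs_diff` (default 0.15). The second
condition is a delta floor in the spirit of DSS's `delta` argument: without
it, boxcar smoothing makes sites up to ~200 bp outside a true DMR
significant, and short DMRs cannot be recovered at 50% reciprocal overlap.
Candidate regions are maximal runs bounded by significant sites in which
consecutive sites are ≤100 bp apart and the significant fraction stays
≥0.5; overlapping maximal runs coalesce. Emitted DMRs must finally show
≥25% mean per-site raw group difference, ≥4 CpGs and ≥50 bp — regions, not
sites, are the inference unit, so no per-site multiple-testing correction is
applied. Direction is "gain" when the focal (first) group is the more
methylated.

## Annotation and enrichment

Promoters are TSS ± 1 kbp (strand-aware); gene bodies are the gene minus the
first 1 kbp downstream of the TSS; intergenic is the rest. The three classes
are made mutually exclusive and exhaustive with precedence promoter >
gene body > intergenic (audited per-bp in tests). A boundary-straddling DMR
is assigned its majority-base-pair class, ties to promoter. DMRs map to a
gene when ≥50% of the DMR overlaps that gene's promoter or body (several
genes may qualify); otherwise an unassigned DMR maps to its nearest gene as
"intergenic" when the gap is 1–5 kbp. Distances are pure gaps: touching or
overlapping intervals are at distance 0 (this differs from BEDTools'
off-by-one closest-distance convention).

Feature enrichment shuffles the DMR coordinates genome-wide (length
preserved, chromosome chosen proportional to length, start uniform; 1,000
iterations by default, 500 available by config), counts ≥1 bp overlaps per
iteration, and reports observed/expected with a one-sample t-test of the
shuffle counts against the observed value; contingency across comparisons
uses a chi-squared test. Gene-set overlap (DEGs × promoter-DMR genes) uses
the exact hypergeometric distribution with a representation factor; the
two-sided p sums all outcome probabilities no larger than the observed
outcome's (a twice-the-smaller-tail variant is available).

## Expression integration

Differential expression is a Wald test on the difference of group means of
log2(TPM+1) with a pooled-variance SE and Benjamini–Hochberg adjustment
across genes. A DEG must satisfy q < 0.05, |log2FC| ≥ 1.5 and maximal
expression ≥10 TPM in at least one sample. This replaces a
bootstrap-variance Wald test on pseudoalignment abundances, which needs
read-level data; at the matrix level the inference surface is the same.
Genes split into OFF (mean TPM < 5) plus four equal-count ON bins;
metaprofiles average methylation from TSS−2 kbp to TES+2 kbp with
fixed-width flank bins and length-normalised body bins, strand-flipped.
Promoter methylation vs expression uses Spearman rank correlation.

## Inheritance classification

Wild DMRs from all pairwise comparisons are merged (bookended or overlapping
intervals coalesce, provenance retained). For each merged DMR and each
contributing comparison, common-garden counts are aggregated over the DMR's
CpGs per sample and re-tested with the region-level beta-binomial Wald test
(aggregation keeps power at n=2 per common-garden group). A DMR is **fixed**
when the test is significant (p < 0.05), in the wild direction, and every
sample's region mean lies on its group's side of the other group's mean;
otherwise **reset**. DMRs with no covered common-garden CpG in one group are
*untestable* and excluded from proportions. A merged DMR spanning several
comparisons is fixed if any contributing comparison re-tests fixed. Only
wild-defined coordinates are ever tested in the common-garden generation, so
within-generation variation arising there cannot create new calls. Length
comparisons between fixed and reset sets use percentile bootstrap CIs
(5,000 resamples by default) for the difference of means.

## Cohort statistics

PCA operates on the centred, unit-scaled sample × site level matrix
(complete sites only; zero-variance sites dropped; component signs fixed by
the largest-absolute-loading-positive convention). MANOVA on retained PC
scores uses Pillai's trace with the standard F approximation (df₁ = s(2m+s+1)
— 4 for three groups on two components). Welch's heteroscedastic ANOVA with
Satterthwaite df is followed by Games–Howell all-pairs tests via the
studentized-range distribution; both are implemented directly and
cross-checked against independent implementations in the test suite.
Correlation clustering builds the pairwise Spearman matrix between samples,
takes Euclidean distances between its rows, and applies complete linkage;
the sample × DMR mean-methylation matrix supports cross-platform
(RRBS-style subsampled vs WGBS-style) validation with pairwise-complete
handling of uncovered DMRs.

## The synthetic data generator

The generator emulates the study design end to end, with one global seed
feeding independent substreams per stage (genome, wild cohort, expression,
common garden, inheritance labels), so every stage is independently
reproducible.

- **Genome** (defaults: 4 × 2.5 Mb): non-overlapping strand-assigned gene
  models placed with ≥4 kbp gaps; CpG sites from a homogeneous Poisson
  process (10/kbp) with 5× density inside CpG islands; CGIs at half of
  promoters (centred on the TSS) plus orphan islands; transposon repeat and
  high-divergence (HDR) intervals. That yields ≈10⁵ CpGs.
- **Methylation**: each site draws a baseline level from a beta distribution
  (concentration 30) around its compartment mean — promoter-CGI 0.10,
  orphan-CGI 0.15, promoter 0.55, gene body 0.85, repeat 0.85, intergenic
  0.75 — reproducing a globally methylated fish-like methylome with
  hypomethylated islands. Per sample, coverage is negative-binomial (mean
  30, size 8; the deposited study's ~9× regime is one setting) and
  methylated counts binomial. Proportions are clipped to [0.01, 0.99] so
  binomial draws stay non-degenerate and Wald SEs finite.
- **Planted DMRs** (150 by default, effect 0.45) are anchored at CpG
  islands: real population-scale methylome divergence concentrates at
  CpG-dense regulatory elements (the study's DMRs have ~15 CpGs in ~250 bp
  against a ~10/kbp genome background), and the anchoring reproduces that
  local density. Because island baselines are low, planted shifts are
  methylation gains — the dominant mode in the system emulated. The focal
  population's proportion is shifted by +0.45 inside the interval.
- **Expression**: log-normal TPM; gene-level mean log2 TPM decreases with
  mean promoter methylation (slope 8 log2-units per unit mCG/CG, chosen so
  the cohort-wide Spearman correlation lands at the reported magnitude,
  ρ ≈ −0.25…−0.31); 60 planted DEGs with |log2FC| = 2, of which 43% are
  genes hosting a planted promoter DMR with the expression shift opposing
  the methylation shift.
- **Common garden**: two samples per population; planted DMRs are labelled
  fixed with probability 0.112, keep their shift if fixed, revert every
  population to baseline if reset.

What the generator does **not** emulate: read-level artefacts (mapping,
conversion failure, PCR duplicates), non-CpG methylation, hemimethylation,
SNP–methylation interactions, loss-direction DMRs, linked genetic structure,
and realistic gene-length/expression distributions. Passing tests therefore
demonstrate correctness of the inference machinery under the generating
model, not robustness to those real-data features.

## Problem sizes and numerical choices

Tests and the acceptance script run at the defaults above (10⁵ CpGs, 3 vs 3
wild samples, 2 common-garden samples, 5 RNA samples per population), with
500 planted DMRs for inheritance-recovery checks and 1,000-iteration
shuffles; bootstrap coverage checks use 200 replicates of n=100 with 1,000
resamples. Medians use the midpoint-of-two rule. Degenerate inputs are
explicit errors (zero spike-in coverage, constant correlation vectors,
empty bootstrap sets, <2 samples per DEG group) rather than NaNs.

## Known limitations

- With 2 samples per common-garden group the fixed/reset re-test leans on
  the pooled dispersion; per-call power is limited and ~2–3% of truly reset
  DMRs are miscalled fixed at α = 0.05.
- The boxcar smoother still extends called DMR boundaries by up to ~80 bp
  per side past planted edges; recovery is assessed at 50% reciprocal
  overlap.
- The shuffle null does not exclude assembly gaps unless an exclusion BED is
  supplied.
- At desk scale the DEG × promoter-DMR representation factor is compressed
  (the promoter-DMR gene set is a large fraction of the small universe); the
  planted overlap *fraction* of DEGs is the comparable quantity.
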