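# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions at edge cases.

## Exon profiles and the AD:RD index

Per-exon expression is summarized as within-gene TPM: for exon *e* with
length *L(e)* and count *k(e)*, the read rate is *k(e)/L(e)* and TPM rescales
the rates so they sum to 10⁶ over the gene's exons. The denominator is
deliberately the gene's own exons rather than the whole library: only one
gene's profile is analyzed at a time, and any transcriptome-wide constant
cancels both in anchor normalization and in the exon-ratio index. The
consequence is that these TPMs are comparable across exons and across samples
of the same gene, not across genes.

Anchor normalization divides a sample's profile by its TPM at a chosen
anchor exon. Exon 2 (the first translated exon) and exon 7 (a mid-RD exon)
are both sensible anchors depending on whether the 5′ end or the canonical
transcript is the reference; the anchor is a parameter (CLI default 7).
Samples with zero anchor signal are excluded with a recorded reason — they
are not errors, just unusable for ratio analyses. A pseudocount is never
applied inside ratios (it would bias the index); the +1 convention is
reserved for log-scale displays.

The DNF index is the ratio of anchor-domain to replication-domain exon TPM,
`tpm(exon 14)/tpm(exon 5)`. Group boundaries are: A (2, ∞); B (1.1, 2];
C [0.9, 1.1]; D (0, 0.9). The published ranges leave the exact boundary
points ambiguous ("exceeds 2" vs "1.1–1.99"); this package resolves ties
conservatively: a ratio of exactly 2 is B, and ties at 0.9/1.1 fall into the
balanced group C. The classification partitions (0, ∞) — every positive
finite ratio receives exactly one label (property-tested).

Between-exon comparisons use the two-sided Mann–Whitney U test, unpaired by
convention even though both exons come from the same samples (the pairing
structure is deliberately ignored to match common practice for this
comparison; a paired test would be more powerful). Exact enumeration is used
when both sides have n ≤ 8 without ties, otherwise the normal approximation
with tie and continuity correction.

Internal-TSS detection is single-changepoint binary segmentation: the
breakpoint maximizes the size-weighted between-segment squared mean
difference `n₁n₂/n (m₁−m₂)²` subject to a minimum segment length (default 3
bins). A transition is only reported when the downstream/upstream mean ratio
leaves [1/1.5, 1.5]; flat profiles return "no transition". Multi-changepoint
segmentation is out of scope — the biological signal of interest is a single
internal start site.

Group-composition similarity between a stratum and the cohort uses a
chi-squared goodness-of-fit statistic with expected counts taken from the
cohort's group proportions (df = groups with nonzero expectation − 1), not a
2×4 contingency test: the question asked is "does this stratum deviate from
the cohort profile", with the cohort treated as the reference distribution.
Groups with zero expectation and zero observation are dropped; zero
expectation with a nonzero observation makes the test degenerate (p = 0,
flagged). Strata with fewer than ~5 samples per group emit a small-sample
warning.

## Negative-binomial differential expression

Counts are modeled as NB with mean *sⱼμ₉ᵢ* and variance *μ + φμ²* (φ = 0 is
Poisson). The implementation is a deliberately transparent, moment-based
version of the standard shrinkage-heavy packages:

- **Size factors** are median-of-ratios: per sample, the median over
  features (nonzero in every sample) of count/geometric-mean, rescaled to
  geometric mean 1. When no feature is nonzero everywhere the total-count
  ratio is used with a warning.
- **Dispersions** are per-feature method-of-moments estimates
  `max(0, (s² − μ̄)/μ̄²)` with the variance pooled within groups, optionally
  blended (weight 0.5 by default) with a least-squares mean–dispersion trend
  `φ(μ) = a/μ + b`. The shrinkage stabilizes small-sample estimates without
  reproducing any particular package's empirical-Bayes machinery.
- **The Wald test** contrasts group means of normalized counts:
  log₂FC = log₂(μ̂₂/μ̂₁) with a delta-method standard error from
  `Var(kᵢⱼ) = sⱼμ + φ(sⱼμ)²`, and a two-sided p from the normal reference
  (no t correction, per Wald convention). When one group's mean is zero,
  half the feature's smallest nonzero normalized count is added to both
  group means — a local pseudocount that keeps log₂FC finite without
  perturbing well-expressed features. Features with all-zero counts are
  reported untested (NaN p, NS direction).
- **BH FDR** is the exact step-up, with NaN p-values excluded from m and
  propagated. Direction calls are UP iff log₂FC ≥ 1 and q < 0.05 (≥, so a
  fold change of exactly 2 counts), DN iff log₂FC ≤ −1 and q < 0.05,
  applied post hoc rather than inside the test statistic. π values are
  log₂FC · (−log₁₀ q) with q = 0 clamped to 1e-300; ranking is descending
  with feature-id tie-breaks.

Validation is against planted truth and analytic oracles: the null
calibration band (3.5–6.5% of p < 0.05 at φ = 0.1, n = 20+20), sensitivity
≥ 0.9 for planted |log₂FC| = 2 at base mean ≥ 50, Poisson-GLM agreement in
the φ → 0 limit, and a cross-check against DESeq2 restricted to log₂FC
correlation and sign (exact agreement is not expected — the two pipelines
shrink differently). The same operations serve ATAC consensus-peak counts;
features are opaque ids throughout.

## Positional clusters

Genes are points at their start coordinate; strand is ignored. Windows of
10 Mb slide at 1-Mb steps per chromosome (the final partial window keeps its
actual span for density purposes). Per window and per category (all genes,
coding, lncRNA, UP/DN × coding/lncRNA) the fold enrichment vs the
chromosomal average is the window density divided by the chromosome density;
additionally, for UP-coding genes, the enrichment vs local gene density is
the window's UP-coding share of genes divided by the chromosome's share — a
scale-free way of asking "more UP genes than the local gene content
predicts". A window qualifies as cluster material when UP-coding enrichment
is ≥ 2 on both scales and the window holds ≥ 5 UP-coding genes; overlapping
or bookended qualified windows merge, and the window with maximal
chromosomal enrichment is the reported peak. Thresholds are configurable;
the defaults take the lower bounds of the enrichment ranges the motivating
analyses report. No multiple-testing correction is applied across windows —
cluster calling is descriptive and threshold-based, while gene-set overlap
(below) is corrected across sets.

Two study conditions are used for validating the caller, because one genome
cannot exhibit both properties at once. Null specificity runs on the
realistic default genome (6.5 genes/Mb — the human-genome rate — with 8% of
genes differential, 15% of those UP): at that UP density a 10-Mb window
holding ≥ 5 UP-coding genes is a rare Poisson clump, and ~97% of null
genomes yield zero calls. Recovery runs on a gene-dense, strongly perturbed
genome (20 genes/Mb, as on gene-rich chromosomes; 30% differential, half
UP), where a planted 5× cluster contains enough UP genes to clear the
count threshold essentially always; at the sparse default density a 5×
cluster holds only ~4 UP genes in expectation and is intentionally below
the caller's resolution.

lncRNA fractions among UP and DN genes come with exact Clopper–Pearson 95%
intervals. Gene-set overlap uses the hypergeometric upper tail
P(X ≥ k) with the population restricted to the supplied universe, BH across
the collection — the running-sum enrichment statistic is out of scope.

## qPCR

ΔCt = Ct(target) − Ct(reference gene) per sample/amplicon (replicate wells
averaged first), ΔΔCt subtracts the calibrator group's mean ΔCt per
amplicon, and RQ = 2^−ΔΔCt, so the calibrator's geometric mean RQ is 1.
Stage aggregation reports n/mean/median/quartiles per stage × amplicon and a
Welch t test between the two amplicons within each stage (pooled-variance
optional), with the conventional significance bands (* < 0.05, ** < 0.01,
*** < 0.001). Amplicon–amplicon agreement is Pearson's r, by default on
log₂ RQ since RQ is multiplicative; the linear scale is an option. Ct values
outside 10–40 cycles trigger a soft warning only. Amplification efficiency
is assumed ideal (100%); standard-curve methods are out of scope.

## Synthetic data

All generators are pure functions of their spec (including its seed):
identical specs give bit-identical outputs, and planted truth is always
returned with the data.

**Exon counts.** The expected count for exon *e* is
`scale_s · L(e) · (base + α·[e ≥ tss])`: a full-length transcript at
per-bp abundance `base` plus a second transcript starting at the internal
TSS exon with abundance α. Negative α (down to −base) models 3′ depletion.
Overdispersion is placed at the gene level: each sample draws one Gamma
factor (mean 1, CV² = φ) shared by all exons, and exon counts are Poisson
around the scaled mean. Marginally every exon count is NB(μ, φ), but the
within-sample exon ratio carries only Poisson read noise — which is how real
single-gene coverage behaves, since biological variability moves the whole
transcript, not individual exons independently. Had the exons been given
independent NB noise, the ratio would carry ~√(2φ) relative noise and a
±10% "balanced" band would be unreachable at φ = 0.05. Library depth varies
log-normally with a given CV (default 10%). Defaults: per-bp abundance 5
(anchor-exon expectation ≈ 900 reads), dispersion 0.05.

**Cohorts.** Regimes are lists of (size, α); α for a target expected ratio r
is `(r − 1)·base`. Stages default to a round-robin I–IV assignment.

**Genomes.** Background genes are placed uniformly per chromosome
proportional to length; each is UP/DN/NS by the direction mix and receives a
biotype by direction-conditional lncRNA probabilities (defaults 38% among
UP, 4% among DN, 30% among NS, matching the observed proportions in the
motivating cohort). Planted clusters add Poisson-distributed extra UP genes
so the local UP density reaches `fold ×` background. Genes never overlap
constraints — they are treated as points at their starts for all density
work.

**DE matrices.** Baseline means are log-uniform over a range (default
5–500); planted features multiply the group-2 mean by 2^log₂FC; NB noise at
a common dispersion with log-normal library-size variation.

**qPCR.** Latent per-sample log₂ abundances are multivariate normal with a
block coupling structure (RD pair and AD pair internally correlated at 0.95,
uncoupled across domains by default); Ct = reference Ct + offset − latent +
N(0, σ) cycle noise.

What the generators do **not** emulate: GC/length biases, mappability,
isoform complexity beyond the two-transcript mixture, correlated features,
batch effects, gene overlaps/strand structure, or amplification-efficiency
drift. Passing recovery tests therefore demonstrates correctness of the
statistics under their stated models, not robustness to those artifacts.

## Problem sizes and determinism

The validation suite uses 300-sample cohorts, 5,000-feature DE matrices
(20–30 samples per group), 100-seed null genome panels and 60-sample qPCR
panels — sizes at which the asymptotic approximations in use are reliable
while the whole suite runs in well under a minute. All randomness flows
through numpy `SeedSequence`; the acceptance script derives every
sub-analysis seed from the single `--seed` argument.

## Known limitations

- Two-level designs only; no covariates, no multi-factor contrasts.
- The dispersion trend `a/μ + b` is a convenience fit, not an
  empirical-Bayes posterior; borderline features near the significance
  threshold can differ from shrinkage-based packages.
- Cluster calling reports no p-values — it is a descriptive scan with
  thresholds, and the null false-call rate (~3% of genomes at defaults)
  is a property of those thresholds, not a controlled error rate.
- The Mann–Whitney exon comparison ignores within-sample pairing.
- A 5× positional cluster at sparse (realistic) UP density is below the
  caller's resolution by design; detecting such clusters requires either
  denser cohorts or relaxed thresholds.
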