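# Methods

## Heterogeneity scoring

MATH is computed as `100 · (1.4826 · median|VAF − median(VAF)|) / median(VAF)`
over a patient's somatic VAFs. The scaling constant follows the standard
MAD convention (consistent estimator of σ under normality), so for a
unimodal VAF cloud MATH approaches 100·σ/μ; for a subclonal mixture the
inter-clone spread dominates and MATH grows with clonal divergence. The
score is scale- and permutation-invariant and needs no matched-normal
beyond the somatic calls themselves.

Defaults that matter:

* **ITH cutoff 40.0, strict.** MATH > 40 is classed high-ITH; a score of
  exactly 40 goes low. The cutoff is a configurable parameter
  (`AnalysisConfig.ith_cutoff`).
* **min_variants = 5.** MATH over fewer points is dominated by sampling
  noise; patients below the floor raise `InsufficientDataError` carrying
  the count rather than returning a meaningless number.
* **Pre-score filter.** Non-silent classes, depth ≥ 14 reads, VAF ≥ 0.05 —
  common practice for exome callers; every threshold is an argument of
  `filter_variants_for_math`, and passing `min_depth=None, min_vaf=0` with
  the full class set reproduces unfiltered behaviour.
* **Cluster filter OFF by default.** An optional 1-D Gaussian-mixture step
  (BIC-selected up to 6 components) can drop VAF components carrying less
  than 5% of variants before scoring. Mixture fitting introduces algorithm
  and initialization dependence, so the plain formula is the reproducible
  baseline and the filter is opt-in. It never empties the sample (falls
  back to the input).
* **TMB** counts non-silent calls per 38 Mb of exome by default; both the
  denominator and the counted classes are parameters.

## Neoantigen enumeration

Protein effects (missense, nonsense, frameshift with translated novel
tail, in-frame indels) arrive as annotation: a protein FASTA plus an
effect table; the package does not re-annotate genomes. Mutant proteins
are built per effect, and all 8/9/10-mer windows overlapping the changed
residues are tiled. Missense windows are paired with their positional
wild-type counterparts; frameshift/indel windows have no positional WT, so
they carry none and any window occurring verbatim in the wild-type protein
is discarded as non-novel. Nonsense variants create no novel sequence and
yield no windows. Within a variant, duplicate peptide strings collapse.

Binder classification uses percentile ranks: strong at rank ≤ 0.5, weak at
rank ≤ 2. Equality classifies into the stronger class, matching the
behaviour of the standard rank-based predictors whose "below threshold"
wording is ambiguous at ties. The neoantigen unit is the unique mutant
peptide per patient at its best (lowest) rank across the patient's
alleles — not peptide×allele pairs — so a peptide presentable by several
alleles counts once. NAL is the strong-binding SNV-derived count by
default (`nal_definition="strong_all"` adds indel-derived strong binders).

Rank sources are pluggable. `TablePredictor` adapts netMHCpan-style output
(missing peptide×allele pairs are reported, not dropped, and score as
non-binders). `SurrogatePredictor` maps SHA-256(peptide|allele|seed) to a
Uniform(0,100) rank: a pure, platform-stable function that exercises every
counting path. Its ranks carry no binding biochemistry, so surrogate
counts are plumbing checks, not predictions.

Recognition potential A·R: A = Kd(WT)/Kd(mutant) (plain ratio; a saturated
variant can be layered on via config), R = logistic((s* − 26) · 4.87) with
s* the best gapless BLOSUM62 local-alignment score against a reference
epitope set — the published defaults of the recognition-potential model
this follows. Frameshift-novel peptides have no WT partner; their
amplitude defaults to the configured constant 1.0 and they are flagged.

## Escape index

`escape = sNAL/(sMAD/sMedian) − NAL/(MAD/median)`. The dispersion ratio
MAD/median is exactly MATH/100 — the same two statistics that enter the
heterogeneity score, before any optional cluster filtering unless the
caller opts in. The standard density defaults to the cohort's medians of
NAL and MAD/median (`method="cohort_median"`), because an absolute
standard for myeloma is not yet established and only relative indices are
interpreted; `method="fixed"` passes externally established constants
through. Zero dispersion makes the density undefined and raises rather
than returning an infinity. Median splits send ties at the median to the
low group (fixed, arbitrary, documented).

## Cohort statistics

Implemented over scipy.stats and lifelines. Conventions: all tests
two-sided at α = 0.05; Wilcoxon rank-sum uses the exact distribution up to
20 pooled untied observations, else the tie-corrected normal
approximation; the 2×2 chi-square is the **uncorrected** Pearson statistic
(df = 1) — the Yates-corrected statistic does not reproduce p = 0.047 on
the 8/22-vs-14/21 response table, the uncorrected one does; Cox models use
Efron tie handling (lifelines' default and the modern standard), report
Wald CIs and p-values, and flag non-convergence instead of crashing.

## Synthetic cohorts

The generator emulates the structure of a newly-diagnosed myeloma WES
cohort with known ground truth:

* **VAFs.** Each patient has a truncal clone (CCF 1.0) holding a
  Uniform(0.2, 0.5) share of mutations and 2–6 subclones at CCF
  Uniform(0.12, 0.6) splitting the rest (Dirichlet). Reads are
  alt ~ Binomial(depth, purity·CCF/2) at depth ~ Poisson(120) truncated at
  10, purity Uniform(0.65, 0.95), 20–70 mutations per patient (median
  ≈ 45, near the reported median of 42 variants per sample). These
  architecture ranges were chosen so the realized MATH distribution
  matches the study cohort's reported profile (median ≈ 59, range ≈ 10–123,
  ~88% above the cutoff of 40); the seed-1 49-patient cohort lands at
  median 59.5 with 43/49 high-ITH. The diploid heterozygous VAF model
  carries no copy-number variation by design.
* **NAL.** Negative-binomial marginal (mean 42, matching the reported
  median strong-binder count; size 6 for a long right tail), coupled to
  the realized MATH ranks by a Gaussian copula with latent correlation
  ρ = sin(π·τ/2) at target τ = −0.25. The coupling is reduced-form — the
  study reports a correlation, not a mechanism — and is applied at cohort
  level because the copula needs cohort ranks; tie-induced attenuation is
  small at these parameters.
* **Immune fractions.** CD8 and NK percentages couple to NAL the same way
  at τ = +0.26, CD19 at −0.30; CD3 and CD4 are uncoupled — mirroring which
  lymphocyte subsets the study found associated with neoantigen load.
* **Survival and response.** PFS is exponential with log-hazard
  β_MATH·(MATH − median) + β_NAL·(NAL − median), β_MATH = ln(1.022) and
  β_NAL = ln(0.982) per unit — the per-unit hazard ratios reported for
  MATH and strong-binder count — with baseline median 25 months. A patient
  is censored with probability 0.5 at a Uniform(0, T) time, giving an
  event rate near the study's ≈ 47%. P(≥VGPR) is logistic in NAL (slope
  0.05/binder), chosen to produce a response-rate gap between NAL halves
  of the magnitude the study observed (~36% vs ~67%).

What the generator does **not** emulate: mutation-signature composition,
gene identity effects, copy-number and HLA-LOH events, mechanistic
immunoediting (NAL is imposed, not derived from the simulated peptidome),
and inter-patient depth/purity correlation structure. Passing recovery
tests therefore shows the estimators and couplings behave correctly under
the stated model, not that the model captures every property of real
cohorts.

Because the surrogate rank predictor is independent of the generator's
latent NAL by construction, end-to-end recovery tests consume the
ground-truth strong-binder counts; the surrogate path is exercised
separately on the synthetic peptidome.

## Numerical choices and degenerate inputs

Medians via numpy (average-of-two convention for even n). VAFs must lie in
(0, 1] for MATH; a zero median raises. Escape densities require positive
dispersion. Rank-correlation calls reject constant inputs rather than
returning NaN. ANOVA on globally constant data returns the degenerate null
(F = 0, p = 1). The logistic in R is clamped against overflow for
extremely dissimilar peptides. All generators derive their streams from
`numpy.random.default_rng([seed, stream, index])`, so every artifact is a
pure function of the spec and seed.

## Problem sizes in the shipped tests and drivers

Recovery checks run at 200 patients (τ, escape stratification over 20
seeds) and 500 subjects × 50 seeds (Cox hazard-ratio recovery); the
scripted analysis uses the 49-patient default cohort. These sizes put
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the full suite in the tens of seconds.

## Known limitations

No RNA-expression filtering of candidates; no proteasomal-cleavage or TAP
modeling; no class-II prediction; no copy-number-adjusted cancer-cell
fractions (MATH is used as the single-sample ITH proxy); HLA-LOH is
accepted only as an optional per-patient boolean (the study cohort showed
none); the true cross-cohort standard neoantigen density is unknown, so
escape indices are comparative, never absolute.
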