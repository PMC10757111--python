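# mmith — intratumor heterogeneity, neoantigen load and immune escape in multiple myeloma

`mmith` is an analysis pipeline for single-sample whole-exome cohorts of
multiple myeloma (and other liquid tumors where multi-region sampling is
impossible). It quantifies intratumor heterogeneity (ITH) from the somatic
variant-allele-fraction (VAF) distribution, enumerates candidate MHC
class-I neoantigens from protein-altering variants, scores each patient's
immune escape, and links all three to treatment response and
progression-free survival (PFS). It is aimed at cancer-genomics analysts
who already have somatic calls (MAF/VCF/TSV), HLA class-I haplotypes, and
binding predictions (netMHCpan-style tables), and want the downstream
cohort analysis to be reproducible and testable.

## The quantities it computes

**MATH score** (mutant-allele tumor heterogeneity). For a patient's somatic
VAFs,

    MATH = 100 · MAD / median,    MAD = 1.4826 · median(|VAF_i − median(VAF)|)

The 1.4826 factor makes the MAD estimate the standard deviation under
normality, so MATH → 100·σ/μ for tightly clustered VAFs. Subclones sitting
at distinct cancer-cell fractions widen the VAF distribution and raise
MATH. A sample with MATH > 40 (strict) is classed high-ITH.

**Neoantigen load (NAL).** Every protein-altering variant is expanded into
all 8/9/10-mer mutant windows overlapping the altered residues (proteins
shorter than 8 aa contribute nothing). Each unique mutant peptide keeps its
best percentile rank across the patient's HLA-A/B/C alleles; rank ≤ 0.5%
makes it a strong binder and ≤ 2% a weak binder. NAL is the count of unique
strong-binding SNV-derived peptides. A recognition potential A·R
(binding-amplitude gain × logistic BLOSUM62 similarity to known pathogen
epitopes) is available per candidate.

**Escape index.** A patient's neoantigen density is NAL/(MAD/median); the
escape index is the cohort-standard density minus the patient's:

    escape = sNAL/(sMAD/sMedian) − NAL/(MAD/median)

High escape = few strong binders per unit of heterogeneity: the tumor has
diversified without presenting proportionally more strong neoantigens.
Only relative values within a cohort are meaningful; the default standard
is the cohort's own medians.

**Cohort statistics.** Median splits, Kendall/Spearman rank correlations,
Wilcoxon rank-sum, uncorrected 2×2 Pearson chi-square, Kaplan–Meier +
log-rank, multivariate Cox PH (via lifelines), and one-way ANOVA.

A synthetic-cohort generator produces myeloma-like cohorts with known
ground truth — binomial read sampling over subclonal architectures, a
target MATH↔NAL Kendall τ imposed by a Gaussian copula, immune-cell
fractions coupled to NAL, and exponential proportional-hazards PFS — so
every stage is testable without access to patient data.

## Worked example

```bash
ith simulate --n-patients 49 --seed 1 --out cohort/
ith math --variants cohort/variants.tsv --out math.tsv
ith run --cohort-dir cohort/ --out report/
```

Or the scripted analysis sequence (cohort data lands under `scratch/`,
summary tables under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_heterogeneity.py
python analysis/03_neoantigens.py
python analysis/04_escape_index.py
python analysis/05_cohort_statistics.py
```

Output of steps 01–02 and 05 on the default 49-patient cohort (seed 1):

```
n49: 49 patients, 2283 somatic variants, median true MATH 59.5, median NAL 42, event rate 0.49
49 patients scored
median MATH 59.5 (range 16.1-103.2)
high-ITH (MATH > 40): 43/49
MATH vs NAL kendall_tau_b: -0.259 (p = 0.009)
MATH vs NAL spearman_rho: -0.360 (p = 0.011)
printed response table 8/22 vs 14/21: chi2 = 3.949, p = 0.047
```

Reading: the generated cohort has the intended heterogeneity profile
(median MATH ≈ 59, 43/49 patients above the high-ITH cutoff of 40), the
imposed negative coupling between heterogeneity and strong-binder load is
recovered from the data (τ ≈ −0.26), and the uncorrected chi-square on the
response table (8 of 22 vs 14 of 21 patients reaching ≥VGPR, i.e. 36.4% vs
66.7%) gives p = 0.047 — patients with less neoantigen loss respond better.

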