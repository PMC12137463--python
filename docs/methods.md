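# Methods notes

This note records the statistical models implemented in `varscreen`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
comparing output against other tools.

## Study design being modelled

The package implements the analysis plan of a two-arm common-variant
screen plus a rare-variant exome arm for a heterogeneous phenotype
(pediatric POTS): a family cohort of complete trios tested by TDT, an
independent case–control cohort tested by PC-adjusted logistic
regression, an intersection rule requiring nominal significance in both
cohorts with concordant effect direction, gene-level aggregation and
set-level ORA, and a whole-exome case–control burden analysis of
qualifying rare variants followed by pathogenicity-database consensus.
Cohort-size defaults mirror that design: 100 trios, 207 cases vs 4063
controls on the array side, 87 cases vs 2719 controls on the exome side.

## Per-SNP tests

**TDT.** Transmissions are counted per trio from the genotype triple:
with `n_het` heterozygous parents and `forced` homozygous-alternate
parents, the child received `child − forced` effect alleles from
heterozygous parents; triples where that count is impossible are
Mendelian errors and are skipped (the QC stage removes loci with more
than 3 such trios). The statistic is (b−c)²/(b+c) on χ²₁, two-sided, the
PLINK convention; effect direction is carried separately for the
concordance rule, so sidedness does not interact with the intersection.
The χ² P tracks the *mid-P* exact binomial McNemar test within ~4% for
b+c ≥ 30 (the conservative exact test differs by up to ~30% at the
boundary; the property suite asserts both bounds).

**Logistic association.** One IRLS fit per variant (statsmodels Logit),
additive genotype coding, Wald P on the genotype term. Ancestry
correction uses the first 10 PCs of the mean-imputed, centred,
sqrt(2p(1−p))-scaled genotype matrix; component signs are fixed by
making each component's largest-magnitude loading positive so scores are
reproducible. Separation, non-convergence (|β| > 15 is treated as
de-facto separation) and zero genotype variance yield an *untestable*
flag (NaN P) rather than a number; no Firth correction is applied, so
untestable variants are visible instead of silently shrunk.
Zero-variance covariate columns are dropped before fitting, which also
makes "no informative covariates" reduce exactly to the unadjusted fit.

## Concordance and sensitivity

Effect alleles are harmonised before comparing directions: if the two
cohorts report swapped alleles the direction is negated and the OR
inverted; pairs matching neither orientation (including potential strand
flips) are dropped with a warning. The intersection uses strict
`P < alpha` in both cohorts and equal nonzero direction. Under
independent nulls the concordant fraction is α²/2 (α² for both P, times
1/2 for two equiprobable directions agreeing), and the suite checks this
by simulation. The leave-samples-out sensitivity report counts retained
SNPs (reduced-analysis P < α), and rescues lost SNPs that map to a gene
still containing a retained SNP; the gene map and ±50 kb window are the
same ones used for the gene-based test.

## Gene-based test

The gene statistic is Σᵢ F⁻¹(1−pᵢ; χ²₁) over mapped SNPs (the
"full-gene" variant; no top-x% truncation). The null draws
z ~ MVN(0, R) with R the Pearson correlation of additive genotype codes
estimated in controls (pairwise-complete), and compares Σ zᵢ². R is
repaired by eigenvalue clipping when slightly non-PSD (hard error below
−0.05). Simulations escalate through 10³ → 10⁴ → 10⁵ draws while fewer
than 10 exceedances support the estimate; P = (1+exceed)/(1+n) is never
0 and is floored at 1/(n+1). With identity LD the empirical P matches
the χ²_m closed form within Monte-Carlo error (checked for
m ∈ {1, 2, 5, 10}).

The expected number of genes reaching P < α in two independent cohorts
is G·α² (53.265 → 53 for G = 21,306, α = 0.05). The tail test for "more
overlap than chance" is a binomial upper tail computed by logsumexp over
log point masses, so it remains finite far beyond double-precision
underflow; the binomial choice is this package's documented convention —
the test behind the corresponding published figure is not identifiable,
so that number is not asserted anywhere.

## QC filters

Applied in the order R² → Mendelian errors → parental sex effect → HWE;
each filter removes variants only, never samples, and is idempotent.
The sex-effect test is a two-sided Fisher exact test on the 2×2 parental
allele-count table (exact at family-cohort sizes; χ² available); the
paper-style protocol names no specific test, and allelic rather than
genotypic comparison is the default. The HWE test is the exact
conditional-enumeration test (sum of outcome probabilities ≤ the
observed outcome's), with a mid-P variant behind a flag; it matches an
exact-fraction enumeration oracle on all inputs with total ≤ 200.
The IBD estimator is a method-of-moments solve of the IBS-class moment
equations at observed allele frequencies without PLINK's finite-sample
bias correction — adequate for the duplicate / parent-offspring /
unrelated distinctions it is used for, and a crude keep-every-k-th
prune flag stands in for LD pruning. Missing genotypes are excluded
pairwise/per-trio, never imputed (except mean-imputation inside PCA).

## Rare-variant burden

Qualification keeps variants with reference-population (NFE) AF ≤ 0.001
— "greater than 0.001 excluded" read literally, boundary kept — and at
least one satisfied predicate among the 14 predictor (field, value)
pairs; absent AF counts as 0 (novel). Carrier classes per gene and
individual: HOM if any qualifying homozygous-alternate genotype,
otherwise HET if ≥ 1 qualifying het, with CH flagged at ≥ 2 distinct
qualifying hets (no phasing is assumed, the TRAPD convention, so CH is
an upper bound on true compound heterozygosity and a subset of HET).
An individual counts once per model regardless of how many qualifying
variants they carry (an allele-count mode is deliberately not the
default). P_DOM is the one-tailed hypergeometric upper tail on dominant
carriers against the internal control cohort; this convention
reproduces all 55 published P_DOM values to 3 significant figures from
their printed HET/CH/HOM counts, which is why it is the defining
convention even though a public-database comparison (summary-control
mode, AC/AN capped at max(AN)/2 carriers) is also provided. Coverage
normalisation rescales the effective control cohort size per gene by
callable_frac_ctrl/callable_frac_case (floor 1); no published formula
exists for this step, so the rule is this package's documented choice
and is off by default.

## P/LP consensus

ClinVar and InterVar strings are lower-cased, split on `/ , | ;`, and
matched for standalone "pathogenic" / "likely_pathogenic" tokens; any
"conflicting" assertion vetoes the call. HGMD counts only the exact
class "DM" ("DM?", "DP", "FP" never qualify). Consensus requires ≥ 2 of
the 3 databases by default. The patient summary reports the fraction of
cases carrying ≥ 1 classified variant and the genes whose ≥ 2 distinct
P/LP variants are carried by ≥ 2 different individuals.

## Synthetic data

The generator is deterministic given `SimConfig` (per-stream
`SeedSequence` keys derived from a CRC of the stream name, so streams
are independent and stable across runs).

- *Trios*: parents from Hardy–Weinberg at per-SNP MAF (uniform in
  `maf_range`); each heterozygous parent transmits the minor allele with
  probability τ (0.5 null). Mendelian errors can be injected at a
  configurable rate by replacing child genotypes with impossible values.
- *Case–control*: two subpopulations diverged by a Balding–Nichols
  model at `strat_fst`; LD imposed blockwise via a Gaussian copula with
  exchangeable within-block correlation `ld_rho` (the latent correlation
  matrix is therefore known exactly); disease from a logistic liability
  with per-SNP log-ORs at baseline prevalence 0.1; cases drawn from
  subpopulation 1 with probability 0.5 + bias/2. The subpopulation label
  is recorded in the sample id (`_p0`/`_p1`).
- *Exome*: per gene a fixed variant count with a configurable qualifying
  fraction; dominant-carrier status Bernoulli per sample at the
  configured rate, with carriers split 90% single-het / 8% compound-het /
  2% homozygote; ClinVar P/LP labels at `plp_label_rate` with InterVar
  and HGMD agreeing at `plp_db_overlap` each.
- Missingness is MCAR at `missing_rate` with a sentinel code; real call
  sets cluster missingness by sample and locus, which is not modelled.

Default per-gene carrier rates for a true-effect gene are 0.08 (cases)
vs 0.0018 (controls) — the median burden-significant gene of the
published table (7/87 vs 5/2719). At those rates the exact one-tailed
Fisher at 87 vs 2719 has analytic power ≈ 0.72 at the genome-wide
threshold, so the power simulation expects a clear majority of
true-effect genes to reach significance; at rates as low as 0.05 vs
0.001 the analytic power is only ≈ 0.40, which is why the median-row
rates are the defaults.

What passing tests show, and do not show: calibration and power results
hold under the generator's idealised assumptions (independent samples,
MCAR missingness, exact Balding–Nichols structure, unlinked causal
SNPs); real data add linkage between causal and typed variants, batch
effects, differential missingness and cryptic relatedness, none of which
are claimed to be handled beyond the explicit QC filters.

## Problem sizes used by the checks

The self-checks run at reduced but statistically meaningful sizes chosen
so Monte-Carlo error stays well inside the asserted tolerances: null
calibration on 2000–4000 SNPs (binomial SE of the size estimate ≤ 0.005
at α = 0.05), 500 trios for TDT size (keeps b+c large enough that
discreteness does not bias the χ² size), 100 replicates for OR recovery,
300 genes for burden power, and 10⁵ simulations for the gene-test
closed-form comparison. Oracle-equivalence checks run on ≥ 1000
randomised small instances per exact test.

## Known limitations

- No X-chromosome models anywhere (the design analyses autosomes only).
- No mixed-model or meta-analytic association; cohorts are intersected,
  not combined.
- No LD clumping or genomic-control λ; stratification handling is PCs
  only.
- The IBD estimator is intentionally simple; it is a relationship
  screen, not a segment-level IBD method.
- Coverage normalisation is an effective-sample-size heuristic; with
  per-gene callable fractions near 1 it is a no-op.
- ORA tests one collection at a time; cross-collection FDR is not
  computed (matching per-collection reporting).
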