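# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices and the known limitations of `cogsys`.

## Phenotype preparation

Raw test scores pass through four steps in a fixed order that mirrors how such
cohorts are typically curated:

1. **Validity filter.** Individuals with a severe-medical flag
   (`medical_rating == 4`) are removed outright; rows whose validity code is
   not `V`/`V2` keep their covariates but have the score set to missing.
2. **Residualization.** Ordinary least squares of the score on an intercept,
   age (years) and a 0/1 sex indicator; the residual is the working phenotype.
   A rank-deficient design (no joint variation in age and sex) is an error,
   not a silent fallback.
3. **Outlier rule.** Residuals more than `k_sd` (default 4) sample SDs from
   the residual mean are blanked. Mean and SD come from the pre-filter
   residuals; a zero SD makes the rule a warning-level no-op. For a
   standard-normal sample of 10,000 the rule trims ~0.6 observations in
   expectation — it is a guard against gross artefacts, not a trimming step.
4. **Tertile binarization.** Empirical quantiles (linear interpolation) at
   1/3 and 2/3 split the scored rows into `poor` (bottom), `good` (top) and
   `unassigned` (middle). Boundary ties are inclusive, so under heavy ties the
   extreme groups may exceed n/3; a fully tied input yields no labels rather
   than a seed-dependent split. For distinct scores the groups balance to
   within one of ⌊n/3⌋.

## Genotype quality control

Per-variant and per-sample filters are composable pure functions; the
orchestrator applies them as: heterozygosity outliers (|rate − mean| > 3 SD)
→ missingness (individuals, then SNPs, fraction > 0.05) → relatedness →
MAF (< 0.01 removed; frequencies over non-missing calls; strict inequality)
→ exact Hardy–Weinberg (p < 1e-6). LD pruning (windowed greedy, window 50,
step 5, r² > 0.2, lower-MAF member dropped, ties to the later position) is
available as an operation and an opt-in pipeline step but is not destructive
by default: pruning is a device for relatedness/ancestry estimation, and
applying it to the association panel would discard most of the signal being
scanned.

The Hardy–Weinberg test is the standard exact conditional test (non-mid-p):
the distribution of the heterozygote count given the allele counts is built by
the usual two-sided recurrence from the mode, and the p-value sums the
probabilities of all tables no more probable than the observed one, with a
1e-12 relative tolerance on the comparison to absorb float round-off. It
matches an exact-rational enumeration for every table with n ≤ 30 at 1e-12.

Relatedness uses a single estimator — the off-diagonal of the standardized
GRM — for the kinship threshold (default 0.185); of each flagged pair the
member with more missingness (ties: the later index) is dropped, iterating
from the most related pair downward. Ancestry assignment projects samples and
labeled reference panels into a shared PC space (SVD of the combined
standardized dosages) and assigns a sample to a reference cluster when it lies
within `k_sd` (default 5) per-PC SDs of the cluster centroid on every retained
PC — a per-axis box rather than a Mahalanobis ellipse, the literal reading of
"within k SD of the centroid"; samples matching several clusters are flagged
ambiguous.

## Mixed-model association with LOCO

The label (good = 1, poor = 0) is analysed as a quantitative trait in a linear
mixed model — the convention of mixed-model GWAS tools for binarized traits —
not a logistic model. The GRM is

    A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1 − p_i))

over non-monomorphic SNPs, missing dosages mean-imputed per SNP. In-sample
allele frequencies zero each standardized column's sum, so the full matrix has
zero grand sum and the off-diagonal mean is exactly −trace/(n(n−1)); tests
assert this identity rather than naive centering at zero.

For each chromosome c the scan fits the null model by REML on the
leave-one-chromosome-out GRM: eigendecomposition of K, then a bounded scalar
search (tolerance 1e-8) over log(σ²_g/σ²_e) of the profiled restricted
likelihood, with a ratio→0 boundary candidate always evaluated so the fit
never does worse than OLS. Each SNP on c is then tested by GLS with the fitted
covariance structure: the data are whitened by D^(−1/2) in the eigenbasis
(D = ratio·s + 1), the covariate block is projected out by QR, and the Wald
ratio uses a per-SNP re-profiled residual scale (degrees of freedom
n − p − 1). Fixing the *structure* while re-profiling the *scale* is the
EMMAX/GEMMA convention; it makes the test reduce exactly to OLS at ratio 0,
which the test suite asserts to 1e-8 against statsmodels, and agree with a
dense explicit-inverse GLS oracle to 1e-8. Two-sided p-values use the standard
normal on the Wald ratio (large-n convention; at n = 500 the discrepancy
against the t reference is below 1e-3 in the CDF and does not disturb the
type-I calibration checks). Monomorphic SNPs yield flagged rows with missing
p. With a single chromosome LOCO is impossible and the scan falls back to the
whole-genome GRM with a warning. Covariates default to the intercept only —
age and sex are residualized upstream — but an optional covariate matrix is
accepted for designs that include ancestry PCs as fixed effects.

A fast engine (`linear_score_assoc`) implements the plain per-SNP linear score
test via correlations, vectorised over many phenotype vectors at once. It
exists for permutation re-runs at scale; observed and permuted statistics are
always computed by the same engine, never mixed.

## SNP-to-gene mapping

Only protein-coding genes are mapping targets. Three evidence channels:

- **eQTL**: an (SNP, gene, tissue) record is retained iff the SNP lies in
  open chromatin — intervals whose core 15-state chromatin value is ≤ 7
  (merged); enhancers are the `Enh`/`EnhG` states.
- **Hi-C**: an interaction contributes iff its enhancer side overlaps a known
  enhancer; the contacted gene is the one whose strand-aware promoter window
  (250 bp upstream to 500 bp downstream of the TSS, reflected on the minus
  strand) overlaps the promoter side. SNPs overlapping the promoter-side
  anchor receive the link by default; the enhancer side is selectable
  (`hic_snp_side`), since the source convention is ambiguous and both readings
  are defensible. A separate ±2 kb TSS window utility annotates promoter
  anchors for exploratory use.
- **Positional**: distance is 0 inside a gene body, else the minimum distance
  to the TSS or TES. The default maps each SNP to its nearest gene when that
  distance is ≤ 60 kb, keeping all co-nearest ties and all containing genes;
  an `all` mode keeps every gene within 60 kb.

Functional evidence has priority: a SNP with any eQTL or Hi-C link is never
also positionally mapped; a SNP may map through both eQTL and Hi-C, and to
several genes. The integrated map asserts this invariant on output.
Internally all intervals are 0-based half-open (BED convention); gene tables
and SNP positions are 1-based, and conversions are centralized in the I/O
layer.

## Gene-set enrichment

Gene score = min p over the gene's mapped SNPs; rank statistic = −log10(p);
ranking is by decreasing statistic with ties broken by gene id for
determinism. The running sum increments by |stat|^w / Σ_hits |stat|^w on set
members and decrements by 1/(N − N_hits) otherwise; ES is the signed maximum
deviation, and the leading edge comprises the members at or before the argmax
(after it, for negative ES). The weight exponent defaults to 1 (classic
weighted form) with 0 available; at weight 0 the ES is invariant to monotone
transforms of the p-values, which is property-tested.

The null distribution re-runs the identical association engine on
label-permuted phenotypes (default 100 permutations), rescores genes and
recomputes every pathway's ES. NES = (ES − mean(null)) / SD(null) (z-score
normalization, sample SD); nominal p uses the add-one estimator
(1 + #{null ≥ ES}) / (1 + n_perm), which cannot reach zero; q-values are
Benjamini–Hochberg across the tested pathways. Only pathways with 20–500
members *within the scored universe* are tested (inclusive bounds). Reporting
is one-sided: negative-ES pathways appear with their signed NES but are never
called significant, since the scientific target is enrichment of top-ranking
variants.

## The synthetic cohort

The generator emulates the study conditions at desk scale; its defaults are
the package's reference conditions, not tuning knobs:

- **Cohort**: 3,116 individuals aged 8–21 (uniform), balanced sex. Genotypes
  are two independent haplotypes per individual; within an LD block (10 SNPs)
  each haplotype copies the previous allele with probability `ld_rho` (0.8
  default; 0.9 yields median adjacent r² ≈ 0.8) and redraws from the SNP's
  allele frequency otherwise (frequencies uniform on (0.05, 0.5]). Missing
  calls are injected uniformly at random (1%) so the missingness filters have
  non-trivial input.
- **Score**: intercept + 0.1·age + 0.2·sex + causal + polygenic + noise. The
  causal term is an additive sum over one designated SNP per causal gene
  (default 30 genes, total variance 0.08); the polygenic term sums small
  random effects over all non-causal SNPs (variance 0.3, matching reported
  SNP-heritability for such phenotypes); the noise picks up the remaining
  unit non-covariate variance. Each realized component is rescaled to its
  exact target variance, so variance accounting is exact and recovery tests
  can condition on the realized fractions. The polygenic term is deliberately
  *not* drawn from N(0, σ²·GRM), keeping the generative model independent of
  the GRM estimator under test.
- **Annotations**: a deterministic toy genome tiles non-overlapping genes
  (alternating strand, ~6% non-coding) over chromosomes carrying a 2-kb SNP
  grid. A fraction of non-causal SNPs (5%) receive brain eQTL links with open
  chromatin over the SNP; another fraction (2%) sit inside promoter anchors of
  enhancer–promoter Hi-C contacts whose enhancer anchors overlap generated
  enhancers. Causal SNPs lie inside causal gene bodies and map positionally by
  construction. One pathway holds exactly the causal genes plus filler; the
  remaining pathways are random draws from the non-causal coding genes, so the
  planted set competes against pure noise sets — a simplification relative to
  real pathway databases, where overlap between sets dilutes ranking.

What the generator does **not** emulate: population stratification and
admixture (beyond the two-cluster ancestry fixture used by the QC tests),
linkage between causal and non-causal SNPs across blocks, realistic gene
length/SNP density variation, pathway overlap, genotyping batch effects, and
case ascertainment. Passing recovery tests therefore demonstrates
correctness of the machinery under the stated generative model, not expected
power on real cohort data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen to exercise every code
path with stable statistics: null type-I calibration pools 20 cohorts of
n = 500 × 2,000 SNPs through the full LOCO scan; enrichment null calibration
uses 10 cohorts of 50 pathways × 100 permutations with the fast engine;
pathway recovery uses 20 replicates of n = 2,000 with a 30-gene causal
pathway at 10% causal variance and 250 permutations (the NES ranking is
noticeably more stable at 250 than at 100 permutations). REML ratio recovery
bands ([0.75, 1.25] for the median, [0.4, 2.5] per seed) were frozen from a
pilot on a family-structured kinship; individual REML ratio estimates are
log-scale noisy even under strong structure.

Tie-breaks are deterministic everywhere (gene id in rankings, later
position/index in QC drops); all randomness flows through
`numpy.random.default_rng` with named child streams derived from a single run
seed, so every fixture and manifest is byte-reproducible. Degenerate inputs
(constant phenotype, zero-SD nulls, monomorphic SNPs, all-missing SNPs,
single-chromosome LOCO) are handled explicitly as errors, warnings or flagged
rows rather than silent propagation.

## Limitations

- The binarized label is modelled linearly; no logistic mixed model.
- No genotype imputation, phasing, strand reconciliation or genome-build
  conversion; inputs are assumed on one build and strand.
- Hi-C significance calling and chromatin-state model fitting are out of
  scope; the mapping consumes already-called interactions and segmentations.
- The permutation FDR is Benjamini–Hochberg over per-pathway nominal p-values,
  not the pooled-NES FDR of classic GSEA implementations.
- At very small SNP counts the GRM off-diagonal noise is large relative to the
  0.185 kinship threshold, so the relatedness filter over-trims; use it with
  panels of a few thousand SNPs or more.
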