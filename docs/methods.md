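# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the simulators do and do not emulate, and the
numerical conventions that make results reproducible.

## The analysis chain

The package targets the downstream half of a quantitative-trait GWAS in a
small clinical cohort: per-variant covariate-adjusted linear association,
gene-set enrichment of sub-significant signal, polygenic scoring from an
external base GWAS, and variance-explained/power arithmetic. The trait
modelled throughout is a bounded, right-skewed questionnaire score (8 items
scored 1–4, total 8–32), but nothing in the code is specific to that
instrument beyond the simulator's discretisation.

## Synthetic cohorts

**Genotypes.** Variants are grouped into LD blocks. Within a block each of
an individual's two haplotypes is a stationary first-order autoregressive
latent Gaussian (parameter `rho`, default 0.8) thresholded at Φ⁻¹(MAF), so
genotypes are in Hardy–Weinberg proportions at the drawn allele frequency
and the genotype correlation between adjacent variants equals the
tetrachoric-style quantity implied by `rho` (exposed as
`implied_adjacent_correlation`). Blocks are independent; there is no
recombination-map realism, no multi-ancestry admixture, and no family
structure (a kinship matrix can be injected for QC tests). Allele labels
follow a transition-biased substitution model (Ts:Tv = 2:1, the genome-wide
norm), so strand-ambiguous A/T and G/C pairs arise at realistic rates
(~1/6) rather than the 1/3 a uniform model would give — this matters to the
polygenic-scoring stage, which drops ambiguous variants.

**Phenotype.** On a unit-variance latent scale, the trait is the sum of
planted centred dosage effects, covariate effects, and Gaussian noise. Each
planted variant's coefficient is β = √(pve / 2p(1−p)), the standardised-
genotype convention under which its marginal population variance explained
equals the requested fraction — the same estimand the partial-r² module
reports, so parameter-recovery tests close the loop. Covariates (sex,
genotyping batch, age, three ancestry axes, an ordinal seizure-frequency
category) jointly explain `covariate_pve` (default 0.10) of the variance,
split equally across standardised columns. The default 0.10 is a
middle-of-the-road choice for demographic plus clinical covariates on a
behavioural trait; none of the calibration results are sensitive to it.
In `bis_like` mode the latent trait plus per-item noise is cut into four
ordered categories per item at quantiles (0.50, 0.80, 0.95) — giving the
right-skewed bounded sum typical of impulsivity self-ratings — and summed
over 8 items. Discretisation attenuates planted effects, so
parameter-recovery tests use the continuous mode; the bounded mode is for
end-to-end realism (integer scores in [8, 32], positive skew).

**Seizure-frequency covariate.** Its real-world distribution is not
something the simulator claims fidelity to; it is exposed as a configurable
ordinal (default 4 levels, uniform) and enters the association model as a
single ordinal column.

**Base GWAS.** External summary statistics for polygenic scoring are
simulated by rescaling the cohort's planted standardised effects so the
implied additive genetic variance equals `h2`, then adding the sampling
noise of a quantitative GWAS of `n_base` (default 100,000) individuals with
unit trait variance: se_j = 1/√(n·2p_j(1−p_j)), β̂_j = β_j + se_j·z. With
no planted variants and h2 > 0, effects are spread infinitesimally over all
variants. This emulates a well-powered external study sharing the target
cohort's architecture; it does not model cross-ancestry LD differences or
ascertainment.

**Seeding.** All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawns (genotypes, metadata, covariates, noise,
items, missingness each get their own stream), so outputs are bit-identical
given the configuration and no stage can perturb another's stream.

## Quality control

Variant filters: call rate < 0.90 removed, MAF ≤ 0.01 removed, imputation
quality r² ≤ 0.4 removed; individuals with dosage call rate < 0.90 removed.
Hardy–Weinberg failures at P < 10⁻⁴ are flagged in the report but retained,
matching the common array-QC practice of flagging rather than dropping in
founder-effect-prone clinical cohorts. The HWE test is the exact
conditional test (conditioning on the minor-allele count and summing the
probabilities of all heterozygote configurations no more probable than the
observed one), not the chi-square approximation: at a 10⁻⁴ flag level with
rare alleles, exactness matters. Computed in log-gamma space; configurations
tied with the observed probability are included with a 1e-12 log slack.

Kinship pruning consumes a kinship matrix rather than estimating one (the
estimator belongs to the relatedness-inference literature; the rule applied
here is the < 0.088 threshold). Selection of the unrelated subset is greedy
— repeatedly drop the individual with the most remaining ties at or above
the threshold, ties broken by the higher row index — which is deterministic
and, on the sparse relatedness graphs of cohort data, within one of the
maximum independent set (asserted against brute force on random 8-node
graphs).

The inverse normal transform uses Blom's offset c = 3/8,
Φ⁻¹((r − c)/(m − 2c + 1)) on average ranks; ties map to equal values and
missing values stay missing.

## Association

Each variant is tested by OLS of the trait on dosage, an intercept and the
configured covariates. P-values use the t reference with
n_used − predictors − 1 degrees of freedom rather than the normal: at a few
hundred individuals the difference is visible. Missing dosages are handled
per variant by complete-case deletion (default) or mean imputation — both
are exposed because genotype-tool conventions differ, and neither is
asserted as canonical. When no dosages are missing the scan uses the
Frisch–Waugh shortcut (residualise trait and dosage matrix against the
covariate block once, then per-variant simple regression), which is exact
for OLS and keeps a 5,000-variant scan at n = 2,000 in the low seconds.
Monomorphic or rank-deficient variants are emitted with NaN effect and
p = 1 rather than dropped, so output rows always align with input variants.

On the X chromosome (non-pseudoautosomal), hemizygous males are coded 0 for
the reference and 2 for the alternate allele under the X-inactivation
assumption; a heterozygous male X call is an error, since QC should have
removed it. The simulator and the VCF reader emit male X dosages already in
{0, 2}; the association scan verifies.

Population-structure covariates are taken as provided columns; PCA is not
reimplemented (the simulator emits ancestry axes directly).

## Gene-set enrichment

Variants with p ≤ 5×10⁻⁴ (configurable) are each annotated to the gene with
the nearest transcription start site on the same chromosome, strand
ignored; distance ties break to the smaller TSS, then lexicographic gene id
(the choice is arbitrary but must be deterministic). Genes hit by several
variants count once. Selected variants on chromosomes without annotation
are recorded as unassigned with a warning.

Each gene set is scored with the exact one-sided upper-tail hypergeometric
test — k hits in a set of size K, n selected genes, universe N — and the
fold enrichment (k/n)/(K/N). The universe is an explicit required input
because it silently controls every p-value; the worked examples use
N = 18,520, a protein-coding-scale universe under which five hits in sets
of nine and eight genes with 810 selected genes give 12.7- and 14.3-fold
enrichment simultaneously.

Calibration permutes the GWAS p-value column across variants B times
(default 2,000), keeping the variant-to-gene geometry fixed, and re-applies
the selection threshold and the hypergeometric statistic each time — so the
per-permutation selected-gene count varies, as it should when the selection
rule itself is part of the procedure. The permutation p-value per set is
(b + 1)/(B + 1), counting permutations whose statistic is at or below the
observed one; the pseudo-count keeps it off zero and puts its floor at
1/(B+1) — 0.0005 to four decimals at B = 2,000. Permuting p-values across
variants preserves the selected-count distribution but not LD clustering of
selected variants; this is the stated procedure's null, and its
super-uniformity under a fully null table is verified by simulation.

## Polygenic scores

Clumping is greedy: the remaining variant with the smallest p (ties by
chromosome, then position) becomes an index; remaining variants on the same
chromosome within ±`window_kb` whose r² with the index reaches
`r2_threshold` are pruned. Defaults r² = 0.1 and 250 kb are conventional
clumping-and-thresholding settings, exposed in config and never asserted as
anything more. The output is invariant to input row order, and every run is
audited post hoc against the no-correlated-pair rule in tests. LD r² comes
from reference genotypes as the squared Pearson correlation of
(mean-imputed) dosage columns.

Scores are Σ_j dosage_ij(effect allele)·w_j, then mean-centred. Effect
alleles matching the cohort's alternate allele use the dosage directly;
matches to the reference flip the weight sign (the constant this introduces
vanishes under centring); strand-ambiguous A/T and G/C variants are dropped
— deterministic and safe at this scale, where frequency-based resolution
buys little. Weights are on the additive scale (log odds for binary base
traits, beta for quantitative); a natural-log default with a log10 switch
is immaterial to association p-values since it only rescales the score.
Missing dosages contribute the in-sample mean dosage. The score–trait
association reuses the OLS engine and reports the Bonferroni critical value
0.05/(number of scores in the family) alongside.

## Variance explained and power

PVE of a variant group is the partial r²: fit the covariate-only model and
the covariates-plus-group model on the same complete cases and report
(RSS_base − RSS_full)/RSS_base. With one variant and no covariates this is
exactly the squared Pearson correlation; nested groups are monotone.

Power for a variant explaining fraction `pve` of the (covariate-adjusted)
trait variance in n individuals is the upper tail of a 1-df noncentral
chi-square with λ = n·pve/(1 − pve) beyond the central critical value at α.
The λ = n·pve/(1 − pve) convention (variance explained of the residualised
trait) is used rather than λ = n·pve: at the design point n = 324,
pve = 0.12, α = 5×10⁻⁸ it gives 88% power where the alternative gives ~78%,
and a design claim of 80% power at that point is only consistent with the
former. Both the formula and its limitation are tested: it is a
large-sample approximation that sits slightly above finite-sample
Monte-Carlo power of the OLS t-test (by ~0.1–2 points at n = 100–200,
from the degrees-of-freedom difference and the randomness of the realised
noncentrality), so the Monte-Carlo comparison in the tests uses a small
absolute band rather than simulation error alone.

## Pipeline and formats

`run_pipeline` chains simulate → QC → association → enrichment → PRS →
PVE/power from one nested config dict and one seed, writing text outputs
only: VCF v4.2 (GT for hard calls, DS for fractional dosages, MAF/R2 in
INFO), TSVs with a leading `#` dialect comment, GMT with the background
universe as a trailing `#UNIVERSE` pseudo-set so collections round-trip,
and JSON for reports. The manifest records the seed, a config hash, and
per-stage counts; a stage error aborts the run but the manifest still
records what completed. Everything is single-threaded by contract.

Default problem sizes (324 individuals × 1,000 variants for the packaged
config; up to n = 5,000 × 20 variants × 200 replicates and 2,000-variant ×
5,000-variant null scans in the calibration tests) are chosen so each
statistical check has the resolution it needs while the whole suite runs in
well under a minute of compute on one core.

## Known limitations

* The LD model is blockwise AR(1) on a latent Gaussian — adequate for
  clumping and enrichment geometry, not for fine-mapping realism.
* `info_r2` is a scalar per variant; imputation uncertainty is not
  propagated into dosages.
* The permutation null treats variants as exchangeable; LD among selected
  variants is preserved only through the fixed variant-to-gene geometry.
* Gene sets are flat (no GO DAG propagation or term ancestry), and no
  multiple-testing correction is applied across sets beyond reporting.
* The power formula is asymptotic (see above); for exact finite-sample
  power, simulate.
* Passing tests on these simulators shows the machinery is correct and
  calibrated under the stated generative model; it does not certify
  behaviour under real-data pathologies (differential missingness, batch
  confounding, cryptic structure) that the generator does not emulate.
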