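# Methods

## Study design assumed

All methods target a 1:1 individually matched case-control design: each
case is paired with one control of the same sex whose age lies within a
tolerance (default ±9 years). The pair identifier is a hard structural
invariant — every loaded cohort must decompose into pairs of exactly one
case and one control of equal sex — because the conditional likelihood is
defined per pair and silently broken pairs would bias every downstream
estimate.

Genotypes are reduced at load time to risk-allele dosages keyed by rsID:
0/1/2 copies for autosomal SNPs and for females at X-linked SNPs, 0/1 for
hemizygous males. Allele matching is by nucleotide identity only;
strand-ambiguous A/T and C/G sites are accepted with a warning and never
flipped, which is appropriate for candidate-panel genotyping on a single
platform but would be wrong for cross-platform meta-analysis. Missing
genotypes are never imputed: each per-SNP analysis uses the pairs complete
for that SNP, so per-SNP denominators vary, and risk scores are computed
over observed SNPs with the number of missing panel SNPs recorded per
subject.

## Hardy–Weinberg exact test

The primary test is the exact conditional test. Conditional on the
observed allele totals, the probability of a genotype configuration with
`h` heterozygotes is

    P(h | n, nA) = n! 2^h nA! na! / (nAA! h! naa! (2n)!),

and the two-sided p-value sums all configurations whose probability does
not exceed the observed one (with a 1e-12 relative slack when comparing
probabilities, so exact ties accumulated in floating point are counted as
ties). Factorials are evaluated as log-gamma, which keeps the computation
exact to ~1e-10 relative error against a rational-arithmetic oracle at the
sample sizes of interest (hundreds of subjects); the test suite checks
this exhaustively for all instances with at most 40 alleles. The exact
conditional test is discrete and therefore conservative: its rejection
rate under the null sits at or below the nominal level, which the null
simulation tests assert as an upper bound rather than an equality.

A one-degree-of-freedom chi-square variant is included for cross-checking
only. X-linked SNPs are tested in females only; hemizygous males carry no
information about genotype-frequency equilibrium.

## Conditional logistic regression

For 1:1 pairs the conditional likelihood reduces to a no-intercept
logistic likelihood on case-minus-control covariate differences with all
responses 1. The implementation is Newton–Raphson on that formulation:

* gradient tolerance 1e-8 (max-norm), at most 50 iterations, step-halving
  whenever a full Newton step would decrease the log-likelihood —
  small designs converge in a handful of iterations and the procedure is
  fully deterministic;
* covariate columns that are concordant within every pair (zero
  difference throughout, e.g. the matching variables sex and, usually,
  age group) carry no conditional information and are dropped from the
  fit; a model whose every column is dropped raises a non-identifiability
  error;
* complete separation is detected two ways: a coefficient escaping past
  30 during iteration, or a "converged" coefficient larger than 15 (the
  gradient flattens along a separated direction before the in-loop bound
  is reached). Both raise an error naming the offending covariate; the
  per-SNP scan converts such errors into flagged result rows instead of
  aborting.

Standard errors come from the inverse observed information at the
optimum; confidence intervals and p-values are Wald-based, matching the
common reporting of OR with 95% CI. A likelihood-ratio omnibus p per SNP
(crude codominant fit against β = 0, where the null conditional
log-likelihood is −n·ln 2) is the single primary p-value to which the
Bonferroni threshold α/48 is applied — one test per SNP, not per
contrast.

Agreement with an independent implementation (statsmodels
`ConditionalLogit`) is asserted in the tests to ~1e-4, and the
single-binary-covariate case is asserted against the closed form (the
discordant-pair ratio) to 1e-6.

## Genetic models

The reference genotype for the codominant and recessive encodings is the
most frequent homozygote in the pooled (cases + controls) complete
observations, with ties broken toward the non-risk homozygote. Dominant
is the carrier indicator (dose ≥ 1), recessive the risk-homozygote
indicator (dose = 2). The allelic comparison is implemented as
conditional logistic regression on the per-subject dose treated as a
continuous 0/1/2 covariate, because allele-level pairing within matched
pairs is not well defined; the crude allele-level cross-product OR from
the 2×2 allele-count table is available alongside
(`crude_or_2x2(freq_table(..., level="allele"))`). For the X-linked SNP
in mixed-sex cohorts, a dose-1 male (hemizygous carrier) is encoded on
the heterozygote/carrier column; this folds hemizygotes into the carrier
contrast rather than modelling sexes separately, and is noted as a
simplification.

Adjusted models difference the covariate design within pairs. Categorical
covariates are dummy-coded against their first level with missing kept as
an explicit category; energy intake enters as a quantitative column, with
missing intakes mean-imputed and accompanied by a missing-indicator
column (the quantitative analogue of the missing-as-category rule).

## Frequency tests

Case-control genotype and allele tables are tested by chi-square without
continuity correction unless any expected cell is below 5, in which case
an exact test is used: two-sided hypergeometric for 2×2, full conditional
enumeration for 2×3 (all tables with the observed margins, summing
probabilities ≤ the observed table's), and a seeded Monte-Carlo exact
test for anything larger, flagged as such in the result. Tables with a
zero margin return an undefined p with a flag. Crude 2×2 odds ratios use
the cross-product with a Woolf log-normal CI and a +0.5
Haldane–Anscombe correction (flagged) when a single cell is zero.

## Genetic risk scores

The count score sums coded doses; the weighted score multiplies them by
per-SNP weights. The X-linked SNP is coded 0/0.5/1 in **both** scores
(female heterozygote 0.5, male carrier 1): the count-score maximum of 95
(= 2×47 + 1) requires it. The default weight is the published per-allele
OR itself: under OR-weighting the panel maximum is 2×52.12 + 1.04 =
105.28 ≈ 105, consistent with the score range the panel is described
with, whereas log-OR weights would give ≈ 9.9. The literal
"β-coefficient" (log-OR) convention remains available as
`weight_mode="log_or"`; under it, SNPs with OR < 1 (rs12080929,
rs11987193, rs1665650) contribute negative weights and the theoretical
bounds reported by `score_bounds` account for that. Panel entries with
OR < 1 otherwise contribute their tabulated risk allele and weight as-is.

Score-case-status association is a conditional logistic fit with the
score as a single continuous covariate (crude or adjusted); group
comparison reports means, s.d. and ranges plus a paired t-test and a
Wilcoxon signed-rank alternative. Zero-variance pair differences make the
t statistic degenerate, so that case is short-circuited: p = 1 for a zero
shift, p = 0 for a nonzero constant shift.

## Correspondence analysis

Simple CA of the subjects × category-indicator matrix rather than a
Burt-matrix multiple CA: each binary variable contributes two 0/1
columns, a missing value leaves that variable's block zero (logged), and
one carrier flag (dose ≥ 1) is added per selected SNP. The correspondence
matrix P = N/n is centred by the rank-one margin product, standardised by
the square roots of the row/column masses, and decomposed by SVD;
principal coordinates are mass-scaled singular vectors times singular
values, per-axis inertia fractions are squared singular values over their
sum, and total inertia equals the table's chi-square statistic divided by
the grand total (asserted in tests to 1e-10). Axis signs are fixed
deterministically by making the largest-magnitude column loading positive
on each axis; sign indeterminacy is the only permitted divergence from a
reference SVD.

## Synthetic cohorts

The generator's defaults describe a faecal-occult-blood screening cohort:
integer ages uniform on 50–69 (binned into 50–59 / 60–69 for analysis),
66.2% male, covariate prevalences typical of such a cohort
(overweight/obese 67%, low physical activity 77.4%, ever-smoker 60.9%,
alcohol tertiles ≈ a third each, deprivation Q4–Q5 30.4%), energy intake
normal with mean 2100 and s.d. 600 kcal/day truncated at 800, and 5% of
covariate values set missing to exercise the missing-as-category path.
Disease is assigned by a logistic model: logit = baseline + Σ dose·ln(OR)
+ covariate log-odds (covariate effects default to zero). The baseline
logit defaults to −1.5 and the source population to 10× the requested
pairs, which yields roughly 1.8 eligible cases per requested pair and
makes matching reliably feasible; a shortfall raises an error naming the
deficit rather than returning a partial cohort. Matching is greedy: cases
in random order each take the nearest-age unused control of the same sex
within the tolerance (ages are bucketed by integer year, so this is
exact). All randomness flows from one integer seed and identical
configurations produce byte-identical output tables.

What the generator does **not** emulate: linkage disequilibrium between
panel SNPs (simulated independent), population stratification,
genotyping error, and covariate-genotype correlation unless explicitly
configured. Passing tests therefore demonstrate correctness of the
estimators under the design's own assumptions, not robustness to those
real-data complications.

## Problem sizes used in validation

The recovery checks run 200 replicates of 1000-pair cohorts with one SNP
at true OR 2.0 and two null SNPs: the mean estimated log-OR is required
to land within 0.05 of ln 2, empirical 95% CI coverage within [90%, 98%],
and null type-I error at α = 0.05 within binomial noise. Estimates
reconstructed from published marginal genotype counts average the
conditional log-OR over 40 seeded random pairings, because the pairing is
the one ingredient of the conditional estimate the marginal counts do not
determine; the average stabilises within ±0.05 of the marginal
cross-product. These sizes were chosen as the smallest at which the
Monte-Carlo error of each check is comfortably below its tolerance.

## Known limitations

* The X-linked codominant encoding folds male hemizygotes into the
  carrier column instead of fitting sexes separately.
* The allelic "conditional" estimate conditions on subject pairs, not
  allele pairs; no allele-level pairing is defined.
* The exact frequency test beyond 2×3 is Monte Carlo (seeded), not a
  network enumeration.
* Adjusted fits drop the whole SNP model on complete separation of any
  covariate column; a penalised (Firth-type) fallback is not provided.
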