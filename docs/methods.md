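# Methods

## Genotype-to-phenotype translation

CYP2D6 function is summarized by the activity-score (AS) system: every star
allele carries a value in {0, 0.5, 1} (no / decreased / normal function),
duplications written `*1x2` multiply the base value, and the diplotype score
is the sum of the two allele values. Scores map to metabolizer categories as
PM = 0, IM = (0, 1), NM = [1, 2], UM > 2. The IM band is deliberately the
whole open interval rather than the single value 0.5 so that tables
containing 0.25-valued alleles still classify; on the default value set
{0, 0.5, 1} the two definitions coincide.

The default allele table (normal: \*1, \*2, \*35; decreased: \*9, \*10,
\*17, \*29, \*41; none: \*3–\*6) was cross-checked against public
genotype–phenotype translation tables and can be replaced by any YAML/JSON
map. An allele absent from the table yields an *unknown* score and the
UNKNOWN phenotype — never a silent zero — and UNKNOWN patients are excluded
by the inclusion filter rather than guessed at. Comparing UNKNOWN against
the metabolizer order raises an error by design.

Cohorts may alternatively supply a pre-called `gPT` column directly,
bypassing diplotype translation, since phenotype callers operating on array
data are the common upstream source.

## Phenoconversion rules

Inhibitor strength is a total order NONE < WEAK < MODERATE < STRONG; a
patient's exposure is the maximum strength over their concomitant
medications (the main treatment drug is not counted as its own inhibitor).
The correction is:

| gPT | strong | moderate | weak/none |
|-----|--------|----------|-----------|
| UM  | PM     | NM*      | UM        |
| NM  | PM     | IM       | NM        |
| IM  | PM     | IM       | IM        |
| PM  | PM     | PM       | PM        |

(*) UM under a moderate inhibitor is an extrapolation: the source rule set
never encountered ultrarapid metabolizers, so we apply a one-step reduction
and flag the resulting conversion event `extrapolated=True`. Note this
single cell breaks idempotence of the correction (NM would drop further to
IM on a second application); within the PM/IM/NM value set the correction
is idempotent, monotone non-increasing, and monotone in inhibitor strength.

Drug names are normalized (lowercase, trimmed, salt suffixes such as
"hydrochloride" stripped) before lookup. CYP2D6 has no known inducers, so
no induction pathway exists and tables containing `inducer` entries are
rejected with a clear error. Inhibitor dose and exposure timing are ignored
(binary exposure) — a deliberate mirror of clinical phenoconversion
calculators, and a known limitation.

## Cohort summaries

The inclusion filter retains patients with a main treatment drug, a known
phenotype, and a chlorpromazine-equivalent dose of 25–1000 mg/day, logging
one named reason per exclusion. Frequency tables report counts and
within-stratum percentages (one decimal); conversion metrics report the
number and share of patients whose pPT differs from their gPT, the PM count
before/after correction, and the percent increase in PM (nearest integer).
When only strong and weak inhibitors occur, the number of conversion events
equals the PM gain; the code counts any pPT ≠ gPT and reports
conversions-to-PM separately, so a hypothetical moderate-inhibitor cohort
is still counted coherently.

The test battery wraps Kruskal–Wallis (tie-corrected H, chi-square
reference; an exact full-enumeration p is available for small samples),
Dunn's pairwise z-tests on pooled tied ranks, and categorical association
with the conventional switch: Fisher's exact test when any expected cell is
below 5 (2×2 exactly; larger tables by fixed-margin Monte-Carlo on the
chi-square statistic, seeded), Pearson's chi-square otherwise, with the
method recorded in the result. Bonferroni correction is min(1, m·p); the
family size m defaults to the number of comparisons in the reported family
and is configurable, since reporting conventions differ.

## Outcome models

Continuous scales use OLS. The log-likelihood is the profile Gaussian
likelihood and AIC = 2k − 2lnL with k counting the intercept, the slopes,
and the residual variance — the convention of R's `AIC()` — so AIC values
are comparable across nested fits of the same rows. R² is 1 − RSS/TSS.

The six-level BARS uses a proportional-odds cumulative logit model:
P(Y ≤ j | x) = logistic(θ_j − xβ) with strictly increasing thresholds θ and
slopes shared across splits. Fitting is delegated to statsmodels'
`OrderedModel` (logit link), which implements exactly this likelihood with
the ordered-threshold reparameterization via log-increments; we wrap it with
an informed start (null-model thresholds, zero slopes) and a gradient-norm
tolerance of 1e-6, fall back to a derivative-free polish if line search
stalls, and surface diverging coefficients (|β| > 30) as a
complete-separation error instead of returning a silent non-fit. With two
outcome levels the model reduces to binary logistic regression, a property
the tests exploit. R² for ordinal fits is McFadden's pseudo-R²
(1 − lnL/lnL₀), labelled as such. A model whose free terms have all been
dropped is handled in closed form from the category frequencies.

Phenotype enters every model as an unordered factor with NM as the
reference level, matching how PM/NM contrasts are conventionally reported.
Ethnicity enters as a white/non-white indicator: cohorts of this kind are
~80% white and full dummy coding is rank-fragile in 50-patient drug groups.

**Backward stepwise AIC.** Starting from the full covariate pool, the
single non-forced term whose removal most reduces AIC is dropped until no
removal helps; the phenotype term (and anything else in `forced_terms`) can
never be removed. Exact ties break toward the smaller model, and candidate
order is alphabetical so selection is deterministic. Complete cases are
fixed once, over the outcome and the *initial* term pool, so every submodel
sees identical rows — without this, AICs are not comparable. Candidate
models are scored by a likelihood-only fit (BFGS on the same likelihood);
the accepted model is refit in full, warm-started at the candidate optimum.
Greedy backward selection can in principle miss the global subset optimum;
the tests verify it reaches the exhaustive-enumeration minimum on
independent-covariate designs and that its AIC trajectory never increases.

**Dual-basis comparison.** The protocol runs once with gPT and once with
pPT, then applies the ΔAIC rule: |AIC_g − AIC_p| < 2 means the bases are
indistinguishable (preferred = neither); otherwise the lower-AIC basis is
preferred. Covariates with no variation within a drug group are dropped
from the candidate pool before fitting.

## Synthetic cohorts

`generate_cohort` draws, per patient: sex (79.6% male), gPT from
(PM, IM, NM) = (4.1%, 40.5%, 55.3%) — printed frequencies that sum to 99.9%
are renormalized — a main treatment drug from the four-drug mix
122:111:60:49, a dose uniform on 50–700 mg/day rounded to 5 mg (chosen to
match a reported mean of ~368 mg while staying inside the 25–1000 inclusion
window by construction), inhibitor exposure with probability 102/412 and a
68% strong share (strong picks weighted toward paroxetine over fluoxetine
49:10, weak picks weighted by their observed frequencies), and covariates
(age ~ N(27, 7.1²) clipped to 16–50, illness duration ~ N(4.3, 3.5²),
episodes 1 + Poisson(0.7), 35.4% smokers, 36.7% birth-control use among
women). Diplotypes realize the sampled gPT deterministically: PM → \*4/\*4,
IM → \*4/\*41, NM → \*1/\*1, UM → \*1x2/\*1. (\*4/\*41 rather than \*1/\*4
for IM because \*1/\*4 has AS 1.0, which the cutpoints classify NM; the
chosen diplotype round-trips through the translation layer.)

Outcomes are linear predictors plus Gaussian noise (continuous) or a latent
logistic variable cut at fixed thresholds into the six BARS levels
(ordinal). Phenotype effects can be keyed to gPT or pPT via
`effect_basis`, giving the dual-basis comparison a known ground truth; the
default PM effect sizes are of the magnitude reported for poor metabolizers
on symptom scales (e.g. +9 points on PANSS negative, residual sd 8). The
generator is reproducible: the same seed yields a byte-identical table.

What the generator does *not* emulate: correlation between inhibitor use
and covariates (depression indication, sex-specific prescribing), dose
distributions by drug, longitudinal exposure, linkage structure among
alleles, or missing data. Tests passing on synthetic cohorts therefore
validate the *machinery* — rule arithmetic, likelihoods, selection — not
clinical effect estimates on real data.

`reconstruct_marginal_cohort` is the deterministic counterpart: given
phenotype counts, per-phenotype strong-inhibitor assignments, and an
optional per-sex split, it emits a cohort reproducing those marginals with
equality (women are filled first within each phenotype block; paroxetine is
the canonical strong inhibitor). Placeholder fields are valid and inside
inclusion bounds. Where a printed report gives only per-sex totals, the
within-sex IM/NM split of inhibitor assignments is under-determined; any
split consistent with the totals reproduces all per-sex summary statistics,
and the shipped fixtures use one such split.

## Numerical choices and problem sizes

- Stepwise tie tolerance 1e-10; AIC–likelihood identity asserted to 1e-8.
- Ordinal convergence: gradient norm 1e-6; small-sample optima verified
  against a refined dense grid search to 1e-3 in log-likelihood.
- Rank checks by QR with relative pivot threshold 1e-8, reporting the
  collinear columns by name.
- Monte-Carlo p-values use an add-one correction and a fixed seed.
- Simulation-based checks use 100 replicates at n = 412 (basis preference)
  and n = 2000 (coverage of a +5-point PM effect, residual sd 10), sizes at
  which the checked properties are sharp while the suite stays fast.

## Known limitations

- Binary inhibitor exposure; no dose–response or washout modelling.
- Only CYP2D6: outcomes of drugs cleared mainly by CYP1A2/CYP3A4 are
  modelled with the same covariate pool but no enzyme-specific terms.
- The UM-under-moderate rule is an extrapolation (flagged in output).
- Greedy stepwise is not guaranteed globally optimal for correlated
  covariate pools.
- The proportional-odds assumption is imposed, not tested; a
  non-proportional (multinomial) alternative is out of scope.
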