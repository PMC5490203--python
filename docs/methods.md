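# Methods

`dimorph` reimplements, as a tested library, the statistical pipelines used
to quantify sexual dimorphism (SD) in high-throughput mouse phenotyping
data: how often sex influences a trait in wildtype animals, and how often
sex modifies the effect of a gene knockout. This note records the models,
the numerical choices, and what the synthetic-data tests do and do not
establish.

## Data model and assembly

The unit of input is one animal × trait measurement with full provenance
(centre, genetic background, pipeline, procedure, parameter, metadata
group, batch date, sex, genotype class, body weight). A *batch* is the
calendar date of measurement at one centre; environment drifts over time,
so batch enters every continuous model as a random intercept shared by all
animals measured that day.

Assembly rules:

- **Wildtype data sets** group controls by (centre, background, pipeline,
  parameter, metadata group) and are retained only with both sexes present
  and strictly more than 100 observations per sex (read strictly: ≥ 101).
  "Data points" are counted as rows.
- **Mutant data sets** join one knockout colony with all matching controls
  from the same context; retention needs both sexes with strictly more
  than 5 mutant readings per sex (≥ 6). For continuous traits every
  analysed animal must carry a body weight; weightless animals are dropped
  with a logged count before the count rule applies.
- **Body weight** is the nearest measurement within ±4 days of the trait's
  batch date; at an exact |offset| tie the earlier date wins
  (deterministic, arbitrary but fixed).
- **Workflow classes** describe how a knockout cohort spreads over
  batches: *multi-batch* = ≥ 4 distinct mutant batches with ≥ 3 in one sex
  and ≥ 2 in the other; *one-batch* = a single date; everything else
  *low-batch*.
- **Viability**: a line is non-viable with 0 homozygotes among ≥ 28
  intercross offspring, subviable when the homozygote fraction is < 13%.

## Statistical primitives

**Bias-reduced logistic regression.** Categorical outcomes (recoded
as-expected → 0, not-as-expected → 1) are modelled by logistic regression
maximizing the Jeffreys-penalized likelihood ℓ(β) + ½ log det I(β)
(Firth-type), which gives finite estimates under complete separation — the
normal situation with 7-animal cohorts. Fitting is Newton iteration on the
modified score with step-halving; frequency weights let 2×2 tables be
fitted from their margins. The likelihood-ratio test uses the *profile*
construction: the null is the full model with the tested coefficients
constrained to zero, so both likelihoods carry the same penalty, the
statistic is non-negative and vanishes exactly when the data carry no
signal. The statistic is referred to a chi-square with df equal to the
rank difference (the bias-reduction literature offers alternatives; the
chi-square reference is the conventional choice).

**Mixed models.** Continuous traits are modelled as fixed effects plus a
batch random intercept plus residual noise whose variance is either
homogeneous or stratified by a declared factor (sex for wildtype analyses,
genotype for mutant analyses). statsmodels' MixedLM cannot stratify the
residual, so the marginal Gaussian likelihood is implemented directly:
per-batch covariance blocks D + σ²_b·11′ are inverted by Sherman–Morrison,
fixed effects are profiled out by GLS at every variance evaluation, and
the 2–3 log-variance parameters are optimized by L-BFGS-B (with a
Nelder-Mead polish when a line search fails at a variance boundary). All
fits are ML, not REML, because LR tests compare models with different
fixed-effect structures. The homogeneous special case reproduces
statsmodels MixedLM log-likelihoods to ~1e-4.

**Residual-structure selection.** The stratified structure is kept only
when it improves the likelihood significantly — a chi-square LR test at
α = 0.01 — rather than by AIC. Measured on null resampling studies, greedy
AIC adopts the extra variance parameter ~16% of the time and the tests
conditional on that adoption reject at ~22%, inflating the overall
type-I error to ~0.08; the LR rule at 0.01 restores calibration while
keeping essentially full power to detect a genuine 4× variance ratio.
AIC selection remains available (`mixed_model_fit(selection="aic")`).

**Exact stratified test.** The categorical genotype test is the one-sided
Cochran–Mantel–Haenszel mid-p: conditioning on all margins, the total
mutant abnormal count is the convolution of per-stratum hypergeometrics;
the mid-p counts half the probability of the observed total, softening the
conservatism of discrete tests. Direction is one-sided toward *higher*
abnormality in knockouts, because outcomes are coded against an
"as expected" baseline. Degenerate tables (single-point null, e.g. zero
abnormal anywhere) return p = 1 and are filtered.

**Attainability filters.** Discrete tests have a minimal attainable p
given their margins ("alpha star"). Data sets whose alpha star is ≥ 0.05
can never reach significance and are excluded *before* testing, shrinking
the multiplicity family. Two filters exist: the Mantel–Haenszel alpha star
(minimum of the CMH mid-p over outcome allocations; computed on the mid-p
scale for internal consistency — the deposited scripts' scale is not
stated) and the knockout-only LR alpha star (minimum of the penalized LR p
over splits of the observed abnormal count between the sexes).

**Multiplicity.** "Hochberg to control the FDR" is ambiguous (Hochberg's
step-up controls FWER; Benjamini–Hochberg controls FDR). Both are
implemented via statsmodels; the pipeline default is `hochberg_stepup`
because that is the procedure named, with `benjamini_hochberg`
selectable. Adjustment families are always study-wide per analysis
variant, never per centre, and the stage-1/stage-2 families of the mutant
pipelines are separate per trait kind.

**Effect intervals.** Differences of two proportions get the Newcombe
hybrid score interval (square-and-add of per-group Wilson limits), which
stays non-degenerate at 0/n. Per-sex genotype effects get Wald 95%
intervals with no multiplicity correction (matching the per-gene summary
convention) and are standardized by the average of the wildtype female and
male means; standardization is refused when that denominator is within
1e-8 of zero.

## Pipelines

**Wildtype sex effect.** Categorical: penalized LR of `Y ~ sex` vs
`Y ~ 1`; effect = female − male abnormality-rate difference. Continuous,
weight-adjusted: LR of `trait ~ sex + weight + (1|batch)` vs
`trait ~ weight + (1|batch)`; absolute: the same pair without weight.
(The weight-adjusted model pair is a reconstruction from the stated
purpose — the source's equation images are unreadable.) Direction labels
are attached only to significant results, after study-wide adjustment.
Cross-centre concordance is computed per parameter measured at ≥ 3
centres; discordant = at least two centres significant in opposite
directions (mixed significant/non-significant is indeterminate, not
discordant, since sensitivity differs across centres); the denominator is
variables, not variable×centre pairs.

**Sex as a modifier of the knockout effect.** Two stages: does genotype
matter at all; if so, does sex modify it. Continuous models (again
reconstructions of unreadable equation images, following the stated stage
purposes):

- Stage 1: `trait ~ genotype + sex + genotype:sex + weight + (1|batch)`
  vs the model without genotype terms (df = 2), Hochberg at 5% FDR.
- Stage 2 (stage-1 hits only): the same full model vs the model without
  the interaction (df = 1), Hochberg at 5% FDR.
- Final model: genotype nested within sex
  (`trait ~ sex + weight + genotype:female + genotype:male + (1|batch)`),
  giving directly interpretable per-sex estimates.

Categorical stages: CMH mid-p (after the MH alpha-star filter) at 5% FDR;
then, on knockout animals only (control sex differences assumed
negligible at this stage), the penalized LR of sex after the LR-KO
alpha-star filter, at 20% FDR. Stage-1 hits that fail the stage-2 filter
are classed "genotype effect with no sex effect" — they were untestable
for interaction, not evidence of one.

**Classification taxonomy** (stage-2 significant only): exactly one
per-sex interval excluding zero → *female only* / *male only*; both
excluding zero with opposite signs → *opposing directions*; same sign →
*female greater* / *male greater* by |standardized estimate|; neither →
*cannot classify*. The interval-based rule is this package's concrete
definition of boundaries the source leaves informal. Labels map exactly
under swapping the sex coding (tested).

## Synthetic data

The generator emulates the structure the analyses assume: batch-structured
accumulating controls (default 50 batches a week apart, 3/sex/batch),
knockout cohorts of 7/sex, batch deviates shared by all animals measured
on a date, residual SD 1 with batch SD 25% of it, sexually dimorphic body
weight (female 22 g, male 28 g, SD 2 g — plausible, flagged as arbitrary)
optionally feeding the trait, per-sex genotype effects, and per-sex×
genotype Bernoulli abnormality rates. Multi-batch cohort placement scales
the number of collection dates with cohort size (~5 animals/sex/date; the
canonical 7/sex cohort uses the minimal 3+2 pattern), since a batch is a
calendar date. All randomness flows from one seed through spawned
substreams, so lines are regenerable in isolation.

What generated data does *not* contain: litter/maternal-microbiome
structure, age or season covariates, non-Gaussian or autocorrelated batch
effects, QC artefacts. Consequently a green type-I-error test establishes
calibration *under the model's own assumptions*; in particular the
one-batch workflow's inflation is mild here (~0.06–0.07 at nominal 0.05)
because a correctly specified Gaussian mixed model absorbs most Gaussian
batch confounding — the dramatic one-batch failures reported on real data
need batch structure that is not exactly Gaussian. The validation suite
therefore asserts nominal calibration (within 3 Monte-Carlo SEs of 0.05)
for multi-batch and random workflows, and detectable above-nominal
inflation for one-batch.

## Validation studies

Two designs, reduced to 500 iterations by default (the original scale of
2,000 is a config change; Monte-Carlo tolerances scale accordingly):

- **Resampling**: control observations are relabelled — never redrawn — as
  mock knockout cohorts (7/sex) following a named workflow's batch
  pattern; both stages run without multiplicity adjustment; rejection
  rates are recorded over a threshold grid. "Random workflow" is uniform
  sampling of mock-knockout animals.
- **Parametric stage-2**: wildtype populations over 300 batches (batch SD
  = 0.25 × residual SD, read as an SD despite the source's mixed
  variance/SD wording), mock cohorts of 14/sex, body weight sampled from
  the wildtype female distribution, and an equal-in-both-sexes shift of
  {0, 0.5, 1, 1.5, 2} × SD added to the knockouts. A pure main effect
  leaves the interaction test's size flat across all levels (the shift
  cancels exactly in the interaction contrast).

## Known limitations

- Chi-square references for LR tests are asymptotic; with 7/sex cohorts
  the stage tests sit slightly above nominal (~0.055–0.06 measured), which
  is inherent to the method, not the implementation.
- Equations for the continuous models are reconstructions (see above);
  reproducing the published headline percentages additionally requires the
  deposited data set and matching the deposited scripts' multiplicity
  method, so exact agreement is not guaranteed by this package alone.
- The categorical pipeline assumes batch-to-batch and litter variation is
  negligible, as the source analyses do.
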