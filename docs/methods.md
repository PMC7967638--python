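# Methods

## Setting and model

The package analyses cohorts of mother–child pairs in which a rare binary
outcome (registration with a Regional Council for Children Requiring Care
by age 3; 11 of 893 in the motivating study, 1.2%) is related to
categorical questionnaire covariates from pregnancy notification forms.
All covariates are categorical, so a logistic model over K-category
variables reduces to binary dummies against each variable's reference
category, and the data enter inference only through grouped counts
(pattern, group size m_j, events y_j).

With so few events, maximum-likelihood logistic regression is biased or
divergent, and Wald intervals are meaningless.  Inference is therefore
exact and conditional: for a target dummy with coefficient β and
sufficient statistic T (events among the exposed), all other parameters —
including the intercept, whose statistic is the total event count — are
eliminated by conditioning on their observed statistics.  The conditional
law is an extended noncentral hypergeometric distribution with integer
weights c_t; in the 2×2 case c_t = C(m₁,t)·C(m₀,k−t), the classical
noncentral hypergeometric.

## Enumeration

Weights are computed by multiplying per-group generating polynomials
Π_j Σ_k C(m_j,k) u^k z^(k·x_j) in exact Python big integers, pruning
terms whose total event count exceeds the observed total.  Coefficients at
the C(834,11) ≈ 10²² scale survive unrounded; only when tilting by β are
logs taken (log-sum-exp throughout, so β = ±35 is still stable).  The cost
is governed by the total event count, not the cohort size, which keeps
the 893-subject designs at a few seconds even for the joint
six-dummy fit.  A brute-force enumerator over outcome assignments
(feasible to ~25 subjects) serves as an independent oracle and is verified
to agree exactly on randomized small designs.

## Estimates and conventions

* **CMLE**: solves E[T|β] = t_obs.  The map is strictly increasing, so a
  bracketed Brent search on β ∈ [−35, 35] (|Δβ| < 1e−10) is exact for
  practical purposes; a root at the bracket end is reported as a boundary
  with a warning.
* **MUE**: when t_obs is at the support minimum (maximum) the CMLE is
  −∞ (+∞); the median unbiased estimate solves P(T ≤ t|β) = ½
  (P(T ≥ t|β) = ½).  For interior t the midpoint of the two tail
  solutions is returned.
* **CI**: equal-tail exact inversion — lower limit from
  P(T ≥ t|β) = α/2 (exactly 0 at the support minimum), upper from
  P(T ≤ t|β) = α/2 (+∞ at the maximum).  This convention reproduces the
  motivating study's printed intervals to the printed precision,
  including the "0–U" intervals of its zero-event cells, which is how the
  (undocumented) convention of its software was adjudicated.
* **p-values**: default is the probability method — the total null
  probability of support points no more probable than the observed one —
  with a twice-smaller-tail variant exposed.  Printed evidence cannot
  distinguish the two (only a p < 0.05 bolding is published); both are
  consistent with it.
* **Degenerate support** (a single point, e.g. after conditioning on a
  perfectly collinear dummy): flagged `non_informative`, odds ratio NaN,
  never silently dropped by the fitting layer.  The pipeline excludes
  such parameters from score derivation and records them in the manifest.

## Recoding and missingness

Maternal age uses half-open bands [0,20), [20,25), [25,40), [40,∞); late
registration means notification at ≥ 12 gestational weeks (12 itself is
late); the "unexpected and not happy" feelings pool into one category.
Respondent-level missingness ("not answered") is an analysis category of
its own, folded into the reference category when fewer than 5 respondents
skipped the item (merged rows carry a "<ref>/not_answered" label).
Municipality-level structural missingness ("not investigated" — the field
was never digitized there) is constant within a (municipality, variable)
pair and is never merged.

## Risk score

Factors enter the joint model when a crude-fit category's 95% CI excludes
1 (equivalent to exact p < 0.05 under the matching convention, and
reproducible from printed output).  Adjusted ORs map to integer weights:
3 at OR ≥ 10, 2 at 5 ≤ OR < 10, 1 below 5.  The 1-point band (rather
than 0) for ORs under 5 follows the published formula's treatment of its
two sub-5 categories; ORs below 1 also get the minimum weight but emit a
warning, since weighting a protective category positively is almost
certainly not intended.  The maximum score sums each variable's largest
category weight (7 for the published formula).  Records are classified
positive at score ≥ cutoff; the default cut-off criterion is Youden's J
(ties toward the smaller cutoff), which reproduces the published choice
of 2.  Maximum raw accuracy is exposed as an alternative but is a poor
criterion at 1.2% prevalence — it picks the classify-almost-nobody
cutoff 7 on the published table.  AUC is the tie-adjusted Mann–Whitney
statistic; its CI uses the DeLong structural-components variance with a
normal approximation, truncated to [0,1] (the motivating study does not
state its method; DeLong is the field default and was cross-checked
against pROC on a fixture).

## Synthetic cohorts

The generator's defaults are the study conditions: n = 893, target
prevalence 11/893, covariate categories drawn independently from the
published marginals (with structurally missing mass removed), and five
municipalities whose masking sets reproduce the published "not
investigated" totals exactly in expectation (417/893 for marital status;
326/893 for pregnancy progress, passive smoking and disease history;
202/893 for worries/anxiety; 124/893 for infertility treatment, satogaeri
and mental-illness history).  The outcome model's default coefficients
are the logs of the published adjusted odds ratios; the intercept is
calibrated by exact enumeration of the (independent) covariates carrying
coefficients, mixed over municipalities, so the expected prevalence hits
the target.  Draw order is fixed and a single stated RNG
(`numpy.random.default_rng(seed)`) makes cohorts byte-identical across
runs with the same seed.

Limitations to keep in mind when reading green tests: real questionnaire
items are correlated (unmarried status and smoking, say) while the
generator draws them independently unless a joint sampler is supplied; the
split of merged "not answered" cells is unknowable from published
marginals and is assigned to the base category; and the published
municipality-level cross-tabs do not exist, so the assignment of masking
sets to municipalities is one convenient solution of the marginal
constraints.  Passing tests demonstrate the machinery is correct under
the stated structure, not that the structure captures every feature of
the original data.  One visible consequence: variables masked by the same
municipalities have identical "not investigated" dummies, so the joint
fit's conditional support for one of them collapses and the pipeline
drops it (flagged) — a behavior real data would rarely produce.

## Problem sizes in the validation suite

Coverage of the exact CI is checked on 500 replicate 2×2 cohorts
(100 + 100 subjects, true OR 5, 5% baseline risk): coverage must be
≥ 93% at the nominal 95%, the conservative direction expected of exact
intervals.  Parameter recovery runs 200 replicates at n = 2000 and 5%
prevalence with one true factor at OR 5, requiring near-zero median log
bias and ≥ 93% coverage.  The generating-function/brute-force equivalence
property test runs 200 randomized designs with up to 20 subjects and 3
dummies.  These sizes keep the full suite at a few minutes while leaving
each check statistically meaningful.

## What is and is not reproduced

From the published per-category counts alone the package reproduces every
crude exact OR, CI and estimate kind, and from the published adjusted ORs
the score weights and maximum score.  The adjusted ORs themselves, the
observed score distribution, the classification table and the AUC of the
original cohort depend on the unreleased individual-level joint
distribution and are reproduced structurally (on synthetic cohorts), not
numerically.
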