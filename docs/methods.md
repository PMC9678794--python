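# Methods

## Study design being emulated

The pipeline analyses a nested matched case-control study: a source
cohort of people treated for obesity is followed for incident heart
failure (HF); each incident case is matched 1:1 to a control sampled
from the case's risk set (cohort members still event-free at the case's
event time, so a later case may serve as a control first), on sex and
surgery group exactly, age within a caliper, and follow-up time
implicitly through risk-set sampling.  Baseline plasma protein panels
are screened for association with later HF.

## Synthetic cohort generator

`GeneratorConfig` defaults encode the design being emulated: 411 cases,
410 controls, a source population of 4 037, 184 assays on two 92-plex
panels, 6 assays engineered to fail the limit-of-detection (LOD) rule,
surgery in 42% of the population, and planted per-SD log odds ratios
equal (in magnitude) to the 32 published biomarker sORs, with
surgery-dependent effects for three proteins (stratum sOR pairs
1.80/1.16, 1.39/1.02, 2.26/1.14).

**Covariates.** Age, BMI, blood pressures, heart rate, creatinine,
lipids, glucose, diabetes and smoking are drawn from distributions
matching the published baseline table's scale (e.g. BMI ~ N(40.5, 4.8),
SBP ~ N(144, 19)); glucose is a diabetes-dependent mixture.

**Events.** Event times are exponential with a log-linear covariate
hazard (positive weights on age, male sex, BMI, SBP, heart rate,
triglycerides, glucose, diabetes, current smoking; negative on HDL);
censoring is administrative, uniform on 6–26 years.  Surgery has no
hazard effect, so its prevalence among cases equals the population
fraction in expectation.  The baseline hazard is calibrated by root
finding so the expected event count exceeds `n_cases` by
max(15%, 4·√n_cases), and the realized case series is thinned at random
to exactly `n_cases` — a fixed-size case series, as in a study that
enrols a predetermined number of cases.  Only the relative ordering of
event times matters to risk-set matching; a consequence of the
memoryless hazard is that events sit earlier in follow-up (mean ≈ 8–9
years) than in the real cohort (≈ 15.6 years), which affects nothing
downstream because duration enters the models linearly.

**Matching.** Cases are processed in event-time order; eligible
controls share sex and surgery, lie within ±2 years of age, are still
at risk at the case's event time, and have not been used as controls
before.  The nearest-age eligible subject is taken (ties by person id),
making matching deterministic given the population.  The age caliper of
±2 years is chosen to reproduce near-perfect age balance (matched-pair
t-test p ≈ 1).  Controls inherit the case's event time as their
`duration` covariate, since controls are adjusted for the matched
case's time to incident HF.  A case with no eligible control is
retained unmatched with a warning; additionally, matched controls are
dropped at random until `n_controls` remain, emulating controls lost to
missing plasma samples (default 411 cases / 410 controls).

**Proteins.** Expression is unit-SD Gaussian noise around per-assay
baselines, with block-exchangeable correlation (default blocks of 8 at
ρ = 0.35, a typical within-panel scale).  A planted log OR b shifts the
case distribution by b: if controls are N(μ, 1) and cases N(μ + b, 1),
the likelihood ratio is exactly log-linear in expression with slope b,
so the adjusted logistic model's coefficient per unit of within-group
SD is exactly the planted value.  Interaction proteins receive their
additional shift only in no-surgery cases.  Because the case shift adds
between-group variance, standardizing to the *pooled* SD inflates the
estimated per-SD |log OR| by √(1 + b²·p(1−p)) — about 2% at sOR 1.5,
noticeable only at the largest planted effects; recovery tests
therefore use moderate effects.  The 6 below-LOD assays are chosen
among effect-free proteins and given LODs at their 90th percentile
(> 80% of values strictly below); all other assays get LODs at the 2nd
percentile.  Values below LOD are generated, not masked: the platform
reports extrapolated values there, so the filter uses the threshold,
not missingness.

**Determinism.** The master seed spawns named substreams (population,
matching, proteins) via `SeedSequence` spawn keys, so a stage can be
regenerated without re-running the others; identical config + seed
yields byte-identical CSVs.

## What the generator does not emulate

Protein-protein correlation beyond exchangeable blocks; correlation of
proteins with the clinical covariates (in real plasma data biomarkers
track age, kidney function and adiposity, which widens standard errors
and is why the published effects of this magnitude were only
borderline-significant); assay batch effects and bridging;
missingness; BMI trajectories.  Consequently the synthetic study has a
cleaner signal-to-noise ratio than real data: with the published sOR
magnitudes planted, most of the 32 planted proteins reach the ≥ 80%
stability tier rather than the published 12/20 split.  Passing tests
demonstrate the statistical machinery is correct and calibrated, not
that real biomarker identities would be recovered.

## Association stage

Unconditional logistic regression (maximum likelihood via statsmodels)
of case status on standardized expression plus the four matching
variables — age and duration linear, sex and surgery as indicators —
exactly as the design specifies, rather than conditional logistic
regression on pairs.  Wald 95% CIs and two-sided p-values; per-protein
complete-case analysis with `n_used` recorded.  Non-convergence or
separation (non-finite or absurd standard errors, SE > 50 on the log
scale) is flagged, never silently reported.  The FDR family is all
assays surviving the LOD filter whose fit converged;
Benjamini–Hochberg is the step-up procedure (verified against a
brute-force implementation).  An `extra_covariates` hook allows
adjusting for further clinical covariates without changing the default
contract.

## Bootstrap stability selection

Default resampling unit is the matched pair (case and its control drawn
together), preserving the design's 1:1 balance; per-subject resampling
is available for sensitivity.  Expression is standardized once on the
full cohort — the sOR scale is a property of the study, not of a
resample — then B resamples are drawn from per-bootstrap substreams
seeded by (seed, bootstrap index), so results are independent of
execution order.  Single-class resamples are redrawn (limit 100, then a
hard error).  FDR is re-applied within each resample across the
converged fits; a non-convergent protein is excluded from that
resample's family and from its own denominator.  Tier semantics are
inclusive at both published boundaries: selection ≥ 0.80 → major
(published proportions of exactly 80.0/80.1% appear in the major
group), 0.50 ≤ s < 0.80 → potential.  The full design uses B = 5000;
analysis scripts and acceptance checks use B = 200, at which a planted
sOR = 3 protein is selected in every resample and Monte-Carlo error on
a proportion is below 0.04.

## Interaction screen

The interaction p-value comes from the Wald test of the expression ×
surgery product term in the pooled adjusted model; stratum-specific
sORs come from separate refits within each stratum (surgery dropped as
constant, other matching covariates retained), so stratum CIs are not
constrained by a shared covariate structure — matching the published
table's layout.  Because interaction tests are low-powered the flag
threshold is a screening α of 0.10; flagged proteins are never
described as significant at 5%.  Strata lacking both outcome classes
raise a named error.

## Power and descriptives

Power for a standard-normal predictor uses the small-effect Wald
information n·p(1−p): power = Φ(Δ − z₁₋α/₂) + Φ(−Δ − z₁₋α/₂) with
Δ = |ln sOR|·√(n·p(1−p)).  Both rejection tails are counted so that
power at sOR = 1 equals the test's size exactly; away from the null the
far tail is ≤ 10⁻⁹.  The inversion ln sOR = (z₁₋α/₂ + z_power)/√(n·p(1−p))
gives the minimum detectable effect (1.27, and reciprocal 0.79, at
n = 821, p = 0.5, α = 0.01, power 0.80).  A Monte-Carlo mode (simulate
a standard-normal predictor with the intercept solved by Gauss–Hermite
quadrature so the marginal event rate is exact, fit, count Wald
rejections) guards against the approximation at large effects.

Summary t-tests default to the Welch form (at n ≈ 411/410 with similar
SDs, Welch and pooled agree to the printed precision of every validated
row).  Fisher's exact test delegates to the standard hypergeometric
implementation for 2 × 2; for 2 × k it enumerates all tables with the
observed margins and sums conditional probabilities not exceeding the
observed table's (Freeman–Halton), with a 10⁻⁹ relative tolerance on
the probability comparison to absorb floating-point ties; a zero margin
returns p = 1 by convention.  The 2 × 3 smoking comparison reproduces
the published p = 0.011 and matches an independent conditional-
enumeration value to 7 decimals.

## Problem sizes in tests

Unit tests use 60-pair cohorts with 12 assays.  Calibration and
recovery checks use 100–500 replicate cohorts of 75–200 pairs, chosen
so binomial Monte-Carlo error is small against each tested margin, and
one full-size run (821 subjects, 184 assays, B = 200).  The whole suite
runs in a few minutes on one core.

## Known limitations

No conditional-logistic option; no penalized or multi-protein models;
no mediation of weight change (surgery and weight loss are collinear by
design); the generator's clean noise model overstates power relative to
real plasma panels, as discussed above.
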