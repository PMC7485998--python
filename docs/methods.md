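# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `tweethood`.

## The estimand and the models

The scientific object is the association between a zone-level (zip-code-like)
social-environment exposure and an individual cardiometabolic outcome.
Exposures are the per-zone percentages of tweets that are happy, mention
physical activity, mention healthy food, or mention fast food, categorized
into tertiles over zones (tertile 1 = lowest = reference). Outcomes are BMI
(continuous) and obesity, hypertension, and diabetes (binary).

For BMI the model is survey-weighted least squares:

    E[BMI] = β0 + β2·T2 + β3·T3 + γ'x

with T2/T3 the tertile indicators and x the adjustment set: age, sex,
race/ethnicity, household-income band, and four masked zone covariates
(percent non-Hispanic white, log median household income, population
density, median age). Weighted WLS solves (X'WX)β = X'Wy; the covariance is
the HC0 sandwich A⁻¹BA⁻¹ with A = X'WX and B = Σᵢ wᵢ²eᵢ²xᵢxᵢ'. The weights
are sampling weights in the estimating-equation sense (the score is
wᵢeᵢxᵢ), which is the convention `statsmodels`' `var_weights` uses; the
tests cross-check against it.

For binary outcomes the model is modified Poisson regression: log-link
Poisson estimating equations applied to 0/1 data, so exp(β) is a prevalence
ratio rather than an odds ratio. Estimation is IRLS with working weight
wᵢμᵢ, convergence at max|Δβ| < 1e-8 (cap 100 iterations; non-convergence
raises with the step trace). The sandwich variance (A = X'diag(wμ)X,
B = X'diag(w²(y−μ)²)X) is not optional: the Poisson model-based variance
over-states the variance of binary data by the factor 1/(1−μ), and the
direction of that inflation is asserted in the tests. CIs are
exp(β ± 1.96·SE) — large-sample normal quantiles throughout.

On a single binary predictor the fitted PR equals the weighted prevalence
ratio p̂₁/p̂₀ in closed form (to 1e-6 in the tests), which is the oracle
anchoring the implementation.

**Survey design simplification.** The original design-based analyses used
stratum/PSU linearization; those design variables are not reproducible
outside a restricted data center, so this package uses weighted estimating
equations with an HC0 sandwich instead. Under the generator (individuals
sampled independently within zones, outcomes independent given the modeled
terms) this is the correct variance; on real complex-survey data it would
understate design effects from clustering within PSUs. Documented
limitation, out of scope by design.

**Missingness** is handled by listwise deletion per model, so the analytic
n varies across models; no imputation. No multiple-testing adjustment is
applied — one unadjusted CI per model cell, matching how such results
tables are conventionally reported.

## Tweet classification

*Sentiment.* A multinomial naive-Bayes classifier with Laplace smoothing
(α = 1) trained on a labeled happy / not-happy corpus. The happiness score
is the posterior probability of the happy class computed in log space;
out-of-vocabulary tokens carry no evidence and an empty token set returns
the prior. A tweet is happy iff score > 0.8, strictly — the threshold is
configurable but 0.8 is the operating point used throughout. The original
pipeline used a trained MALLET classifier; a naive-Bayes posterior fills
the same contract (a calibrated [0,1] rating with a fixed cut), and exact
score reproduction of MALLET is explicitly not attempted. Whether the
published 0.8 cut applied to a probability or an uncalibrated rating is not
stated in the source; it is treated here as a posterior probability.

*Lexicon matching.* Food and physical-activity flags come from
longest-match-first phrase matching over tokenized text (multi-word phrases
as token runs), case-insensitive and word-bounded, so a lexicon containing
both "green beans" and "beans" matches "green beans" once. Flags are
independent: a tweet can be both healthy- and fast-food. Physical-activity
matching applies three rules in order: (1) exclusion idioms ("running
late", "walk away", "home run", …) veto only the activity term they embed;
(2) any spectator verb (watch/attend forms) vetoes the whole tweet; (3) a
team-sport phrase counts only when a play-form (play/plays/playing/played)
is present. Rule 2 is tweet-wide because the source rule excludes *tweets*
containing those verbs; rule 1 is phrase-local because idioms only poison
their own term.

*Preprocessing.* Exact duplicates (whitespace-normalized, lowercased text,
across all users) and job postings (blocklisted hashtags; default {job,
jobs, hiring, careerarc, nowhiring}, configurable) are removed before
classification. Deduplication scope and the job-post blocklist are not
specified in the source; both choices are configurable.

*Tokenization.* Lowercase; URLs stripped; '#' stripped from hashtags (word
kept); punctuation-delimited. The sentiment tokenizer drops @-mentions as
noise; the lexicon matcher keeps the handle word ('@' stripped) because
brand mentions like "@starbucks" are topical signal. Whether the original
matching ran on raw or normalized text is unstated; normalized is used
here.

*Default lexicons.* ~120 packaged phrases (food tagged healthy/fast/other;
PA with team-sport flags) plus exclusion idioms, shipped as TSV and fully
user-replaceable. The original lists (1,430 food words; 376 PA items) are
not public; the packaged defaults are a working vocabulary, not a
reconstruction.

## Geography

Zones are polygons with stable ids (GeoJSON in/out). Point-in-polygon is
even-odd ray casting in planar lon/lat — at zip-code scale the planar
approximation's curvature error is far below coordinate noise — with
boundary points counted inside, so edge tweets are never silently dropped;
an independent winding-number implementation is the test oracle.
Overlapping zones resolve to the first zone in stable order (warned).
Tweets outside all zones are counted and reported, never imputed.

Zone percentages use all assigned tweets as the denominator. Zones with
fewer than a configurable minimum of tweets (default 1, i.e. any tweet
qualifies) get undefined percentages and are excluded from tertile cutting.
Tertiles are rank-based thirds with stable-order tie-breaking (group sizes
differ by ≤1); they are computed over all zones with defined exposures by
default, with a switch to restrict to linked zones (the source is silent on
which population defined its cutpoints).

20-quantile masking replaces each continuous zone covariate with the median
of its rank-based vigintile (log of the median for income). The transform
is rank-preserving and produces at most 20 distinct levels; masked
covariates enter the models as continuous values.

## The synthetic-data generator

The generator emulates the study's inputs at desk scale with knowable
ground truth; its defaults are the packaged study conditions.

*Zones and tweets.* Rectangular zones tiling a unit extent (real GeoJSON
polygons are equally accepted downstream). Tweets per zone are negative
binomial (default mean 200, dispersion 5 — the tweets-per-zone distribution
is not published; a negative-binomial default is assumed and configurable).
Each tweet's category (happy, unhappy, neutral, healthy/fast/other food,
physical activity, PA decoy, job post) is drawn from the zone's mixture;
text is assembled from templates plus a neutral filler and a random number,
so the true category of every tweet is knowable and near-duplicates are
rare; explicit duplicates (2%) and job posts (1%) are injected to exercise
preprocessing. Decoy templates contain only excluded expressions
("running late", spectator verbs, team sports without "play").

The unhappy/neutral templates intentionally share the happy templates'
function-word profile (and/for/so/with/my/today), so that only sentiment
words discriminate the classes. Without that balance, naive Bayes learns
stopwords as sentiment evidence and over-calls happiness on out-of-topic
tweets — an artifact of template corpora that real training corpora do not
share.

*Zone rates.* Per-zone true category rates are beta-distributed with means
matching the observed national zone-level averages (happy 19%, PA 2.2%,
healthy food 1.0%, fast food 0.3%, other food 3.7%) and between-zone SDs
(0.05, 0.015, 0.007, 0.002, 0.015) chosen to reflect the strong dispersion
of real zone-level shares. Explicit per-zone rate vectors can be supplied
instead.

*Population.* Individuals are assigned to zones uniformly; age ~ U(20, 80),
sex, race/ethnicity, and income band follow the weighted survey margins;
sampling weights are lognormal(0, 0.5) — mimicking unequal examination
weights without claiming realism. BMI is baseline 29.1 plus tertile and
covariate effects plus N(0, 6) noise. Binary outcomes are Bernoulli with
log-link probability p = baseline·exp(tertile log-PRs + covariate effects),
so the modified-Poisson estimand equals the generating PR exactly;
configurations implying p > 1 for any individual are rejected at
construction (worst-case bound) and again before sampling — never silently
truncated.

*BMI/obesity coupling.* Obesity must equal BMI ≥ 30 in any coherent
dataset, so BMI cannot follow a free linear model while obesity follows an
independent log-link Bernoulli. The generator therefore has two regimes:
`bmi_mode="linear"` (default) generates BMI from the linear model and
derives obesity from it (the obesity channel may carry no effects), and
`bmi_mode="obesity_coupled"` draws obesity log-linearly and constructs BMI
from the same latent uniform — BMI = 30 + σ(Φ⁻¹(p) − Φ⁻¹(U)) — so the
threshold identity holds individual by individual while P(obesity) = p
exactly (BMI tertile effects must be zero). BMI-effect recovery uses the
first regime; obesity-PR recovery the second.

*Raw measures.* Weight/height encode BMI (weight nudged by ≤1e-6 kg/m² in
the rare float case where the threshold identity would flip); hypertensive
individuals are medication-only (30%) or have elevated paired BP readings
(means drawn ≥2 mm Hg clear of the strict cuts, readings m±d so the mean is
exact); diabetic individuals split between self-report with normal HbA1c
and HbA1c ≥ 6.6%. Applying the outcome definitions to the raw measures
reproduces the intended flags for 100% of individuals — a tested
round-trip invariant.

*Packaged scenarios.* "subcohort" (1,384 zones, 17,048 individuals) and
"full cohort" (2,116 zones, 29,201 individuals), mirroring the two analytic
samples, with default effects equal to the published happy-tweet contrasts.

*What the generator does not emulate:* realistic language, temporal or
network tweet structure, informative missingness, nonresponse weighting,
confounding by covariates (covariates are independent of zone exposures, so
adjusted and crude effects coincide in truth). Passing recovery tests shows
the estimators are calibrated under a correctly specified generating model
— not that the original observational estimates are unbiased.

## Parameter recovery and its tolerances

The headline check simulates 50 independent subcohort-scale studies per
target with the generating effect set to a published adjusted estimate
(happy T3 → BMI −0.85 kg/m²; PA T3 → hypertension PR 0.90; healthy food T3
→ obesity PR 0.88; happy T2 → hypertension PR 0.92), refits the matching
adjusted weighted model each time, and compares the mean fitted contrast to
the truth (tolerance ±0.15 kg/m² for BMI, ±0.03 on the PR scale). Robust
95% CI coverage must lie in [90%, 98%]; because a coverage proportion from
50 replicates has ~3% binomial error (49/50 is the only passing value above
96%), the coverage rate is estimated over 200 replicates — same band,
smaller Monte-Carlo error — while the mean-recovery protocol keeps 50.

## Numerical and degenerate-case notes

- Tertile and vigintile grouping are rank-based with stable-order ties;
  constant vectors split into near-equal groups (documented, tested).
- `quantile_mask` with n < q degenerates to one value per group (identity).
- IRLS linear predictors are clipped to ±30 before exponentiation to avoid
  overflow in early iterations; convergence is unaffected.
- Boundary behavior is exact and mixed by design: obesity and HbA1c cuts
  inclusive (≥), blood-pressure cuts strict (>), happiness strict (>).
- Rank-deficient designs raise with the names of collinear columns; empty
  post-deletion samples and constant columns raise rather than fit.

## Known limitations

- Tertile recovery from tweets is resolution-limited for rare categories:
  at 10,000 tweets/zone the binomial SE of a zone share is ~0.0015 for PA
  and ~0.0005 for fast food, comparable to the spacing between zones near
  tertile cutpoints, so some boundary zones are inevitably misassigned
  (≈8% for PA, ≈15–20% for fast food) even though the measured shares are
  exactly the ground-truth shares of the surviving tweets. This is
  irreducible measurement noise, not implementation error; the happy
  characteristic (19% mean, wide spread) recovers ≥95% of zones.
- No stratum/PSU design variance (above).
- English-only, template-scale lexicons; no sarcasm or humor handling.
- The modified-Poisson fitter targets binary outcomes only; it is not a
  general Poisson count model.
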