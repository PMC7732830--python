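# Methods notes

This note documents the models implemented in `painbalance`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Combined sensation scale

Warmth (0–100) and pain intensity (0–100) ratings are merged onto a single
0–200 continuum by offsetting pain ratings by the warmth span: warmth r ↦ r,
pain r ↦ 100 + r. The mapping is order-preserving across the warmth/pain
boundary and places the pain threshold exactly at 100. All downstream
analysis operates on the combined scale; pain unpleasantness is out of
scope.

## Adaptation correction and stimulus–response curve

A calibration session applies 28 stimulations: temperatures
{40, 44, 45, 46, 47, 48, 49} °C, each once to each of four volar-forearm
sites, in a pseudorandom Latin-square-style order. The rating model fitted
jointly by bounded nonlinear least squares is

    rating = g·max(0, T − T₀)^γ                       (power-law curve)
           + S·(1 − exp(−k/τ))                         (sensitization)
           + Hₐ·exp(−λ·(r − 1))                        (habituation)
           + ε,

where k is overall presentation order (1–28) and r the repeat count at the
stimulated site. The exact parameterization of the published dynamic
order/site correction is not printed anywhere we can consult, so this
additive form — one saturating site-nonspecific component plus one
per-site decaying component, matching the described qualitative structure —
is our documented stand-in. The correction is **reference-preserving**:
corrected = raw − [adaptation(k, r) − adaptation(1, 1)], so the first
presentation at a site's first visit is untouched and any constant part of
the adaptation (which is not identifiable from the curve's intercept)
cancels exactly.

Numerical choices: three starts (including a zero-adaptation start and a
log–log heuristic for the curve), bounds T₀ ∈ [30, 48] °C, g ∈ (0, 300],
γ ∈ [0.1, 5], τ ∈ [0.5, 100] trials, λ ∈ [0, 10]; tolerances 1e−10; ties
broken by lowest residual. If no start converges, raw ratings pass through
with `converged=False` and a warning. Amplitude and time constant of the
sensitization trade off along a flat ridge when τ is large (the saturating
curve degenerates to a line), which bounds the precision of amplitude
recovery at session length 28; the correction itself is insensitive to this
because only differences of the adaptation enter it.

The curve is fitted on the combined scale (a single fit, not separate
warmth/pain fits) to avoid flooring at the pain threshold. Corrected
ratings below 0 are retained unclipped for fitting: clipping would bias the
curve near threshold. Inversion T(s) = T₀ + (s/g)^{1/γ} yields the Warm
(s = 80), threshold (s = 100) and Pain (s = 140) temperatures; a predicted
Pain temperature above the 49 °C safety cap is reported as 49.0 with
`capped=True`. Identification requires the ratings not to saturate the
200-point ceiling; subjects who rate 49 °C at the scale maximum have
partially unidentifiable curve parameters (their derived temperatures are
still well-defined because all three targets lie below the ceiling).
Whether the original correction was estimated per subject or pooled is not
recoverable; it is estimated per subject here.

## A statistic and the task engine

Per-trial performance is the non-parametric A: the average of the areas
under the minimum-area and maximum-area proper (concave) ROC curves passing
through the single operating point (F, H). The implementation is the
piecewise closed form

    A = 3/4 + (H−F)/4 − F(1−H)            for F ≤ 1/2 ≤ H
    A = 3/4 + (H−F)/4 − F/(4H)            for F ≤ H < 1/2
    A = 3/4 + (H−F)/4 − (1−H)/(4(1−F))    for 1/2 < F ≤ H,

verified in the test suite against an independent geometric construction
(exact shoelace areas of the min/max proper-ROC polygons) on a full grid.
A(H=F) = 0.5 and A(1, 0) = 1. Below-chance points (H < F) are defined by
symmetry, A = 1 − A(F, H), and flagged. Edge rates H, F ∈ {0, 1} use the
raw rates — A is finite there, unlike d′ — with no continuity correction.
Missing responses are scored as non-"same" (a miss on targets, no false
alarm elsewhere).

Sequences use 8 letters; round(0.25·(n−2)) targets (2-back repeats,
excluding two burn-in letters) and round(0.125·n) lures (1- or 3-back
repeats that are not 2-back repeats) are placed at random eligible
positions; every remaining letter is drawn to be neither. Because the
counts are deterministic per length, the nominal 25% target rate holds as
an average over the achievable lengths 6–26, not at each length. An
independent label auditor re-derives all labels from the letters alone.

Item count per 20-s trial is floor(20000 / (750 + interval)) — 750 ms of
fixation + letter per item plus the blank interval — giving 6 letters at
the slowest speed (2583 ms) and 26 at the fastest (19 ms).

### Staircase

18 trials, starting interval 2583 ms, bounds [19, 2583] ms. If A exceeds
0.85 on two consecutive trials since the last adjustment the interval is
multiplied by 0.75; below 0.75 on two consecutive trials, by 1.33
(non-overlapping windows: a step resets the counter). The step sizes are
not recoverable from the paradigm description; multiplicative steps suit
the two-decade interval range and are configurable.

The simulated observer population answers each letter correctly with
probability p(i) = 0.5 + 0.47·σ((ln i − ln θ)/0.55), with thresholds θ
log-normal (median 550 ms, log-sd 0.4) chosen so that the resulting final
intervals resemble a human sample (observed median ≈ 600 ms against a
target mean of 579 ms, SD 346 ms). Across 200 observers the mean A over
the final four trials is ≈ 0.81, inside the 0.75–0.85 calibration band.
Note a structural property: at band-level accuracy with ~14 letters per
trial, a single trial's A has binomial standard deviation ≈ 0.17, so a
four-trial mean has sd ≈ 0.085 against a band half-width of 0.05 — *no*
observer model can make the per-run four-trial mean fall inside the band
much more than ~45% of the time, even though the staircase is centred in
the band. The calibration level is a population quantity.

## Synthetic cohort generator

The generator defines the study conditions for every statistical test.

* **Traits.** (PCS, STAI-T, 4-FFMQ) are a trivariate normal with means
  (14.02, 39.34, 103.22), SDs (10.69, 10.13, 17.20) and correlations
  (PCS–STAI 0.43, PCS–FFMQ −0.59, STAI–FFMQ −0.66), clipped and rounded to
  the printed ranges (0–52, 20–80, 32–160). Clipping shifts the PCS mean
  up by ≈ 0.5 points (left tail at 0); tests tolerate this.
* **Latent psychophysics.** T₀ ~ N(41.5, 1) °C, g log-normal(ln 25, 0.3),
  γ log-normal(ln 0.9, 0.15), chosen so the implied pain thresholds and
  Warm/Pain temperatures match the published calibration descriptives
  (threshold ≈ 46.2 ± 1.2 °C). Sensitization S ~ N(8, 3) rating units with
  τ ≈ 8 trials; habituation Hₐ ~ N(10, 4) with decay ≈ 0.7/repeat; rating
  noise sd ≈ 5.
* **Behavioral sessions.** One fixed pseudorandom 36-trial condition order
  (9 per task × heat cell) shared by all subjects. A per-trial latent
  attention-allocation variable z ~ N(0, 1) drives both channels:
  sensation = cell mean + 15·z + noise (cell means 116.17 / 129.85 /
  37.74 / 49.09 matching the published condition table), and per-letter
  accuracy p = p_base + w·0.15·z with subject coupling slope w ≤ 0
  (default −0.35). w steepens by 0.12 per SD of PCS and STAI-T and
  flattens by 0.12 per SD of FFMQ (`moderation_strength`); these
  magnitudes are calibrated to reproduce signs and orderings of the
  moderation effects, not any published coefficient value, which is not
  identifiable from print.
* **Scores.** Since the simulated observer answers letters independently,
  hit and false-alarm counts are exactly binomial; the default path samples
  the counts directly, and `letter_level=True` builds full sequences and
  responses through the task engine — the two are distributionally
  identical. A `continuous_scores` switch replaces sampled counts by their
  expectations for noise-free checks.
* **Seeding.** One cohort seed fans out deterministically to per-subject,
  per-stage streams (`SeedSequence(entropy=seed, spawn_key=(subject, stage))`),
  so any single subject's data can be regenerated in isolation.

The generator emulates the design's statistical structure, not its
mechanics: no reaction times, no within-trial dynamics, no pain
unpleasantness, no post-error processes, and sensation cell means are
injected directly rather than produced by a thermoregulatory model.
Passing tests therefore demonstrate that the analysis chain recovers the
structure it assumes — not that the paradigm's psychological claims hold in
real data.

## Multilevel mediation

A two-stage summary-statistics estimator, organised as a Model/Results
pair (`MultilevelMediation` → `MediationResults`):

1. **Within subject.** Trials are filtered to the model's subset (2-back
   trials for pain interference; painful trials for task analgesia). The
   binary predictor is effect-coded −0.5/+0.5 and standardized; mediator
   and outcome are z-transformed within subject (sample SD) on the filtered
   subset. OLS gives a (M ~ X), b and c′ (Y ~ X + M), c (Y ~ X), ab = a·b;
   the decomposition c = c′ + ab holds to machine precision per subject.
   Subjects with fewer than 4 usable trials, constant variables, or an
   X-collinear mediator are skipped with a logged reason.
2. **Across subjects.** The population estimate of each path is the
   unweighted mean (no precision weighting — first-level uncertainties are
   not propagated, a documented simplification). Inference resamples
   subjects with replacement: bias-corrected (BC, not BCa) percentile
   intervals, with z₀ from the fraction of bootstrap draws below the
   observed mean, and two-sided p-values from the BC-adjusted bootstrap
   CDF. A degenerate (zero-variance) bootstrap distribution takes an exact
   branch (p = 1 when the estimate is 0). Monte-Carlo checks in the test
   suite put the type-I error of the ab test at ≈ 5–6% and the CI coverage
   of the a path at ≈ 93–94% for cohorts of 41 subjects.
3. **Moderation.** Each trait is residualized once against the
   session-interval, pain-threshold and task-speed covariates
   (OLS with intercept), standardized, and correlated with each subject's
   path coefficients; the standardized second-level slope equals the
   Pearson correlation. p-values use the same subject-resampling BC
   bootstrap on (path, moderator) pairs; the residualization is not redone
   inside each resample. The ab moderation regresses the per-subject
   product aᵢ·bᵢ on the moderator (the product of moderated paths is not
   testable per subject). **Sign convention:** positive b₂ means the b
   path becomes more positive as the moderator increases; under the
   generator's defaults, the b₂ for pain catastrophizing is therefore
   negative (steeper trade-off). No multiple-testing correction is applied.

Within-subject z-scoring makes all results invariant to affine rescaling
of the raw sensation and performance measures and to subject ordering.
Note that standardized b paths can exceed 1 in magnitude: most mediator
variance in the pain-interference model is carried by heat level, so a
within-heat-level coupling is amplified when expressed per full mediator
SD.

## Descriptives and exclusion

MTA = mean sensation(Pain × LR) − mean sensation(Pain × 2-back);
MPI = mean A(Warm × 2-back) − mean A(Pain × 2-back). Paired contrasts use
t-tests with Cohen's d = mean difference / SD of differences; the LR vs
2-back performance contrast uses the Wilcoxon signed-rank test with
r = |z|/√n. Quartile slopes average the b path (and its regression
intercept) over the quartile_n = round(n/4) highest- and lowest-scoring
subjects on a moderator, with deterministic tie-breaking by subject id and
a flag when ties straddle the boundary. Reverse-keyed item indices for
STAI-T and the 4-facet FFMQ are instrument metadata not derivable from the
analysis itself; the shipped defaults are editable constants.

Participant exclusion drops subjects with >50% missing trials, >50% of
painful trials not tolerated, or chance-level 2-back session performance
(mean A ≤ 0.5); every dropped subject carries a reason code in the run
manifest. Behavioral-session ratings are not re-run through the adaptation
correction in the pipeline: the behavioral site/order design is
unspecified, and the within-subject z-transform absorbs monotone session
drift (a limitation for non-monotone drift).

## Problem sizes

Monte-Carlo checks in the test suite use cohorts of 41 subjects (200
cohorts for sign/pattern checks; 1000 cohorts with 2000 bootstrap samples
for the type-I error of the ab test), 200 staircase observers, 100-seed
parameter-recovery loops for the psychophysics, and a 200-subject cohort
for path recovery against a 300 × 50,000-trial direct-simulation oracle of
the generative equations. Release-quality mediation runs default to 10,000
bootstrap samples.

## Known limitations

* The adaptation correction is a documented stand-in for an unpublished
  dynamic model; only its qualitative structure is matched.
* First-level estimates enter the second level unweighted.
* The generator's coupling and moderation magnitudes are sign-calibrated,
  not magnitude-calibrated; published coefficient values are not targets.
* The left–right control task is scored through the same signal-detection
  interface (left arrows as signals) without a difficulty manipulation.
* Staircase step sizes and the original second-level weighting scheme are
  unrecoverable from the paradigm description; both are configurable or
  documented choices here.
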