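# Methods

## The problem and the model

In a multiple-response speed–accuracy-tradeoff (MR-SAT) listening task, a
participant hears a sentence and judges its acceptability at every tone of a
train of response tones — here 15 tones every 350 ms, beginning 200 ms
before the onset of the sentence-final critical word, spanning a 5000 ms
response period.  Until a decision is reached the participant holds both
response keys; afterwards they hold YES or NO and may switch at any tone.
Sampling accuracy at every lag traces the full time course of information
accrual, which is what separates *how available* a memory representation is
from *how fast* it is retrieved.

Accuracy at each lag is summarised as the bias-controlled sensitivity
d′ = z(hits) − z(false alarms), and its time course is modelled as an
exponential approach to a limit:

    d′(t) = λ (1 − exp(−β (t − δ)))   for t > δ,   else 0

with asymptote λ (d′ units; representation quality/availability), rate β
(1/s) and intercept δ (s; the time accuracy first departs from chance).
β and δ jointly measure retrieval speed.  The scientific question is carried
by *parameter sharing* across the three sentence constructions (no
interpolated material; an interpolated object relative clause; interpolated
object + subject relative clauses): direct-access retrieval predicts
condition-dependent asymptotes with condition-invariant speed once any
retrieval is required — the 3λ-1β-2δ model — whereas a serial search
predicts distance-dependent speed (a third β or δ group).

## Scoring conventions

* Tone windows are half-open `[t_k, t_{k+1})`; the key state is sampled at
  each tone onset (a key released exactly at a tone is not held).  Event and
  tone times are compared at microsecond tolerance so rounded on-disk
  timestamps preserve the boundary convention.
* Per lag, YES scores 1, NO 0, and a both-press ("undecided") 0.5 toward the
  yes-rate; no-key lags are missing data, excluded from the denominator.
  The 0.5 credit is what produces the ≈50% correct-rejection rates observed
  at early, undecided lags.
* Hit and false-alarm rates are clipped to `[1/(2N), 1 − 1/(2N)]` for cell
  size N, so d′ is always finite and bounded by `2 z(1 − 1/(2N))`.
* The "averaged data" curve pools yes-credit and trial counts across
  participants *before* the z-transform (count pooling); a mean-of-d′
  alternative is available via `average_method="mean"`.
* The empirical asymptote is the mean of a curve's last four d′ values.
* Control-anomaly trials (the anomaly inside the interpolated clause) never
  enter d′; they are summarised as correct-rejection profiles, split into
  the control group and its construction-matched sentence-final-anomaly
  group.
* Model fitting uses the 14 post-onset lags by default (lag 1 precedes the
  critical word), configurable via `fit_lags`.

## Fitting

The objective is unweighted least squares over conditions × included lags
(inverse-variance weighting is available by adding a `weight` column).
Estimation runs a portfolio of bounded optimizers — by default L-BFGS-B,
Powell, TNC and Nelder-Mead through `scipy.optimize.minimize`, the
gradient-based members using the model's analytic gradient — each from 10
uniform-within-bounds seeded starts plus one deterministic data-informed
start (empirical asymptotes for λ, the observed 20%-rise time for δ, a
mid-range β).  The best run (lowest SSE; ties to fewer iterations, then run
order) is polished by a tight-tolerance L-BFGS-B step.  Fits are
deterministic given (data, spec, config): bit-identical results across
reruns.  Default boxes: λ ∈ [0, 6] d′, β ∈ [0.05, 6] s⁻¹, δ ∈ [0, 3] s.
An optional λ floor of 0.4 d′ reproduces the exactly-0.400 boundary
asymptotes seen in published per-participant fits.

Validity flags: `asymptote_overestimated` when a fitted λ exceeds its
condition's empirical asymptote by more than 1.0 d′ or sits at the upper
bound; `at_bound` when any parameter is within 1e−3 of its box.  Flagged
participants are reported as exclusions in model comparison, and are
excluded by default from the group-level fitted-parameter analyses —
mirroring the convention of analysing only participants a model can fit
without overestimating their asymptotes.

Simulation-scale studies in the test-suite use a reduced portfolio (10
gradient-based L-BFGS-B restarts plus the informed start); against a 60-run
reference portfolio the worst SSE excess across a full cohort ladder was
0.045.

## Model comparison and selection

Fit quality is the parameter-adjusted R²,
`1 − [SS_res/(n−k)] / [SS_tot/(n−1)]`, with k the number of λ/β/δ groups.
Nested pairs are compared by ΔadjR² per participant and for the averaged
data.  The preferred-model rule: an added parameter is accepted iff the
averaged-data ΔadjR² exceeds 0.005 *and* a majority of non-excluded
participants improve; among the models surviving this closure the
fewest-parameter model wins, ties between equally sized speed
parameterisations going to the intercept (δ) — the conservative choice when
rate and intercept effects are empirically indistinguishable.  All
constants are config-exposed.

## Group-level inference

Per-participant quantities (empirical asymptote, fitted λ/β/δ per
condition) are analysed with a linear mixed model with random intercepts
for participants (statsmodels `MixedLM`, REML), fixed effects of
Construction and, when requested, standardized receptive-vocabulary ability
and its interaction.  Each fixed effect is reported as a Wald F with a
Satterthwaite-approximated denominator df.  For the balanced
random-intercept designs this package produces, the Satterthwaite df reduce
exactly to the classical repeated-measures values — (J−1)(n−p_between) for
within-subject effects and n−p_between for between-subject effects, with
p_between the between-subject model dimension including the intercept —
and that closed form is what is implemented (verified against a direct GLS
computation in the tests).  Single-df effects use the field's |t| > 2
significance convention; pairwise condition contrasts are paired t-tests on
per-participant values, with a constant nonzero difference reported as an
infinite-t sentinel flagged degenerate.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
the acoustics: per participant and construction a latent exponential d′
curve; equal-variance SDT responding at each tone with symmetric criterion
placement, P(YES | acceptable) = Φ(d(t)/2 − c) and
P(YES | unacceptable) = Φ(−d(t)/2 − c), which inverts exactly to d′; BOTH
emitted deterministically while d(t) = 0 (an optional log-normal decision
delay adds timing jitter, off by default); optional momentary response
flips (`switch_prob`, default 0 — the binomial SDT draw is the default
noise).  Control-anomaly trials follow a curve with asymptote scaled by
0.8, so their correct rejections grow exponentially but below the
experimental conditions.

Cohort defaults are the community-cohort study conditions: 22 participants;
48 trials per sentence type each (all four 96-item lists over four
sessions, 12 instances of each of the 8 types per list); generating truth =
that cohort's averaged-data 3λ-1β-2δ estimates (λ 2.690/1.482/0.834,
β 0.779, δ 1.266/1.579); vocabulary ability ~ Normal(96.41, 13.60)
truncated to [74, 128], standardized, shifting the asymptote only at 0.3 d′
per SD; between-participant heterogeneity as one shared asymptote shift
(sd 0.3 d′), a log-normal rate factor (sd 0.25) and a shared intercept
shift (sd 0.2 s), chosen to mirror the spread of published individual
estimates.  All randomness derives from one root seed with substreams keyed
by (seed, participant, trial), so enlarging a cohort never reshuffles
existing trials.

What the generator does *not* emulate: acoustic/lexical item variability,
serial dependence within a trial's responses (lags are conditionally
independent given the latent curve), attention lapses, and learning or
fatigue across sessions.  Passing tests therefore show that the analysis
pipeline recovers the structure it assumes; they do not certify behaviour
on real response streams beyond that structure.

## Simulation studies and what they show

* **Round-trips.** Noiseless curves generated from each published
  averaged-data parameter row refit to the generating values to three
  decimals — the fitting stack is exact where exactness is possible.
* **Recovery and selection** (100 cohorts, 22 participants, 12 trials per
  cell): generated from the university-cohort averaged row (δ gap 0.392 s,
  the clearly separated two-intercept case); the averaged-data 3λ-1β-2δ
  fit recovers λ with median absolute error ≈ 0.10 d′ and δ ≈ 0.08 s, and
  the ladder-plus-consistency rule returns the generating model in ≈ 92% of
  cohorts.  Under the community-cohort row the same rule is *not* expected
  to be this consistent: that row's noiseless averaged-data ΔadjR² for the
  second intercept is 0.0064, essentially at the 0.005 acceptance
  threshold — matching the original report, where the community cohort's
  improvement was 0.005 with four non-improving participants and the
  two-intercept model was preferred on significance tests rather than
  ΔadjR² alone.
* **Ability signature** (100 default cohorts): ability enters the generator
  on λ only.  With asymptote-flagged fits excluded, the mixed-model
  analysis flags Ability on the fitted-λ table in 86/100 cohorts at slope
  0.3 d′/SD and stays at 5/100 on the fitted-δ table — but shows a 17/100
  false-positive rate on the fitted-β table, well above nominal.  The β
  inflation is a property of per-participant nonlinear estimation, not of
  the mixed-model wrapper (which is calibrated on clean tables — see the
  label-shuffle test): with β(t_max − δ) ≈ 2.7 the curve
  reaches only ~93% of asymptote within the response period, so λ̂ is
  partly an extrapolation (per-participant sd ≈ 0.5 d′, ~1.5× the
  information bound), and β̂ carries a small-sample bias that shrinks as a
  participant's signal-to-noise ratio — and hence ability — rises.
  Consumers of per-participant speed estimates at this trial count should
  treat small ability effects on β̂ with suspicion; the published ability
  effect on λ̂ (F ≈ 50 at n = 22) corresponds to a slope near 0.7 d′/SD,
  large enough to clear this noise floor comfortably.

## Numerical and degenerate-input choices

* Identically-zero curves fit cleanly (λ at the lower bound, SSE 0) with an
  undefined adjusted R² reported as NaN rather than an error.
* The SAT function is exactly 0 at t ≤ δ and continuous at δ; points below
  the intercept contribute zero gradient.
* Adjusted R² requires n > k and non-constant observations; violations
  raise typed errors.
* Per-(unit, model) fit seeds are derived by stable hashing from the root
  seed, so ladders are reproducible and order-invariant; pipeline stages
  derive their seeds the same way.
* All floating output is written at 6 significant digits for diffability;
  reruns with the same manifest are bit-identical.

## Known limitations

* No standard errors or bootstrap for SAT parameters; uncertainty is
  addressed at the cohort level.
* No information-criterion (AIC/BIC) selection; the comparison framework is
  adjusted R² plus consistency.
* Per-participant speed estimates are bias-prone at realistic trial counts
  (see above); hierarchical/shrinkage estimation would help and is out of
  scope.
* The mixed-model Satterthwaite df use the balanced-design closed form;
  strongly unbalanced tables fall outside its guarantee.
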