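# Methods

## Scoring model

All scoring is baseline-to-peak on windows expressed in seconds relative to
stimulus onset.  Windows are half-open `[start, end)` so the onset sample is
counted once; "the 1-s interval immediately preceding onset" is `[-1, 0)`.

**Loud tones (15 trials).**  Per trial and channel the response is the
search-window maximum minus the pre-stimulus baseline mean: eyeblink EMG
peak within 40–200 ms, SC and HR peak within 1–4 s, with 1-s pre-stimulus
baselines for the sampled channels.  Heart rate is derived from interbeat
intervals (HR = 60000/IBI ms); the HR baseline is the mean HR of the two
beats whose R-events immediately precede onset, and the HR peak is the HR of
the shortest interval whose terminating beat falls in the search window.  A
signed square-root transform `sign(x)·√|x|` is applied to response scores:
the plain square root would be undefined for the negative raw responses that
decelerations produce, and the odd extension preserves order and the skew
reduction.  Habituation is summarized two ways: *absolute* — the number of
trials before the first pair of successive non-response trials
(SC < .05 µS, EMG < .30 µV, on raw scores in physical units), scored 0 when
trials 1–2 already qualify and capped at 15 when the criterion is never
reached — and *relative* — the OLS slope of the transformed response on the
natural-log trial number, trials 2–15 only (trial 1 is excluded by
definition; the log base only rescales the slope).  Session means average
all 15 trials.

**Differential conditioning (5+5 habituation, 5+5 acquisition with shock,
10+10 extinction; 8-s CS).**  Per-trial scores subtract the 2-s pre-CS
baseline mean from the channel's highest value during the 8-s CS interval;
for HR the baseline is the mean HR over the 2-s window.  Differential
("conditionability") scores are `mean(CS+) − mean(CS−)` within phase;
CS+-only means are kept as separate features since strong CS− responders can
null the differential.  The unconditioned response is scored against the 2 s
preceding shock onset, peak searched from shock onset through 6 s past
offset, averaged over the five reinforced trials.  Conditioning features are
reported in raw channel units (µS/µV/bpm), matching how such feature blocks
are conventionally tabulated; only the SC orienting response — defined here,
since no published definition exists, as the response to the *first*
habituation-phase presentation (configurable to the habituation mean) — is
square-root transformed to sit on the same scale as the loud-tone means.
HR extinction scores are computed and exposed on the feature object but not
emitted into the analysis feature block, mirroring the predictor set used in
the risk models.

**Script-driven imagery.**  Per channel and script, the response is the mean
level during the ~30-s imagery period minus the mean of the preceding
baseline period, averaged over the two trauma scripts.  The physiologic PTSS
index is the Bayes posterior of the PTSD-like class under a two-group
Gaussian model with pooled covariance over the (HR, SC, lateral-frontalis)
triplet: posterior = `σ(wᵀx + b)` with `w = Σ⁻¹(µ₁ − µ₀)` and `b` absorbing
the class-mean midpoint and the prior log-odds.  The historically derived
discriminant's coefficients were never published, so the model either loads
fixed coefficients from JSON (exact reproduction when known) or is trained
on a labelled synthetic calibration cohort whose class structure makes the
0.5-threshold classification specific but not sensitive, the qualitative
operating character reported for the original function (57% sensitivity,
89% specificity); only the direction of that asymmetry is asserted, not the
values.  Priors default to calibration proportions and are configurable —
whether the original function used equal or sample priors is unknown.
Corrugator imagery responses are computed for completeness but excluded from
the discriminant.

## Cohort analysis

Outcomes (IES-R total; imagery posterior probability) are heavily
right-skewed in healthy cohorts, so each is dichotomized at its empirical
upper tertile (high vs lower-two-tertiles); `Q4_vs_Q1` and `T3_vs_T1`
contrast schemes are provided for robustness checks and mark middle
observations excluded.  Ties at a cut point go to the low group
(deterministic, conservative toward the larger group).  Subjects missing an
outcome are excluded before dichotomization.

Candidate predictors are screened univariately with Welch's
unequal-variance t-test (Satterthwaite df) at α = 0.20, deliberately
uncorrected for multiplicity (the screening is a liberal filter, and the
output notes the caveat).  Missing predictor values among the screened set
are singly imputed at the conditional means of a multivariate-normal EM fit
(observed-data log-likelihood tolerance 1e-6, max 500 iterations; a small
ridge keeps the covariance invertible when n is small relative to p;
observed values are never touched).  Selection is forward-stepwise logistic
regression: at each step the candidate with the smallest Rao score-test
p-value enters if below `p_enter`, then any included term whose Wald p
exceeds `p_remove` is dropped, iterated to stability, with the final model
refit by maximum likelihood.  The published analysis does not state its
entry/stay criteria; defaults are `p_enter = p_remove = 0.15`, which permits
retention of near-significant terms like those reported (p ≈ .06), and both
are configurable and logged.  Model discrimination is the c-statistic (ROC
area, ties counted ½).  Adjusted refits force time-since-trauma and
clinician-rated trauma severity into the selected model and always report
them.  Complete or quasi-complete separation raises a named error rather
than returning unstable estimates.

## Synthetic data

**Cohorts.**  Predictors are multivariate normal with configurable moments
(defaults: the published pre-trauma sample means/SDs; correlations default
to independence — no correlation matrix was published, and independence is
the transparent default, flagged in the log).  Predictors are drawn as plain
normals: integer-valued or range-limited features (e.g. trials-to-criterion)
are not rounded or truncated, keeping the configured moments exact.  Binary
demographics are Bernoulli at the published proportions.  The binary
high-PTSS label follows `Bernoulli(σ(α + Σβx))` with per-unit odds ratios
defaulting to the fitted-model values; α is solved by quadrature + bisection
so the population prevalence equals the upper-tertile target 1/3.  The
continuous outcome scores are then drawn as a right-skewed two-component
mixture separated at a fixed symptom cut and consistent with the labels
(IES-R on 0–88; posterior probability on 0.15–0.95) — the analysis consumes
only the dichotomized outcome, so item-level response simulation would add
nothing the pipeline could detect.  Missingness is MCAR per predictor,
default rate 0.05 (the original records report under 5% unusable/imputed
data); outcomes and covariates stay complete.

**Signals.**  Each subject's latent traits (tonic levels, startle
amplitudes, per-trial geometric habituation decay, CS+/CS− amplitudes per
phase and channel, UCR amplitudes, imagery deltas, noise scales) are
injected into plausible shapes: SC phasics are difference-of-exponentials
kernels (≈0.4 s rise, ≈1.2 s decay constants, grid-normalized so the
sampled peak equals the planted amplitude); integrated-EMG responses are
half-sine bursts inside the scoring windows; HR responses are
plateau-shaped accelerations realized by laying beats down sequentially at
the instantaneous rate.  The kernels are not calibrated to any published
SCR model; their contract is that the scoring windows capture the injected
amplitudes, which the round-trip tests verify.  Default habituation decay is
0.78/trial, which realizes trials-to-criterion near 10 and log-trial slopes
around −0.3…−0.4, the scale of the published feature moments.

Measurement noise is additive Gaussian AR(1) (Ornstein–Uhlenbeck) tonic
wander with a 60-s correlation time rather than sample-level white noise.
This is deliberate: max-based baseline-to-peak scoring is positively biased
under fast noise (the maximum selects upward excursions), and the recorded
channels — SC level and time-constant-integrated EMG — drift slowly rather
than fluctuating per sample.  With slow wander the baseline subtraction
removes most of the noise and peak scores stay unbiased; shortening
`noise_tau` reintroduces the selection bias and can be used to study it.
One known consequence: 30-s imagery period means do not average the wander
away, so imagery deltas carry per-period noise of roughly the trait noise
SD.

**What passing tests do and do not show.**  The generator matches the
analysis' distributional assumptions by construction (normal predictors,
exact logistic outcome, MCAR missingness).  Passing recovery and coverage
tests therefore validate the pipeline's correctness, not its robustness to
real-world violations — correlated predictors, informative missingness,
non-logistic outcome processes, artifacts needing the aberrant-trial repair.
Aberrant-value repair itself is an explicit index-based API
(`replace_aberrant`: interior trials get the neighbour average, edge trials
the single neighbour's value); automated artifact *detection* is out of
scope, as the original procedure was visual review.

## Numerical choices

- Sampling rate is configurable; tests and the generator default to 100 Hz
  (the scoring windows are ≥40 ms, so desk-scale rates lose nothing);
  1000-Hz data are supported.
- Empirical tertile/quartile cuts use linear-interpolation quantiles; ties
  at a boundary go low.
- Welch df is kept at full precision internally and rounded only for
  display.
- The stepwise loop guards against cycling by stopping when a pass changes
  nothing; logistic fits run Newton iterations to `maxiter=200` and raise on
  non-convergence; |coefficient| > 50 triggers the separation check.
- EM groups rows by missingness pattern; convergence is on the observed-data
  log-likelihood; non-convergence warns and returns the best iterate.
- Determinism: every random draw flows from a single seeded generator; rerun
  with the same config and seed reproduces artifacts byte for byte.

## Simulation scales

The repeated-cohort benchmarks use 300 replicates at the study sample sizes
(n = 96/95) for the in-sample c-statistics, 50 replicates of n = 5000 for
odds-ratio recovery, and 200 replicates of n = 5000 for stepwise selection
and CI coverage; these sizes put the Monte-Carlo error of each reported mean
well inside the tolerance it is compared at.

## Known limitations

- The cohort generator draws predictors independently; real feature blocks
  (e.g. the SC measures) are correlated, and screening/stepwise behaviour
  under correlation is only reachable through the configurable correlation
  matrix, not the defaults.
- Single (not multiple) imputation: downstream standard errors ignore
  imputation uncertainty, as in the original analysis.
- The discriminant trained on the synthetic calibration cohort reproduces
  the *kind* of operating point of the unpublished function, not its
  coefficients; posterior probabilities are therefore comparable only within
  a calibration.
- In-sample c-statistics are optimistic at n ≈ 96 (no shrinkage or
  cross-validation), which is exactly the quantity the published models
  report and is reproduced here as such.
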