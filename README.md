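# ptssrisk

Pre-trauma psychophysiologic scoring and prospective risk analysis of
post-traumatic stress symptoms (PTSS).

## The problem

Most people exposed to a traumatic event do not develop PTSD, and prospective
studies of high-risk professions (police, firefighters) ask which traits
measured *before* trauma predict who will carry more post-traumatic stress
symptoms afterwards.  The study design this package implements measures, at
baseline, psychometrics (estimated IQ, depression, trait anxiety, NEO
domains) and laboratory psychophysiology — startle reactivity and
habituation to 15 loud tones, and differential fear conditioning
(CS+ paired with shock vs CS−) — then, after a traumatic exposure, measures
subjective PTSS (IES-R total) and an objective physiologic index: the
posterior probability of PTSD-like reactivity from a linear discriminant
over heart-rate, skin-conductance and frontalis-EMG responses during
script-driven imagery of the event.

The package provides, as a tested pipeline:

- **Epoch scoring** (`epochs`, `tones`, `conditioning`, `imagery`):
  baseline-to-peak response scores on half-open windows (eyeblink EMG
  40–200 ms; SC and HR 1–4 s post tone; 2-s pre-CS baseline vs 8-s CS
  interval; UCR searched through 6 s past shock offset), square-root
  transformation, habituation measured absolutely (trials to two successive
  non-responses, SC < .05 µS, EMG < .30 µV) and relatively (OLS slope of
  √response on log trial number, trials 2–15, `Y = bx + a`), differential
  conditionability `mean(CS+) − mean(CS−)`, and the two-group
  shared-covariance Gaussian discriminant posterior
  `σ(wᵀx + b)`, `w = Σ⁻¹(µ₁ − µ₀)`.
- **Cohort analysis** (`analysis`): upper-tertile dichotomization of the
  skewed outcomes, Welch unequal-variance screening at p < .20
  (uncorrected), single EM imputation of missing predictors under a
  multivariate normal, forward-stepwise logistic regression with backward
  Wald checks (entry/stay p = .15), c-statistic (ROC area), and refits with
  time-since-trauma and trauma-severity forced in.
- **Synthetic data** (`cohort`, `signals`): subject-level cohorts whose
  predictor moments default to the published sample values and whose binary
  high-PTSS outcomes follow a logistic model with the published fitted odds
  ratios (subjective outcome: IQ 0.95, extinction-phase differential
  corrugator EMG 1.17, BDI 1.15; physiologic outcome: IQ 0.94, mean SC
  response 4.02; intercept solved for prevalence 1/3); and raw multichannel
  sessions whose planted response amplitudes the scoring stages recover.

## Worked example

```sh
python analysis/01_simulate_cohort.py
```

```
simulated cohort: n = 99, prevalence target = 0.333
realized high-IESR fraction:  0.303
realized high-PP fraction:    0.273

predictor            configured (M, SD)    realized (M, SD)
est_iq                101.80  10.00       102.93  10.67
bdi                     2.50   3.20         2.30   2.73
emg_diff_ext           -0.70   4.40        -0.90   4.87
sc_mean_response        0.60   0.30         0.53   0.27
```

A 99-subject cohort drawn at the configured moments; at this sample size
the realized means/SDs scatter around the configured values and the
realized high-outcome fractions scatter around the 1/3 target.
`analysis/02_score_physiology.py` simulates raw sessions and shows the
scored features recovering the planted traits (e.g. SC acquisition
differential 0.199 µS recovered for a planted 0.20); `03_screen_and_fit.py`
runs screening → imputation → stepwise selection and prints the model table
(selected predictors, odds ratios, Wald χ², p, c-statistic);
`04_consistency_benchmarks.py` repeats the simulation many times:

```
subjective-outcome model, n=96: mean in-sample c = 0.751 (published 0.70)
physiologic-outcome model, n=95: mean in-sample c = 0.700 (published 0.70)
recovered IQ odds ratio at n=5000: 0.949 (generating 0.95)
recovered SC-response odds ratio at n=5000: 4.084 (generating 4.02)
stepwise at n=5000: all three generating predictors selected in 100% of
100 cohorts; pooled 95% CI coverage 96.7%
```

The same machinery is available from a CLI (`ptssrisk run-all`,
`simulate-cohort`, `simulate-signals`, `score-tones`, `score-conditioning`,
`score-imagery`, `analyze`).

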