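# Methods

## Indices

All index arithmetic operates on already-averaged scalars (no pressure-trace
or image processing):

- `IMR = Pd_hyp × tTmean_hyp` (U = mmHg·s), the thermodilution index of
  microcirculatory resistance at maximal hyperaemia.
- `IMR_corr = Pa_hyp × tTmean_hyp × (Pd_hyp − Pcw)/(Pa_hyp − Pcw)`, the
  coronary-wedge-pressure correction for collateral flow. Wedge pressure is
  measured during balloon inflation, so the correction is accepted pre-PCI
  only; a post-PCI record carrying Pcw is rejected as a schema violation,
  and `Pcw ≥ Pd_hyp` is a degenerate-haemodynamics error (the correction
  would be zero or negative). `Pcw = 0` is short-circuited so the identity
  `IMR_corr = IMR` holds exactly in floating point.
- `IMR_angio = Pa_hyp × QFR × Nframes/fps`, with `fps = 15` by default.
  QFR enters as a measured scalar in (0, 1]; the contrast-flow vs
  fixed-flow variant is carried as metadata and never used in a formula.
- `CFR = tTmean_rest / tTmean_hyp`, the standard thermodilution coronary
  flow reserve. CFR (and the wedge-corrected IMR) are omitted from a
  lesion's panel when their inputs are absent — never imputed.

Frame counts map to transit times by `Nframes = round(tTmean × fps)` with
half-away-from-zero rounding, clamped at one frame (a cine run cannot have
fewer). A record may carry a positive *fractional* frame count: the
simulator's rounding-disabled diagnostic mode uses it to represent the exact
transit time, which is what makes the zero-noise equivalence
`IMR_angio ≡ IMR` hold to machine precision end-to-end.

## Synthetic cohort

The generator emulates a 45-patient primary-PCI cohort with a 15-patient
multivessel subset (both sizes configurable). Its published anchors are
median (IQR) summaries, so each positive quantity is modelled log-normally
with a **median-preserving quantile fit**: `mu = ln(median)` and `sigma` the
mean of the two one-sided log z-scores `(ln median − ln q1)/z75` and
`(ln q3 − ln median)/z75`, `z75 = Φ⁻¹(0.75) ≈ 0.6745`. The fitted median is
exact by construction; when a summary is asymmetric on the log scale the
IQR is compromised symmetrically. Defaults (U): IRA pre-stenting
48.6 (25.5–60.3), IRA post-PCI 30.9 (16.5–52.9), non-IRA 19.0 (12.5–27.5) —
which also fixes the stratum ordering non-IRA < post < pre.

Per patient, pre- and post-PCI latent resistances share a Gaussian copula on
the log scale with `rho = 0.6`. The joint pre/post distribution is not
published; 0.6 makes roughly two thirds of patients land below 40 U after
stenting, bracketing the reported 63.6–69.7% good-responder rates, and is
flagged as an explicit assumption in the provenance record. The non-IRA
resistance is independent.

**Observation model.** For each vessel/timepoint, aortic pressure Pa is
log-normal (median 90, IQR 80–100 mmHg — typical catheter-lab values; not
published in the source summaries). The hyperaemic Pd/Pa ratio is drawn from
a Beta distribution scaled to (0.3, 1.0) — bounded so Pd can never exceed
Pa — with median 0.75 pre-PCI (concentration 4) and 0.95 post-PCI
(concentration 20), matching the published medians and approximate spreads.
The transit time is then **derived**, `tTmean = R/Pd`, so the noiseless
pressure-wire record reproduces the latent resistance exactly; the latent R
is the single ground truth for recovery tests. The angiographic surrogates
are

- `QFR = clip(Pd/Pa × exp(ε), 0.01, 1.0)`, `ε ~ N(0, qfr_noise_sd)`,
- `Nframes = round(tTmean × exp(η) × fps)`, `η ~ N(0, frame_noise_sd)`,

and the angiographic Pa equals the physiologic Pa (the pressure wire stays
in place during the cine acquisition, so both modalities share one aortic
pressure). Resting records (for CFR) use a log-normal CFR matched to the
published summaries (1.27 pre, 1.81 post) and a resting Pd/Pa shrunk toward
1; the wedge pressure of pre-PCI IRA records is `Pd_hyp × Beta(2, 4)`,
always strictly below Pd. Non-IRA vessels are observed once, labelled
post-PCI, with the post-PCI Pd/Pa and CFR distributions (non-culprit
vessels are haemodynamically near-normal).

**Noise calibration.** `qfr_noise_sd = 0.22` and `frame_noise_sd = 0.32`
are calibration constants, set once from a 2,000-lesion simulation and not
revisited. They place the overall Spearman correlation between measured
IMR_angio and IMR at ≈ 0.90 (per-stratum pattern: post > overall > pre >
non-IRA, as in the validation study). Pushing the correlation all the way
down to the reported 0.85 needs total log-scale noise ≈ 0.5, which drags
the Youden-optimal cutoff for predicting an abnormal IMR down to ≈ 33–36 U:
with noisy surrogate scores and asymmetric class spreads the Youden
estimator is biased toward the dense side of the decision boundary. The
chosen constants are the compromise that keeps the correlation inside the
plausible band while the recovered cutoff stays within ±5 U of the true
40 U boundary.

**MVO outcome.** `P(MVO significant) = 1/(1 + (r50/R_post)^β)` with
`r50 = 55 U`, `β = 2.2` — a logistic in log-resistance with midpoint r50.
These defaults put simulated MVO prevalence near 15% among lesions with
post-PCI IMR_angio < 40 U and near 60% at/above, bracketing the published
19%/60% stratification. The continuous burden (% LV mass, threshold 1.55%)
is cosmetic; only the binary flag drives analyses.

**Reproducibility.** All randomness flows from one root seed. Each patient
uses `numpy` `SeedSequence(entropy=seed, spawn_key=(patient_index, stage))`
streams (stage 0 latent resistances, 1 observation, 2 MVO), so cohorts are
byte-identical across runs and invariant to processing order.

**What the simulator does not emulate:** TIMI flow, thrombus burden,
procedural covariates, angiographic image artefacts, QFR analysability
failures, repeated operator readings, or any correlation between
measurement noise and disease severity (real IMR_angio/IMR disagreement
grows above ~75 U). Passing tests therefore show the pipeline's statistics
are correct and well-calibrated under this generative model, not that
IMR_angio performs identically on real patients.

## Diagnostics

Implemented formulaically, each cross-checked in the test suite against an
independent oracle (brute-force Mann–Whitney pair counting for AUC, scipy
for correlations and Fisher, pingouin for the ICC, hand arithmetic for
Bland–Altman and the ICC mean squares):

- **ROC/Youden** — positive calls are `score ≥ threshold`; candidate
  thresholds are midpoints between consecutive sorted unique scores plus
  ±∞ sentinels; AUC by trapezoid along the threshold-ordered curve; Youden
  J ties broken toward the lowest cutoff (deterministic output).
- **Confusion metrics** — PPV/NPV are absent (None), not 0, when their
  denominator is empty.
- **Bland–Altman** — differences are first minus second argument; limits
  are bias ± 1.96·SD with the n−1 denominator.
- **ICC** — ICC(A,1): two-way random effects, single rater, absolute
  agreement, from the mean squares; 95% CI by the F-distribution method;
  the between-subjects F = MSR/MSE is returned alongside. Chosen because
  the two readers are interchangeable raters of the same continuous
  quantity.
- **Fisher's exact test** — two-sided by the point-probability method,
  exact integer arithmetic. For the published MVO 2×2 table
  [[4,17],[6,4]] this gives p = 0.040 and the uncorrected chi-square gives
  p = 0.023; the printed 0.03 matches neither standard method, so the
  pipeline reports both side by side.
- **Responders** — good responder iff the post-PCI index is strictly below
  the threshold (40 U is adverse); the misclassification rate is the
  fraction of patients whose IMR_angio label differs from their IMR label.

The published diagnostic quintet at the 40 U cutoff (sensitivity 83.0%,
specificity 100%, NPV 90.2%, PPV 96.8%, accuracy 92.4%) is internally
inconsistent — perfect specificity forces a perfect PPV — so the tests pin
the nearest consistent 2×2 table (tp=30, fp=1, fn=6, tn=55 at n=92:
sensitivity 83.3%, PPV 96.8%) rather than asserting all five values at
once.

## Pipeline

`run_study` chains simulate → compute → validate in one process and equals
the CSV round trip through the CLI field-for-field. Stratum summaries use
median and quartiles with linear interpolation of the empirical CDF (the
quartile estimator is stated here because several conventions exist).
Report keys are schema-stable: empty strata produce explicit zero-count
blocks rather than missing keys, and the JSON serialiser rejects NaN/inf so
every numeric field is finite by construction. Default problem sizes —
45 patients for study-scale runs, ~870 patients (≈ 2,000 lesions) for
calibration-level checks, 10⁵ draws for quantile-recovery checks — keep
every check well inside interactive runtimes.

## Known limitations

- The IQR of an asymmetric summary is matched only in log-symmetrised form;
  extreme right tails (IMR ≫ 100 U) are thinner than in real STEMI
  cohorts.
- Measurement noise is homoscedastic on the log scale; real agreement
  degrades with severity.
- The MVO link uses the post-PCI *latent* resistance, not the measured
  index, so simulated prediction AUCs for MVO are slightly optimistic.
- Fisher's "two-sided p" has several conventions; only the
  point-probability method is implemented.
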