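# imrangio

Coronary microvascular injury after ST-elevation myocardial infarction
(STEMI) is usually quantified with the **index of microcirculatory
resistance (IMR)** — hyperaemic distal pressure times hyperaemic mean
transit time, `IMR = Pd·tTmean` (units "U" = mmHg·s) — which requires a
pressure wire and thermodilution. The **angiography-derived IMR
(IMR_angio)** replaces both observables with angiographic surrogates: the
quantitative flow ratio (QFR) stands in for the hyperaemic Pd/Pa ratio, and
the contrast frame count over the acquisition rate stands in for the transit
time,

```
IMR_angio = Pa · QFR · Nframes / fps          (fps = 15 frames/s)
```

so the microvasculature can be assessed wire-free in the catheter
laboratory. Before stenting, IMR can additionally be corrected for coronary
wedge pressure (collateral supply):
`IMR_corr = Pa · tTmean · (Pd − Pcw)/(Pa − Pcw)`.

`imrangio` is for interventional-cardiology researchers who want to compute
these indices from per-lesion tables and to study how faithfully IMR_angio
tracks wire-based IMR. It provides:

- **indices** — IMR, wedge-corrected IMR, IMR_angio, CFR and Pd/Pa from
  validated per-lesion records, with CSV input/output;
- **cohort** — a synthetic primary-PCI cohort generator: per-stratum
  log-normal resistances quantile-matched to published median/IQR summaries
  (infarct-related artery pre/post stenting, non-IRA), a Gaussian copula
  coupling pre/post, a noisy QFR/frame-count observation model, and a
  logistic-in-log link to a binary microvascular-obstruction (MVO) outcome;
- **diagnostics** — first-principles ROC/AUC with the Youden cutoff,
  confusion metrics, Bland–Altman limits of agreement, the two-way
  random-effects absolute-agreement ICC with F-based CI, Pearson/Spearman
  correlations, Fisher's exact test, and responder classification at the
  40 U threshold;
- **pipeline / CLI** — `imrangio simulate | compute | validate | run |
  report`, chaining the stages deterministically from one seed.

## Worked example

```
$ imrangio run --seed 1 --out-dir demo
$ imrangio report --report demo/report.json
     all: n=105, Spearman rho=0.851
ira_post: n=45, Spearman rho=0.834
 ira_pre: n=45, Spearman rho=0.776
 non_ira: n=15, Spearman rho=0.768
ROC (IMR_angio vs IMR >= 40U): AUC=0.946, Youden cutoff=36.5U
responders: 45 paired patients, misclassification 6.7%
MVO prevalence: 2% below cutoff, 67% at/above (Fisher p=0.009)
```

A default 45-patient virtual cohort yields 105 lesion panels (45 IRA
pre-PCI, 45 IRA post-PCI, 15 non-IRA). The report shows the rank
correlation between the wire-based and angiographic index overall and per
stratum, how well IMR_angio discriminates an abnormal reference IMR
(≥ 40 U, the prognostically adverse range), the Youden-optimal IMR_angio
cutoff, the fraction of patients whose good/poor stent-response label flips
between the two indices, and MVO prevalence by angiographic stratum. The
full `report.json` also carries Bland–Altman bias and limits of agreement,
ICC with 95% CI, and median (IQR) summaries per stratum.

The same analyses run on real data: put your measurements in
`physiology.csv` / `angiography.csv` (schemas in
`imrangio.indices`) and use `imrangio compute` + `imrangio validate`.

## Documentation

See `docs/methods.md` for the generative model, its assumptions, the
calibration of the measurement-noise constants, numerical conventions, and
known limitations.
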