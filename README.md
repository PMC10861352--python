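# protopanel

Biomarker panel discovery for ultra-high-dimensional (p ≫ n) case–control
proteomics, built for the preoperative-plasma setting: a small balanced
cohort (tens of subjects) measured on ~1400 protein markers (e.g. SOMAmer
relative-fluorescence readouts), with a binary outcome such as
postoperative delirium. The package takes a wide subjects × markers
intensity table plus a 0/1 label table and produces, end to end:

1. **Volcano statistics** — per-marker log2 fold change (case − control
   means of the log2 values) with two-sample t, Kolmogorov–Smirnov and
   Mann–Whitney p-values; a marker is differentially expressed when
   |log2FC| ≥ 0.2 and p_t < 0.05.
2. **Consensus sure-independence screen (SIS)** — rank markers by each
   test's p-value, keep the top *d*ₙ per test (recommended
   *d*ₙ = n/ln n, e.g. 11 at n = 40; conservative default 50), and
   intersect the three retained sets. Marginal screening first avoids the
   noise accumulation and spurious correlation that plague joint modeling
   when p ≫ n.
3. **Lasso logistic panel** — on the screened, standardized markers,
   minimize (1/n)·Σᵢ −ℓᵢ(β₀, β) + λ‖β‖₁ with the intercept unpenalized,
   λ by cross-validated deviance (or a fixed-support-size / fixed-λ
   preset). Coefficients stay on the per-1-SD scale, so exp(β) is the
   odds-ratio factor per SD of a marker.
4. **AIC refinement** — backward elimination from the lasso support under
   AIC = −2 logL + 2(k+1) with unpenalized refits (tiny-ridge stabilized
   and flagged under quasi-separation).
5. **Per-marker ROC** — empirical AUC (normalized Mann–Whitney U),
   direction-oriented so AUC ≥ 0.5, with the Youden-optimal cutoff
   (max J = sensitivity + specificity − 1).
6. **Leave-one-out cross-validation** — refit the final panel's
   coefficients on each n−1 subset, classify the held-out subject at
   probability ≥ 0.5; accuracy is the fraction of correct held-out calls.
   The panel itself is fixed inside the loop, so the estimate still
   carries post-selection optimism (documented, not hidden).

A synthetic cohort generator (`CohortDesign` / `simulate_cohort`)
produces raw-scale intensities whose log2 values are Gaussian with a
small planted set of differential markers (standardized shifts, optional
block equicorrelation), so the whole pipeline is testable without any
real cohort.

## Worked example

```bash
protopanel simulate --n-case 20 --n-control 20 --p 300 --n-true 5 \
    --delta 2.0 --seed 42 --out demo
protopanel run-all --expression demo/expression.csv \
    --labels demo/labels.csv --dn 30 --seed 42 --out demo/out
```

prints (to stderr)

```
INFO protopanel: loaded 40 subjects x 300 markers (20 cases / 20 controls)
INFO protopanel: volcano: 13 up, 8 down, 279 ns of p=300
INFO protopanel: screening: 19 consensus markers at d_n=30
INFO protopanel: lasso: 7 of 19 markers retained at lambda=0.0040085
INFO protopanel: stepAIC: final panel of 2 markers (AIC 6.000)
final panel: M004, M003
in-sample accuracy=1.000 LOOCV accuracy=1.000
```

Reading: of 300 markers, 21 pass the volcano rule; the three-test screen
keeps 19 consensus markers; the lasso retains 7 of them and the AIC step
keeps 2 — both truly differential by construction (markers M001–M005 were
planted at a 2-SD shift). `demo/out/panel.csv` reports each retained
marker's coefficient and odds-ratio factor, e.g. M004's β = 2.57 means a
1-SD increase multiplies the odds of being a case by exp(2.57) ≈ 13.1.
With a 2-SD planted effect the 40-subject cohort is nearly separable, so
both in-sample and LOOCV accuracy reach 1.0 here; at weaker effects the
LOOCV accuracy drops below the in-sample one, which is the generalization
gap the LOOCV stage exists to expose. Every stage also writes a CSV
(`volcano.csv`, `screening.csv`, `panel.csv`, `roc.csv`, `loocv.csv`)
plus `manifest.json`, which records everything needed to reproduce the
run bit-exactly.

The same stages are available as a library — `compute_marker_stats`,
`consensus_screen`, `LassoPanelLogistic` (a scikit-learn estimator),
`step_aic_refine`, `roc_and_youden`, `loocv_panel` — see the docstrings
and `docs/methods.md`.

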