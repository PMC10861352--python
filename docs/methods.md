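# Methods

## Setting and model

The package addresses biomarker discovery in a small case–control cohort
measured on an ultra-high-dimensional proteomic panel: n subjects (default
20 cases, 20 controls) by p markers (default 1433), with positive raw
intensities (relative-fluorescence-unit scale). All modeling runs on
log2-transformed, per-marker standardized values: for marker j,
z_ij = (log2 x_ij − mean_j) / sd_j with the n−1 sample SD, pooled over
cases and controls (one transform feeds every stage). Fold changes are
computed on the pre-standardization log2 values, which the expression
container retains; the three per-marker tests are invariant to the
per-marker affine standardization, so their p-values are the same on
either scale.

The discovery chain is: volcano statistics → three-test consensus
sure-independence screen → lasso logistic panel → backward AIC
refinement → per-marker ROC/Youden characterization → leave-one-out
validation of the final panel. The stage outputs are nested by
construction (screen ⊇ lasso support ⊇ final panel) and the pipeline
enforces that invariant at run time.

## Per-marker tests (dialects)

Small-sample p-values depend on test dialects, which are fixed as:

* **t**: Welch (unequal variances) by default; `t_variant="pooled"` gives
  the classic equal-variance test. Zero variance in both groups yields
  p = 1 when the means agree, 0 otherwise (degenerate convention).
* **Kolmogorov–Smirnov**: exact p-value when n_case·n_control ≤ 10 000,
  else asymptotic.
* **Mann–Whitney**: exact enumeration when both groups have ≤ 8
  observations and no ties; otherwise normal approximation with tie and
  continuity corrections.

The volcano rule classifies a marker as up (down) when
log2FC ≥ +0.2 (≤ −0.2, inclusive) *and* the t-test p < 0.05 (strict);
the three classes partition the markers. No multiplicity correction is
applied at this stage by design — the screen/selection chain downstream
is the multiplicity control.

## Screening

Each requested test ranks all markers by ascending p-value, ties broken
by descending |statistic| then marker id (deterministic across
platforms). The top d_n per test are intersected; the consensus is
ordered by ascending mean rank across tests (an artifact convention —
the set is what matters). d_n defaults to 50; `recommended_dn(n)`
returns round(n/ln n) (11 at n = 40) as the standard alternative.
Enlarging d_n can only grow the consensus. An empty consensus is a valid
result that warns and stops the pipeline with a named stage error.

## Penalized panel fit

`LassoPanelLogistic` minimizes (1/n)·Σ −ℓᵢ + λ‖β‖₁, intercept
unpenalized, features *not* re-standardized internally (they arrive
standardized, so β is per-1-SD and exp(β) is the odds-ratio factor per
SD). The solver is penalized IRLS with cyclic coordinate descent and
soft-thresholding (exact zeros); it is cross-checked against R glmnet to
1e-5 in the test suite. It exists in-house because the generic
stochastic solver otherwise available for this objective recovers the
unpenalized intercept poorly once the penalty zeroes every slope
(errors ~0.1 at tight tolerance), which would corrupt the odds-ratio
and probability arithmetic downstream. λ = 0 falls through to an
unpenalized quasi-Newton fit.

λ strategies (recorded in the run manifest):

* `cv` (default): 10-fold stratified cross-validated mean held-out
  deviance over a 50-point geometric path from λ_max (the smallest λ
  zeroing every slope, max|Xᵀ(y−ȳ)|/n) down to λ_max/100; minimum wins,
  ties to the larger (sparser) λ. The fold shuffle is seeded.
* `support_size:K`: the largest path λ whose support has exactly K
  markers — useful to emulate a selection of known size.
* `fixed:V`: a fixed λ ≥ 0; `fixed:0` is the MLE limit and huge V gives
  the all-zero fit with intercept logit(case fraction). These limits
  anchor the solver tests.

The path floor λ_max/100 reflects that the screened set is comparable in
size to n: pushing further toward λ = 0 mostly explores near-separable
models. The support uses |β| > 1e-8, deliberately tiny so that a
shrunk-but-retained coefficient (e.g. one printed as −0.002) is
distinguished from one excluded by the penalty.

## Unpenalized refits, separation, AIC

Backward AIC refinement and LOOCV refit unpenalized logistic models via
statsmodels' Newton MLE. At n ≈ 40 with strong markers, quasi- or
complete separation is common; a separated or non-converged fit is
re-run with a 1e-6 ridge on the slope block (intercept untouched) and
flagged, and the reported log-likelihood is the unpenalized one at the
ridged estimate. AIC = −2 logL + 2(k+1) counts the intercept. Backward
elimination removes, at each step, the single marker whose removal
lowers AIC most (ties to the earlier marker in the input support) and
stops when no removal lowers it; the trace is strictly decreasing and
the final support is nested in the input.

A finite-sample caveat the tests encode: the likelihood-ratio statistic
of a null marker at n = 40 is stochastically larger than its asymptotic
χ²₁ (removal probability ≈ 0.833 rather than 0.843), and conditioning on
a strong quasi-separating companion inflates it further (≈ 0.79). "AIC
removes a pure-noise marker" is therefore a *usually*, not an *almost
surely*, and the Monte-Carlo thresholds in the suite come from direct
MLE oracle simulations at these conditions, not from the χ² limit.

## ROC, Youden, LOOCV

The AUC is the empirical (midrank / normalized Mann–Whitney U) one.
Each marker is oriented so the reported AUC ≥ 0.5; the direction encodes
whether the rule is "case if value ≥ c" (high_is_case) or "≤ c"
(low_is_case). Candidate cutoffs are midpoints between consecutive
sorted unique values plus ±∞, so sensitivity/specificity are
step-consistent regardless of ≥/> conventions; at the returned threshold
the rule is inclusive. J-ties break toward higher specificity, then the
stricter threshold. A constant marker returns AUC 0.5, J 0, and a
degenerate flag.

LOOCV holds each subject out once, refits the *coefficients* of the
fixed final panel on the remaining n−1, and classifies at
probability ≥ 0.5 (a probability of exactly 0.5 is a case call).
Selection is intentionally not repeated inside the loop — the protocol
validates the fitted panel, and the residual post-selection optimism is
a documented property (the suite asserts in-sample ≥ LOOCV accuracy in
≥95/100 replicates). A quirk worth knowing: with an empty panel and
balanced groups, every fold's training prevalence votes against the
held-out subject (19/39 < 0.5 for a held-out case, 20/39 ≥ 0.5 for a
held-out control), so the LOOCV accuracy is exactly 0 — a useful
closed-form pathology for testing.

## Synthetic cohorts

`simulate_cohort` draws log2 values as Gaussians: marker j has SD
sigma_log2[j] (default 1), mean `baseline_log2` (default 10, a typical
log2-RFU magnitude) in controls, shifted by delta_j·sigma_log2[j] in
cases iff j is planted (defaults: five planted markers at delta = 2).
Optional block equicorrelation (rho within consecutive blocks of
`block_size`) stresses the spurious-correlation regime; rho = 0 with
block size 1 gives independent markers. Raw intensities are 2^(log2
value), so the pipeline's transform round-trips exactly. One integer
seed drives all randomness; identical seeds give bit-identical cohorts,
with cases first in the subject ordering.

What the generator does *not* emulate: assay chemistry and plate
effects, normalization artifacts, heavy tails or outliers, missing
data, and realistic correlation graphs. Passing tests therefore show
that the statistical machinery behaves as specified under a clean
Gaussian-on-log2 cohort of the study's shape — not that any particular
real-data marker list would replicate. The Gaussian choice is an
assumption; the source study describes its data only as log2-transformed
and standardized.

A second fixture, `reference_panel()`, carries the published 12-marker
preoperative delirium panel (lasso coefficients per 1 SD and per-marker
empirical AUCs; the unreported intercept is set to 0 and nothing depends
on it). It anchors the reporting arithmetic — odds-ratio factors such as
exp(0.562) = 1.75, support extraction with the near-zero −0.002
coefficient retained, prediction identities — without any cohort data.

## Numerical and design choices

* Standardization is pooled (cases + controls) before any comparison;
  zero-variance markers fail fast by default or can be dropped with a
  warning.
* Missing cells fail fast by default; optional per-marker mean
  imputation is explicit and flagged. CSV reload is bit-exact (cells are
  parsed with full-precision float conversion).
* Tables are comma-separated UTF-8 with a header; tab-separated input is
  accepted by sniffing the header line.
* Coefficient zero-tolerance 1e-8; ridge fallback 1e-6; penalized solver
  tolerance 1e-10 (coefficients reproducible to ~1e-6).
* Problem sizes in the Monte-Carlo suite: 100 seeded replicates for
  recovery/optimism properties at the study scale (p = 1433) or a
  reduced p (120–300) where the property does not depend on p; 400
  replicates for the single-marker AIC removal rate; 1000–4000 null
  markers for type-I checks.

## Known limitations

* The λ path and CV folds are conventions; no claim is made that any
  particular λ reproduces a historical selection, and `support_size:K`
  exists precisely because a published support size may be the only
  recoverable anchor.
* LOOCV validates coefficients of a fixed panel; it does not undo
  selection bias from screening/lasso performed on the full cohort.
* The ridge-stabilized refit under separation makes reported
  coefficients at separated fits convention-dependent (they are flagged).
* No covariate adjustment, no SCAD/elastic-net penalties, no iterative
  (ISIS) screening, no AUC confidence intervals, no enrichment analysis
  (the final panel is exported as a plain symbol list for external
  enrichment services).
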