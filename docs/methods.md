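# Methods

This note documents the models, the synthetic-data design, and the numerical
choices behind `ntcp-albi`, in the spirit of a statistical package's methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Radiobiological DVH reduction

The normal-liver differential DVH (vᵢ, Dᵢ) — volume fraction and physical
dose per bin — is the dosimetric substrate. Two reductions are applied in
order:

**EQD2 per bin.** Each bin dose is converted to the equieffective dose in
2-Gy fractions with the linear–quadratic model,
`D · (d + α/β) / (2 + α/β)`, where `d = D / n_fractions` is the bin's dose
per fraction (every voxel is assumed irradiated proportionally in every
fraction, the standard DVH-level convention) and α/β = 2.0 Gy for normal
liver. The map is the identity at 2 Gy/fraction, raises bins above it and
lowers bins below it, and is strictly increasing in D, so bin ordering is
preserved. We implement the plain LQ conversion; a linear tail for very high
doses per fraction (an LQ-L variant) would need a transition-dose parameter
for which no value is established here, so it is deliberately out of scope.

**gEUD.** The power mean `gEUD(a) = (Σ vᵢ Dᵢᵃ)^{1/a}` with volume-effect
parameter a > 0, swept over a ∈ {0.01, 0.05, 0.1, 0.5, 1.0, 2.0}. a = 1 is
the mean liver dose (MLD). Properties relied on (and tested): gEUD(1) equals
the mean dose; gEUD is strictly increasing in a whenever the DVH has two or
more distinct dose levels with positive volume (power-mean inequality); and
gEUD always lies between the minimum and maximum dose of the support. 0ᵃ is
defined as 0 so zero-dose bins need no special casing; a ≤ 0 is rejected
rather than mapped to the geometric-mean limit, since only positive a is
meaningful in this sweep.

**Cumulative exports.** Planning systems export cumulative DVHs
(volume at-or-above dose). Conversion takes successive differences and
assigns each bin the midpoint of its dose interval (symmetric and unbiased
for smooth DVHs); volume still at-or-above the last grid dose is assigned at
that dose. An everywhere-constant cumulative column is rejected — the mass's
upper edge is undeterminable. Re-accumulating the differential DVH
reproduces the input cumulative volumes exactly. Volume columns are
normalised to fractions; deviations of the sum from 1 above 10⁻⁶ are
renormalised with a warning, above 1 % rejected as a probable unit error.

## Liver-function scoring and endpoints

- **ALBI score** = 0.66·log₁₀(bilirubin µmol/L) − 0.085·albumin g/L, with
  conventional-unit helpers (mg/dL ×17.1; g/dL ×10). Grades are closed on
  the lower grade: grade 1 iff score ≤ −2.60, grade 2 iff ≤ −1.39.
- **ALBI score until next grade** — the engineered feature — is
  `threshold − score` (−2.60 for grade-1, −1.39 for grade-2 patients), so it
  is ≥ 0 for the admitted population, 0 exactly on a boundary, and its
  expected model coefficient is *negative* (closer to the boundary ⇒ higher
  risk). Grade-3 baselines have no next grade and are excluded.
- **Child–Pugh** uses the standard five-component table (bilirubin <2/2–3/>3
  mg/dL; albumin >3.5/2.8–3.5/<2.8 g/dL; INR <1.7/1.7–2.3/>2.3; ascites;
  encephalopathy), 1–3 points each. Missing components raise rather than
  default.
- **Endpoints.** ALBI1+ compares the worst post-treatment ALBI grade with
  baseline; CP2+ compares recorded Child–Pugh scores (a chart-entry mode —
  recomputation from labs is also possible via `child_pugh_points`); CTCAE2+
  applies the 3-fold rule per enzyme with configurable upper limits of
  normal (default 40 U/L for both AST and ALT — site-specific ULNs are never
  universal, so they are parameters). An endpoint whose inputs are missing
  is reported as *unavailable* (None), never silently negative; one positive
  enzyme decides CTCAE2+ even when the other is missing.
- **Windowing.** Selecting the "worst value within the follow-up window" is
  data curation, not method; this package consumes already-extracted worst
  values.

## Imputation

Missing numeric cells are filled by single-pass, per-column ordinary least
squares: each incomplete column is regressed (with intercept) on all other
numeric columns — temporarily mean-filled — using the rows where the target
is observed, and predictions for its missing cells are clamped to the
observed range. Columns are processed in fixed left-to-right order without
chaining, so imputation is deterministic and observed cells are bit-
identical. Columns with fewer than two observations fall back to the mean;
non-numeric columns take their mode; columns more than 50 % missing are
flagged in the report. This is intentionally the simplest defensible
regression imputation — iterative/chained variants trade determinism for
accuracy the downstream models do not need at the ~5 % missingness typical
here.

## Synthetic cohort generator

The generator is study apparatus, not an afterthought: its defaults *are*
the study conditions, and all model-level claims are made against it.

**Marginals.** Continuous covariates are truncated normals matching the
emulated cohort's reported moments (age 61.7 ± 11.7 y in 18–90; tumor
diameter 7.8 ± 4.1 cm; normal liver volume 1231.3 ± 455.6 cm³; MLD
17.6 ± 8.0 Gy; AST 68.6 ± 41.8; ALT 44.7 ± 28.8; bilirubin 1.4 ± 0.7 mg/dL;
INR 1.10 ± 0.12), with the underlying location solved numerically so that
truncation does not bias the realized mean. Categories use the reported
frequencies (84.6 % male, 49.3 % HBV, 18.9 % HCV, 37.8 % main PVT, 12.4 %
prior surgery, 63.2 % prior TACE; techniques 32.8/46.3/20.9 %), and
fractionation comes from a technique-conditional menu centred on 30 Gy/10 fx
conventionally and 50 Gy/5 fx for SBRT. The albumin marginal (3.72 ± 0.48
g/dL) has no reported value; it was derived from the ALBI formula so the implied
baseline ALBI score is ≈ −2.29 ± 0.41 with ≈ 23 % grade 1 (targets −2.28 ±
0.43 and 20.9 %). Baseline ALBI score and grade are *computed* from the
sampled labs — never sampled directly — so the lab/score coupling is exact;
grade-3 draws are rejected and resampled, mirroring the exclusion criterion.
Covariates are otherwise independent: no correlation structure is reported for such cohorts,
and independence keeps the generator transparent.

**DVHs.** `generate_dvh` mixes a low-dose spared component (exponentially
weighted bins below 0.3 × target) with an irradiated component concentrated
near a peak at the prescription dose (raised when a hot plan demands it),
using the unique mixing weight that makes the physical mean dose equal the
target exactly — so gEUD(a=1) round-trips to the target at float precision,
and every downstream dosimetric feature flows through the real EQD2/gEUD
code path. The model feature `mld` is gEUD(a=1) of the *EQD2-corrected* DVH,
as the clinical pipeline prescribes; cohort-level marginal checks are on the
physical mean dose.

**Toxicity mechanism.** Risk acts on standardized features
(z-scored within cohort):

    η = 0.9·mld − 1.2·distance + 0.5·bilirubin + 0.4·AST − 0.4·liver volume
    true_risk = E_ε σ(α + η + ε),   ε ~ N(0, 0.8²)

The signs encode domain knowledge (dose and lab burden raise risk, spared
volume protects, proximity to the next grade raises risk), with the distance
feature dominant. ε is unmeasured patient heterogeneity; the marginal risk
is computed by 31-node Gauss–Hermite quadrature, so "labels ~
Bernoulli(true_risk)" holds exactly. The intercept α is calibrated by
bisection so the cohort-mean risk equals the 43.1 % target within 10⁻⁴
(mean risk is monotone in α, so bisection cannot fail on a sane mechanism).
The noise scale 0.8 was fixed once so the oracle discrimination — AUROC of
true_risk against its own labels — is ≈ 0.82; with ε = 0 the same
coefficients give ≈ 0.84.

**Outcome realisation.** The ALBI1+ label is *not* attached to the record.
Instead, worst-case bilirubin/albumin are constructed to realise the drawn
outcome — positives are pushed just past the patient's next grade threshold
plus an exponential overshoot (scale 0.15), negatives drift within grade —
by solving the ALBI formula exactly for the split between a bilirubin rise
and an albumin fall. The labels the package reports are then produced by the
real endpoint classifier, keeping that code path under test. Worst AST/ALT
and INR are log-normal multiples of baseline, shifted upward for positives,
so CP2+ and CTCAE2+ are correlated secondary endpoints rather than designed
quantities. Missingness is injected completely at random (default 5 %) on
ALT/ALP/INR — labs the mechanism does not use, so imputation quality can be
studied without confounding the outcome.

All draws come from one seeded generator in documented order; cohorts are
bit-reproducible from (spec, mechanism, seed).

**What the generator does not emulate.** Real covariate correlations
(e.g. cirrhosis linking volume, labs and dose choices), informative
missingness, visit-schedule effects on "worst within window", inter-planner
DVH shape diversity, and case-mix drift beyond the shifted-marginal external
preset. Passing tests therefore demonstrate *methodological* correctness and
recoverability under known truth, not clinical performance on real patients.

## Risk models

Three families behind one Model/Results interface (`NTCPModel.fit()` /
`.fit_cv()`):

- **PLR** — L2-penalized logistic regression on training-fold-standardized
  features, penalty chosen from 10⁻³…10² (as C = 10⁻²…10³) by inner 5-fold
  AUROC. Coefficients are reported on the standardized scale.
- **RF** — 500 trees; depth {3, 5, ∞} × feature-subsample {√p, p} by inner
  3-fold AUROC.
- **GBT** — XGBoost, up to 300 rounds with early stopping (patience 30) on
  inner 3-fold validation, learning rate {0.03, 0.1} × depth {2, 3, 4};
  final refit uses the mean early-stopped round count. **Monotone +1
  constraints** are applied to every dosimetric feature present
  (total dose, MLD, any gEUD entry): predicted risk is non-decreasing in
  delivered dose by construction, which removes physically impossible
  dose–response reversals and stabilises the learned volume effect.

Inner 3-fold (rather than 5) for the tree grids is a deliberate
compute/variance trade-off; the grids themselves are conventional defaults,
overridable per `ModelSpec`.

**Cross-validation** is outcome-stratified 5-fold with shuffling fixed by
seed; fold models retain their held-out predictions, so every patient is
scored exactly once out-of-fold and fold ROC curves can be built and
vertically averaged. Standardization constants are computed on training
folds only.

**Recursive feature elimination** is backward: at each step the feature
whose removal maximises cross-validated AUROC is dropped; the globally best
set along the trace wins, with ties broken toward smaller sets and then
lexicographically (determinism). When the winning set keeps more than one
dosimetric feature, each single-dosimetric reduction is also scored — a
parsimony variant for collinear dose metrics.

**Ensemble** — the arithmetic mean of member predicted probabilities
(PLR + GBT), fitted per fold on shared fold assignments. For external
cohorts the five fold models are frozen and their predictions averaged.

## Evaluation and probes

AUROC is the tie-corrected concordance probability (midrank convention);
average precision is the step-wise sum Σ Δrecall × precision. Both are
cross-checked in the tests against brute-force oracles (exhaustive pair
counting; direct summation — the per-positive sum assumes distinct scores,
so tied-score instances are exercised only for AUROC, where midranks define
the answer). Fold ROC curves are averaged vertically: TPR linearly
interpolated on a fixed 101-point FPR grid, then averaged; the mean curve's
trapezoidal area is reported alongside the mean of member AUROCs.

The behavior probe sets one feature to each of ~50 grid values spanning its
observed range (the grid always contains the feature's mean) for *every*
patient and records the signed change in predicted probability relative to
the prediction at the mean; curves report the per-grid-point mean ± 1 SD
over patients, optionally per stratum (the reference mean stays the
whole-cohort mean, so curves are comparable across strata and are exactly 0
at the mean grid point). A signed difference is used rather than a ratio —
ratios are undefined for near-zero-risk patients and the zero-centred band
is the interpretable object. The ±SD band is over patients, not folds.

## Numerical choices and degenerate inputs

- Volume-sum tolerance 10⁻⁶ (silent), 1 % (warn + renormalise), else reject.
- Bisection: 60 iterations for grade thresholds and up to 200 for intercept
  calibration (tolerance 10⁻⁴ on mean risk); non-convergence raises.
- Monotone audits use a −10⁻¹² slack for float noise; the constraint itself
  tolerates zero violations.
- Single-class outcomes, all-missing columns, zero-range probe features,
  constant cumulative DVHs, and grade-3 baselines all raise explicit errors
  rather than degrade silently.
- Experiment sizes used by the shipped checks: n = 201 for cohort-shape
  checks, 2000 for discrimination recovery, 10 000 for moment and
  prevalence checks, 20 000 for coefficient recovery — sizes at which the
  binomial/SE tolerances quoted in the tests are meaningful.

## Known limitations

- No probability calibration to absolute NTCP: predicted scores rank
  patients; their absolute level is cohort-calibrated only through the
  synthetic intercept. Calibration to an external cohort is future work.
- Plain LQ (no linear tail) may overstate EQD2 for extreme dose-per-fraction
  SBRT bins.
- The imputation model is linear and unchained by design.
- CP2+/CTCAE2+ are generated as correlated by-products, not mechanisms of
  their own; model claims are made for ALBI1+ only.
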