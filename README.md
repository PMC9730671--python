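# ntcp-albi

Machine-learning normal tissue complication probability (NTCP) modelling for
radiation-induced liver toxicity in hepatocellular carcinoma, with the
albumin–bilirubin (ALBI) grade increase as the primary endpoint.

## Who this is for

Radiation oncology physicists and outcomes researchers who want a tested,
reproducible pipeline for the full chain from treatment-planning exports to a
cross-validated risk model:

1. **DVH reduction** — normal-liver dose–volume histograms (cumulative or
   differential, fraction/percent/cm³) are converted per dose bin to the
   equieffective dose in 2-Gy fractions (EQD2, linear–quadratic model with
   α/β = 2 Gy for liver) and reduced to the generalized equivalent uniform
   dose

   gEUD(a) = ( Σᵢ vᵢ Dᵢᵃ )^(1/a)

   swept over volume-effect parameters a ∈ {0.01, 0.05, 0.1, 0.5, 1.0, 2.0};
   a = 1 is the mean liver dose (MLD).
2. **Liver-function features** — ALBI score
   (0.66·log₁₀ bilirubin[µmol/L] − 0.085·albumin[g/L]), ALBI grading
   (grade 1 ≤ −2.60 < grade 2 ≤ −1.39 < grade 3), Child–Pugh points, and the
   engineered *ALBI score until next grade* (distance from the baseline score
   to the next grade threshold — small distance ⇒ high toxicity risk).
3. **Endpoints** — ALBI1+ (grade increase ≥ 1), CP2+ (Child–Pugh increase
   ≥ 2), CTCAE2+ transaminitis (AST/ALT ≥ 3× ULN or ≥ 3× abnormal baseline).
4. **Risk models** — penalized logistic regression (PLR), random forest (RF),
   and gradient-boosted trees (GBT) with **monotone +1 constraints on
   dosimetric inputs** (risk never decreases with dose), recursive feature
   elimination, stratified 5-fold cross-validation, and a PLR+GBT
   prediction-averaging ensemble.
5. **Behavior probes** — empirical effect curves (mean ± SD change in
   predicted risk while sweeping one input over its observed range) for
   auditing a fitted model against dose–toxicity domain knowledge.

Because real patient cohorts of this kind are not public, the package ships a
first-class **synthetic cohort generator** that reproduces the marginal
structure of a 201-patient liver-radiotherapy cohort (age 61.7 ± 11.7 y, MLD
17.6 ± 8.0 Gy, normal liver volume 1231 ± 456 cm³, ~21 % baseline ALBI
grade 1, 43.1 % ALBI1+ prevalence) with a *known* logistic toxicity
mechanism, so every downstream stage can be validated against ground truth.

## Worked example

```python
from ntcp_albi import CohortSpec, NTCPModel, build_feature_matrix, generate_cohort
from ntcp_albi.clinical import FEATURE_PRESETS

records, labels, true_risk = generate_cohort(CohortSpec(n_patients=201), seed=0)
y = labels["albi1plus"].astype(bool).to_numpy()
X = build_feature_matrix(records, FEATURE_PRESETS["selected_tree"])

model = NTCPModel(y, X, family="gbt", seed=0)   # monotone dose constraint applied
print(model.fit_cv().summary())
print(model.fit().summary())
```

prints

```
GBT 5-fold CV  AUROC 0.7579 +/- 0.0361  [0.715, 0.732, 0.741, 0.793, 0.808]
features: ast, albi_score_until_next_grade, baseline_albi_score, total_bilirubin, normal_liver_volume, mld
NTCP model  family=gbt  features=6  params={'learning_rate': 0.1, 'max_depth': 3, 'n_estimators': 16}
----------------------------------------------------------------
feature                          gini importance
ast                                       0.1299
albi_score_until_next_grade               0.3705
baseline_albi_score                       0.1045
total_bilirubin                           0.1328
normal_liver_volume                       0.1151
mld                                       0.1472
```

The held-out AUROC is the discrimination of the cross-validated model; the
Gini importances show the engineered ALBI-distance feature dominating (about
2.5× any other input), with the mean liver dose the strongest dosimetric
contributor. Averaging the best PLR and GBT models raises discrimination
further (`ensemble_crossval`; on this cohort 0.7791 ± 0.0261). At n = 2000
the ensemble reaches ≈ 0.81, within ~0.01 of the generator's oracle AUROC.

The same pipeline runs end to end from the shell:

```bash
ntcp-albi run --seed 1 --out-dir run1           # simulate -> train -> evaluate -> probe
ntcp-albi simulate --n 201 --seed 1 --out-dir cohort1
```

`run` writes the cohort, feature matrix, per-family model directories
(fold AUROCs, importances, ROC curves), external-cohort metrics, effect
curves and a markdown report, all reproducible bit-for-bit from the seed.

## Layout

| module | contents |
|---|---|
| `ntcp_albi.dvh` | DVH containers, file reading, EQD2, gEUD |
| `ntcp_albi.clinical` | ALBI/Child–Pugh scores, endpoints, imputation, feature matrix |
| `ntcp_albi.cohort` | synthetic cohort generator and risk mechanism |
| `ntcp_albi.model` | `NTCPModel` / results objects, CV, RFE, ensembling |
| `ntcp_albi.evaluate` | AUROC/AP, ROC/PR curves, averaging, effect probes |
| `ntcp_albi.pipeline` / `ntcp_albi.cli` | experiment orchestration and `ntcp-albi` CLI |

See `docs/methods.md` for the modelling assumptions, generator design and
numerical choices.
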