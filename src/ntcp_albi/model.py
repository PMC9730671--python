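"""Risk-model fitting: penalized logistic regression, random forest, and
monotonicity-constrained gradient-boosted trees, with recursive feature
elimination, stratified 5-fold cross-validation and PLR+GBT ensembling.

The public surface follows the Model/Results idiom: build an
:class:`NTCPModel` from a feature matrix and binary outcome, call ``fit()``
for a single fitted model (:class:`NTCPResults`) or ``fit_cv()`` for the
cross-validated bundle (:class:`NTCPCVResults`) that carries per-fold
models, ROC curves, out-of-fold predictions and a ``summary()`` table.

Gradient-boosted trees are fitted with monotone (+1) constraints on the
dosimetric inputs (total dose, MLD, any gEUD sweep entry): predicted risk
is forced non-decreasing in delivered dose, encoding the dose-toxicity
prior directly in the model class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import SimpleNamespace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
import xgboost as xgb

from .clinical import FeatureSetSpec

__all__ = [
    "ModelSpec",
    "NTCPModel",
    "NTCPResults",
    "NTCPCVResults",
    "EnsembleModel",
    "RFEResult",
    "fit_model",
    "predict_proba",
    "crossval_5fold",
    "recursive_feature_elimination",
    "ensemble_crossval",
    "default_monotone_constraints",
    "DOSIMETRIC_FEATURES",
]

FAMILIES = ("plr", "rf", "gbt")

#: default hyperparameter grids (overridable per ModelSpec)
DEFAULT_GRIDS = {
    "plr": {"C": tuple(10.0 ** k for k in range(-2, 4))},  # inverse of penalty 10^{-3..2}
    "rf": {"max_depth": (3, 5, None), "max_features": ("sqrt", 1.0)},
    "gbt": {"learning_rate": (0.03, 0.1), "max_depth": (2, 3, 4)},
}
GBT_MAX_ROUNDS = 300
GBT_EARLY_STOP = 30
RF_N_TREES = 500
PLR_INNER_FOLDS = 5
TREE_INNER_FOLDS = 3


def _is_dosimetric(name: str) -> bool:
    return name in ("total_dose", "mld") or name.startswith("geud_a")


DOSIMETRIC_FEATURES = _is_dosimetric


def default_monotone_constraints(features) -> dict:
    """+1 (non-decreasing risk) on every dosimetric feature present."""
    return {f: 1 for f in features if _is_dosimetric(f)}


@dataclass(frozen=True)
class ModelSpec:
    """Family, feature set, hyperparameter grid and constraints for one model."""

    family: str
    features: tuple
    param_grid: Optional[dict] = None
    monotone_constraints: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        feats = tuple(FeatureSetSpec(tuple(self.features)))
        object.__setattr__(self, "features", feats)
        if self.monotone_constraints:
            if self.family != "gbt":
                raise ValueError("monotone constraints are supported for gbt only")
            missing = [f for f in self.monotone_constraints if f not in feats]
            if missing:
                raise ValueError(f"constrained feature(s) not in feature set: {missing}")
            if any(v not in (0, 1) for v in self.monotone_constraints.values()):
                raise ValueError("monotone constraint values must be +1 or 0")

    @classmethod
    def with_default_constraints(cls, family, features, **kw) -> "ModelSpec":
        mono = default_monotone_constraints(features) if family == "gbt" else {}
        return cls(family=family, features=tuple(features), monotone_constraints=mono, **kw)


def _check_xy(X: pd.DataFrame, y: np.ndarray):
    y = np.asarray(y).astype(int)
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values; impute first")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    return y


def _inner_cv_auc(make_est, X, y, n_folds, seed):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y):
        est = make_est()
        est.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[va], est.predict_proba(X[va])[:, 1]))
    return float(np.mean(aucs))


def _fit_plr(X, y, grid, seed):
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    best_auc, best_C = -np.inf, None
    for C in grid["C"]:
        auc = _inner_cv_auc(
            lambda C=C: LogisticRegression(C=C, max_iter=5000),
            Xs, y, PLR_INNER_FOLDS, seed,
        )
        if auc > best_auc:
            best_auc, best_C = auc, C
    est = LogisticRegression(C=best_C, max_iter=5000).fit(Xs, y)
    return est, scaler, {"C": best_C}


def _fit_rf(X, y, grid, seed):
    best_auc, best_params = -np.inf, None
    for depth in grid["max_depth"]:
        for mf in grid["max_features"]:
            auc = _inner_cv_auc(
                lambda d=depth, m=mf: RandomForestClassifier(
                    n_estimators=RF_N_TREES, max_depth=d, max_features=m,
                    random_state=seed, n_jobs=1,
                ),
                X, y, TREE_INNER_FOLDS, seed,
            )
            if auc > best_auc:
                best_auc, best_params = auc, {"max_depth": depth, "max_features": mf}
    est = RandomForestClassifier(
        n_estimators=RF_N_TREES, random_state=seed, n_jobs=1, **best_params
    ).fit(X, y)
    return est, None, best_params


def _fit_gbt(X, y, grid, seed, mono_tuple):
    skf = StratifiedKFold(n_splits=TREE_INNER_FOLDS, shuffle=True, random_state=seed)
    best_auc, best_params, best_rounds = -np.inf, None, GBT_MAX_ROUNDS
    for lr in grid["learning_rate"]:
        for depth in grid["max_depth"]:
            aucs, rounds = [], []
            for tr, va in skf.split(X, y):
                est = xgb.XGBClassifier(
                    n_estimators=GBT_MAX_ROUNDS, learning_rate=lr, max_depth=depth,
                    monotone_constraints=mono_tuple, tree_method="hist",
                    eval_metric="auc", early_stopping_rounds=GBT_EARLY_STOP,
                    random_state=seed, n_jobs=1, verbosity=0,
                )
                est.fit(X[tr], y[tr], eval_set=[(X[va], y[va])], verbose=False)
                aucs.append(est.best_score)
                rounds.append(est.best_iteration + 1)
            auc = float(np.mean(aucs))
            if auc > best_auc:
                best_auc = auc
                best_params = {"learning_rate": lr, "max_depth": depth}
                best_rounds = int(np.round(np.mean(rounds)))
    est = xgb.XGBClassifier(
        n_estimators=max(best_rounds, 1), monotone_constraints=mono_tuple,
        tree_method="hist", eval_metric="logloss", random_state=seed, n_jobs=1,
        verbosity=0, **best_params,
    ).fit(X, y)
    return est, None, {**best_params, "n_estimators": max(best_rounds, 1)}


class NTCPResults:
    """A fitted risk model: estimator, chosen hyperparameters, importances.

    ``params`` holds standardized coefficients for PLR and is None for the
    tree families, whose ``importances`` are Gini importances normalised to
    sum to 1.  ``predict(X)`` returns the predicted toxicity probability.
    """

    def __init__(self, spec: ModelSpec, estimator, scaler, chosen_params: dict):
        self.spec = spec
        self.estimator = estimator
        self.scaler = scaler
        self.chosen_params = chosen_params
        feats = list(spec.features)
        if spec.family == "plr":
            coefs = pd.Series(estimator.coef_[0], index=feats, name="coefficient")
            self.params = coefs
            self.importances = coefs.abs().rename("importance")
            self.intercept = float(estimator.intercept_[0])
        else:
            imp = np.asarray(estimator.feature_importances_, dtype=float)
            total = imp.sum()
            self.params = None
            self.intercept = None
            self.importances = pd.Series(
                imp / total if total > 0 else imp, index=feats, name="importance"
            )

    @property
    def feature_names(self) -> tuple:
        return self.spec.features

    def _check_columns(self, X: pd.DataFrame):
        missing = [f for f in self.spec.features if f not in X.columns]
        extra = [c for c in X.columns if c not in self.spec.features]
        if missing or extra:
            raise ValueError(f"feature mismatch: missing {missing}, unexpected {extra}")
        return X[list(self.spec.features)]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted probability of toxicity, one value in [0,1] per row."""
        X = self._check_columns(X)
        arr = X.to_numpy(dtype=float)
        if self.scaler is not None:
            arr = self.scaler.transform(arr)
        return self.estimator.predict_proba(arr)[:, 1]

    # alias so results objects, CV bundles and ensembles are interchangeable scorers
    predict_proba = predict

    def summary(self) -> str:
        lines = [
            f"NTCP model  family={self.spec.family}  "
            f"features={len(self.spec.features)}  params={self.chosen_params}",
            "-" * 64,
        ]
        table = self.params if self.params is not None else self.importances
        label = "coef(std)" if self.params is not None else "gini importance"
        lines.append(f"{'feature':<32}{label:>16}")
        for name, v in table.items():
            lines.append(f"{name:<32}{v:>16.4f}")
        if self.intercept is not None:
            lines.append(f"{'(intercept)':<32}{self.intercept:>16.4f}")
        return "\n".join(lines)


class NTCPCVResults:
    """Stratified k-fold cross-validation bundle for one model family."""

    def __init__(self, spec, fold_assignments, fold_models, oof_pred, y, fold_auroc):
        from .evaluate import ROCCurve  # deferred: evaluate imports nothing from here

        self.spec = spec
        self.fold_assignments = fold_assignments
        self.fold_models = fold_models
        self.oof_predictions = oof_pred
        self.y = y
        self.fold_auroc = np.asarray(fold_auroc, dtype=float)
        self.mean_auroc = float(self.fold_auroc.mean())
        self.sd_auroc = float(self.fold_auroc.std(ddof=0))
        self.roc_curves = [
            ROCCurve.from_scores(y[fold_assignments == k], oof_pred[fold_assignments == k])
            for k in range(len(fold_models))
        ]

    @property
    def n_folds(self) -> int:
        return len(self.fold_models)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Average of the frozen fold models' predictions (external scoring)."""
        return np.mean([m.predict(X) for m in self.fold_models], axis=0)

    predict_proba = predict

    def coefficient_distribution(self) -> pd.DataFrame:
        """Per-feature fold coefficients (plr) or Gini importances (rf/gbt)."""
        from .evaluate import coefficient_distribution

        return coefficient_distribution(self)

    def summary(self) -> str:
        per_fold = ", ".join(f"{a:.3f}" for a in self.fold_auroc)
        lines = [
            f"{self.spec.family.upper()} {self.n_folds}-fold CV  "
            f"AUROC {self.mean_auroc:.4f} +/- {self.sd_auroc:.4f}  [{per_fold}]",
            f"features: {', '.join(self.spec.features)}",
        ]
        return "\n".join(lines)


class NTCPModel:
    """NTCP risk model builder (Model/Results idiom).

    Parameters
    ----------
    y : array-like of 0/1
        Binary toxicity outcome (e.g. ALBI1+).
    X : DataFrame
        Complete numeric feature matrix; columns not in ``features`` are ignored.
    family : {"plr", "rf", "gbt"}
    features : sequence of names, optional (default: all X columns)
    monotone : "auto" applies +1 constraints to dosimetric features for gbt;
        a dict gives explicit constraints; None disables.
    """

    def __init__(self, y, X: pd.DataFrame, family: str = "gbt", features=None,
                 monotone="auto", param_grid: Optional[dict] = None, seed: int = 0):
        features = tuple(features) if features is not None else tuple(X.columns)
        if monotone == "auto":
            mono = default_monotone_constraints(features) if family == "gbt" else {}
        else:
            mono = dict(monotone or {})
        self.spec = ModelSpec(
            family=family, features=features, param_grid=param_grid,
            monotone_constraints=mono, seed=seed,
        )
        self.X = X[list(features)]
        self.y = _check_xy(self.X, y)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "albi1plus", features=None, **kw):
        if outcome not in df.columns:
            raise ValueError(f"outcome column {outcome!r} not in dataframe")
        feats = features if features is not None else [c for c in df.columns if c != outcome]
        return cls(df[outcome].to_numpy(), df, features=tuple(feats), **kw)

    def fit(self) -> NTCPResults:
        return fit_model(self.spec, self.X, self.y)

    def fit_cv(self, n_folds: int = 5) -> NTCPCVResults:
        return crossval_5fold(self.spec, self.X, self.y, seed=self.spec.seed, n_folds=n_folds)


def fit_model(spec: ModelSpec, X: pd.DataFrame, y) -> NTCPResults:
    """Fit one model; hyperparameters chosen by inner cross-validated AUROC."""
    if not isinstance(spec, ModelSpec):
        raise TypeError("spec must be a ModelSpec")
    X = X[list(spec.features)]
    y = _check_xy(X, y)
    grid = {**DEFAULT_GRIDS[spec.family], **(spec.param_grid or {})}
    arr = X.to_numpy(dtype=float)
    if spec.family == "plr":
        est, scaler, chosen = _fit_plr(arr, y, grid, spec.seed)
    elif spec.family == "rf":
        est, scaler, chosen = _fit_rf(arr, y, grid, spec.seed)
    else:
        mono_tuple = tuple(spec.monotone_constraints.get(f, 0) for f in spec.features)
        est, scaler, chosen = _fit_gbt(arr, y, grid, spec.seed, mono_tuple)
    return NTCPResults(spec, est, scaler, chosen)


def predict_proba(model, X: pd.DataFrame) -> np.ndarray:
    """Probability predictions from any fitted model/ensemble object."""
    return model.predict_proba(X)


def crossval_5fold(spec: ModelSpec, X: pd.DataFrame, y, seed: Optional[int] = None,
                   n_folds: int = 5) -> NTCPCVResults:
    """Outcome-stratified k-fold CV with held-out predictions for every patient."""
    X = X[list(spec.features)]
    y = _check_xy(X, y)
    if len(y) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} patients for {n_folds}-fold CV")
    if min(np.bincount(y)) < n_folds:
        raise ValueError("minority class too rare to stratify into folds")
    seed = spec.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assign = np.empty(len(y), dtype=int)
    oof = np.empty(len(y), dtype=float)
    models, aucs = [], []
    for k, (tr, va) in enumerate(skf.split(X, y)):
        m = fit_model(replace(spec, seed=seed + k), X.iloc[tr], y[tr])
        p = m.predict(X.iloc[va])
        assign[va] = k
        oof[va] = p
        models.append(m)
        aucs.append(roc_auc_score(y[va], p))
    return NTCPCVResults(spec, assign, models, oof, y, aucs)


@dataclass(frozen=True)
class RFEResult:
    """Backward-elimination outcome: winning set, full trace, dosimetric variants."""

    best_features: tuple
    trace: tuple  # ((features...), mean_auroc) per step, first entry = full set
    best_auroc: float
    single_dosimetric_variants: tuple = ()  # ((features...), mean_auroc)


def recursive_feature_elimination(spec: ModelSpec, X: pd.DataFrame, y,
                                  seed: Optional[int] = None, min_features: int = 1) -> RFEResult:
    """Backward feature elimination scored by cross-validated AUROC.

    At each step the feature whose removal maximises CV AUROC is dropped; the
    globally best set along the trace wins (ties: smaller set, then
    lexicographic).  When the winning set keeps more than one dosimetric
    feature, each single-dosimetric reduction is also evaluated and reported.
    """
    if len(spec.features) < 2:
        if min_features > len(spec.features):
            raise ValueError("cannot eliminate below one feature")
        cv = crossval_5fold(spec, X, y, seed=seed)
        return RFEResult(spec.features, ((spec.features, cv.mean_auroc),), cv.mean_auroc)
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    seed = spec.seed if seed is None else seed

    def score(feats) -> float:
        sub = replace(
            spec, features=tuple(feats),
            monotone_constraints={f: v for f, v in spec.monotone_constraints.items() if f in feats},
        )
        return crossval_5fold(sub, X, y, seed=seed).mean_auroc

    current = list(spec.features)
    trace = [(tuple(current), score(current))]
    while len(current) > min_features:
        candidates = []
        for f in sorted(current):
            remaining = [g for g in current if g != f]
            candidates.append((score(remaining), f, remaining))
        best = max(candidates, key=lambda t: t[0])  # sorted() above makes ties lexicographic
        current = best[2]
        trace.append((tuple(current), best[0]))
    best_set, best_auc = max(
        trace, key=lambda t: (t[1], -len(t[0]), tuple(sorted(t[0])))
    )
    # prefer smaller sets on AUROC ties
    for feats, auc in trace:
        if auc == best_auc and len(feats) < len(best_set):
            best_set = feats

    variants = []
    dosi = [f for f in best_set if _is_dosimetric(f)]
    if len(dosi) > 1:
        for keep in sorted(dosi):
            feats = tuple(f for f in best_set if not _is_dosimetric(f) or f == keep)
            variants.append((feats, score(feats)))
    return RFEResult(tuple(best_set), tuple(trace), best_auc, tuple(variants))


class EnsembleModel:
    """Prediction-averaging ensemble; the best-performing combination is PLR + GBT."""

    def __init__(self, members: Sequence):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    predict_proba = predict


def ensemble_crossval(specs: Sequence[ModelSpec], X: pd.DataFrame, y, seed: int = 0,
                      n_folds: int = 5) -> NTCPCVResults:
    """Cross-validate a prediction-averaging ensemble on shared folds.

    Each member family is fitted per fold on its own feature set; the fold's
    held-out prediction is the member average.  Returns a CV bundle whose
    fold models are per-fold :class:`EnsembleModel`s.
    """
    all_feats = sorted({f for s in specs for f in s.features})
    Xa = X[all_feats]
    y = _check_xy(Xa, y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assign = np.empty(len(y), dtype=int)
    oof = np.empty(len(y), dtype=float)
    fold_models, aucs = [], []
    for k, (tr, va) in enumerate(skf.split(Xa, y)):
        members = [
            fit_model(replace(s, seed=seed + k), X[list(s.features)].iloc[tr], y[tr])
            for s in specs
        ]
        ens = _ColumnSlicingEnsemble(members)
        p = ens.predict_proba(X.iloc[va])
        assign[va] = k
        oof[va] = p
        fold_models.append(ens)
        aucs.append(roc_auc_score(y[va], p))
    spec = SimpleNamespace(family="ensemble", features=tuple(all_feats))
    return NTCPCVResults(spec, assign, fold_models, oof, y, aucs)


class _ColumnSlicingEnsemble(EnsembleModel):
    """Ensemble whose members select their own feature columns from a wide X."""

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.mean(
            [m.predict_proba(X[list(m.spec.features)]) for m in self.members], axis=0
        )

    predict_proba = predict
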