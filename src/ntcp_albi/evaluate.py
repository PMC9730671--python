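"""Discrimination metrics, fold-curve averaging, and empirical model probes.

AUROC is the tie-corrected concordance probability (ties count 1/2);
average precision is the step-wise area under the precision-recall curve.
Fold ROC curves are averaged vertically (TPR interpolated on a fixed
101-point FPR grid).

The behavior probe replays each patient through the model while sweeping a
single input from its observed minimum to maximum and records the change in
predicted probability relative to the prediction at the feature's mean —
an empirical partial-dependence curve with a +/- 1 SD band over patients,
the standard audit that a fitted black-box respects dose-toxicity domain
knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = [
    "ROCCurve",
    "PRCurve",
    "EffectCurve",
    "auroc",
    "average_precision",
    "average_roc",
    "probe_feature_effect",
    "coefficient_distribution",
]

_FPR_GRID = np.linspace(0.0, 1.0, 101)


def _check_labels(labels):
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (midrank tie convention)."""
    labels = _check_labels(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(_skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def average_precision(scores, labels) -> float:
    """Average precision: sum over positives of (recall step) x precision."""
    labels = _check_labels(labels)
    if labels.sum() == 0:
        raise ValueError("average precision requires at least one positive label")
    return float(_skm.average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) pairs from (0,0) to (1,1) with trapezoidal AUROC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float

    def __post_init__(self):
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")
        area = float(np.trapezoid(tpr, fpr))
        if abs(area - self.auroc) > 1e-9:
            raise ValueError("stored AUROC does not match trapezoidal area")

    @classmethod
    def from_scores(cls, labels, scores) -> "ROCCurve":
        labels = _check_labels(labels)
        fpr, tpr, _ = _skm.roc_curve(labels, scores, drop_intermediate=False)
        if fpr[0] > 0 or tpr[0] > 0:
            fpr, tpr = np.insert(fpr, 0, 0.0), np.insert(tpr, 0, 0.0)
        if fpr[-1] < 1 or tpr[-1] < 1:
            fpr, tpr = np.append(fpr, 1.0), np.append(tpr, 1.0)
        return cls(fpr, tpr, float(np.trapezoid(tpr, fpr)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


@dataclass(frozen=True)
class PRCurve:
    """(recall, precision) pairs, recall non-decreasing, with average precision."""

    recall: np.ndarray
    precision: np.ndarray
    average_precision: float

    def __post_init__(self):
        rec = np.asarray(self.recall, dtype=float)
        prec = np.asarray(self.precision, dtype=float)
        object.__setattr__(self, "recall", rec)
        object.__setattr__(self, "precision", prec)
        if np.any(np.diff(rec) < 0):
            raise ValueError("recall must be non-decreasing")
        if np.any((prec < 0) | (prec > 1)) or not 0 <= self.average_precision <= 1:
            raise ValueError("precision and AP must lie in [0, 1]")

    @classmethod
    def from_scores(cls, labels, scores) -> "PRCurve":
        labels = _check_labels(labels)
        prec, rec, _ = _skm.precision_recall_curve(labels, scores)
        return cls(rec[::-1], prec[::-1], average_precision(scores, labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"recall": self.recall, "precision": self.precision})


def average_roc(curves: Sequence[ROCCurve]) -> ROCCurve:
    """Vertical fold-curve averaging on a fixed 101-point FPR grid.

    The returned curve's ``auroc`` is the trapezoidal area of the mean
    curve; the mean of the member AUROCs is attached as
    ``mean_member_auroc`` (the two differ in general).
    """
    if not curves:
        raise ValueError("need at least one ROC curve to average")
    tprs = np.vstack([np.interp(_FPR_GRID, c.fpr, c.tpr) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    mean_tpr = np.maximum.accumulate(mean_tpr)  # guard float non-monotonicity
    out = ROCCurve(_FPR_GRID, mean_tpr, float(np.trapezoid(mean_tpr, _FPR_GRID)))
    object.__setattr__(out, "mean_member_auroc", float(np.mean([c.auroc for c in curves])))
    return out


@dataclass(frozen=True)
class EffectCurve:
    """Empirical feature-effect curve: mean +/- SD prediction change over a grid.

    ``mean_change`` is zero at the grid point equal to the feature's
    reference mean, by construction.
    """

    feature: str
    grid: np.ndarray
    mean_change: np.ndarray
    sd_change: np.ndarray
    stratum: Optional[str] = None

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mean_change", np.asarray(self.mean_change, dtype=float))
        object.__setattr__(self, "sd_change", np.asarray(self.sd_change, dtype=float))
        if np.any(np.diff(grid) <= 0):
            raise ValueError("effect grid must be strictly increasing")
        if np.any(self.sd_change < 0):
            raise ValueError("SD band must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"grid_value": self.grid, "mean_change": self.mean_change, "sd_change": self.sd_change}
        )
        if self.stratum is not None:
            df["stratum"] = self.stratum
        return df


def probe_feature_effect(model, X: pd.DataFrame, feature: str, grid_size: int = 50,
                         strata: Optional[pd.Series] = None):
    """Sweep one input over its observed range and record prediction changes.

    For every patient and grid value v, change = p(x with feature=v) -
    p(x with feature=mean).  Returns one :class:`EffectCurve` (mean and SD
    of the change over patients per grid point), or a dict of curves keyed
    by stratum when ``strata`` (a grouping aligned with X's rows) is given;
    the reference mean is always the whole-cohort mean.
    """
    if feature not in X.columns:
        raise ValueError(f"feature {feature!r} not in matrix columns")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    col = X[feature].to_numpy(dtype=float)
    lo, hi = float(col.min()), float(col.max())
    if hi - lo <= 0:
        raise ValueError(f"feature {feature!r} has zero observed range; nothing to probe")
    mean = float(col.mean())
    grid = np.unique(np.append(np.linspace(lo, hi, grid_size), mean))

    Xref = X.copy()
    Xref[feature] = mean
    baseline = np.asarray(model.predict_proba(Xref), dtype=float)
    changes = np.empty((len(X), grid.size))
    Xv = X.copy()
    for j, v in enumerate(grid):
        Xv[feature] = v
        changes[:, j] = np.asarray(model.predict_proba(Xv), dtype=float) - baseline

    def _curve(mask, label):
        sub = changes[mask]
        return EffectCurve(feature, grid, sub.mean(axis=0), sub.std(axis=0, ddof=0), label)

    if strata is None:
        return _curve(np.ones(len(X), dtype=bool), None)
    strata = pd.Series(np.asarray(strata), index=X.index)
    return {
        str(s): _curve((strata == s).to_numpy(), str(s))
        for s in sorted(strata.unique(), key=str)
    }


def coefficient_distribution(cv) -> pd.DataFrame:
    """Per-feature fold-model coefficients (PLR) or Gini importances (RF/GBT).

    Returns a DataFrame with one row per fold plus a ``mean`` row.  Raises
    when the CV bundle mixes model families (e.g. an ensemble).
    """
    with_spec = [m for m in cv.fold_models if hasattr(m, "spec")]
    fams = {m.spec.family for m in with_spec}
    if len(with_spec) != len(cv.fold_models) or len(fams) != 1:
        raise ValueError("coefficient_distribution needs fold models of a single family")
    family = fams.pop()
    rows = []
    for m in cv.fold_models:
        rows.append(m.params if family == "plr" else m.importances)
    df = pd.DataFrame(rows, index=[f"fold{k}" for k in range(len(rows))])
    df.loc["mean"] = df.mean(axis=0)
    return df
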