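"""ALBI / Child-Pugh scoring, toxicity endpoints, imputation and feature assembly.

The albumin-bilirubin (ALBI) score is the fully quantitative liver-function
index

    ALBI = 0.66 * log10(bilirubin [umol/L]) - 0.085 * albumin [g/L]

graded 1 (score <= -2.60), 2 (-2.60 < score <= -1.39) or 3 (score > -1.39).
The engineered model feature "ALBI score until next grade" is the (signed-
positive) distance from a patient's baseline score to the next grade
threshold: patients sitting close to the boundary need only a small
post-treatment deterioration to register a grade increase.

Toxicity endpoints supported: ALBI1+ (grade increase >= 1), CP2+ (Child-Pugh
score increase >= 2) and CTCAE2+ transaminitis (AST or ALT >= 3x the upper
limit of normal when the baseline is normal, or >= 3x baseline otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dvh import DifferentialDVH, RadbioParams, DEFAULT_A_VALUES, eqd2_transform, geud

__all__ = [
    "ALBI_GRADE1_MAX",
    "ALBI_GRADE2_MAX",
    "LabPanel",
    "PatientRecord",
    "EndpointLabels",
    "FeatureSetSpec",
    "FEATURE_VOCABULARY",
    "FEATURE_PRESETS",
    "albi_score",
    "albi_score_conventional",
    "albi_grade",
    "albi_score_until_next_grade",
    "child_pugh_points",
    "classify_endpoints",
    "impute_missing",
    "build_feature_matrix",
    "BILIRUBIN_MGDL_TO_UMOLL",
]

#: Grade boundaries (closed on the lower grade): grade 1 iff score <= -2.60,
#: grade 2 iff score <= -1.39.
ALBI_GRADE1_MAX = -2.60
ALBI_GRADE2_MAX = -1.39

#: Unit conversion: total bilirubin mg/dL -> umol/L.
BILIRUBIN_MGDL_TO_UMOLL = 17.1

#: Default upper limits of normal for transaminases (U/L), configurable.
DEFAULT_ULN_AST = 40.0
DEFAULT_ULN_ALT = 40.0


def albi_score(total_bilirubin_umol_l: float, albumin_g_l: float) -> float:
    """ALBI score from bilirubin in umol/L and albumin in g/L."""
    if not (total_bilirubin_umol_l > 0 and albumin_g_l > 0):
        raise ValueError("bilirubin and albumin must be positive")
    return 0.66 * math.log10(total_bilirubin_umol_l) - 0.085 * albumin_g_l


def albi_score_conventional(total_bilirubin_mg_dl: float, albumin_g_dl: float) -> float:
    """ALBI score from US-conventional units (bilirubin mg/dL, albumin g/dL)."""
    return albi_score(total_bilirubin_mg_dl * BILIRUBIN_MGDL_TO_UMOLL, albumin_g_dl * 10.0)


def albi_grade(score: float) -> int:
    """ALBI grade 1/2/3 for a finite score."""
    if not math.isfinite(score):
        raise ValueError("ALBI score must be finite")
    if score <= ALBI_GRADE1_MAX:
        return 1
    if score <= ALBI_GRADE2_MAX:
        return 2
    return 3


def albi_score_until_next_grade(score: float, grade: int) -> float:
    """Distance (>= 0) from a baseline score to the next grade threshold.

    Grade 1 patients are measured against -2.60, grade 2 against -1.39.
    Grade 3 has no next grade (such patients are excluded at baseline).
    """
    if grade == 3:
        raise ValueError("grade 3 has no next grade threshold (excluded at baseline)")
    if grade not in (1, 2):
        raise ValueError(f"grade must be 1 or 2, got {grade!r}")
    if albi_grade(score) != grade:
        raise ValueError(f"score {score} is not grade {grade}")
    threshold = ALBI_GRADE1_MAX if grade == 1 else ALBI_GRADE2_MAX
    return threshold - score


_ASCITES = ("none", "slight", "moderate+")
_ENCEPH = ("none", "grade1-2", "grade3-4")


def child_pugh_points(
    total_bilirubin_mg_dl: float,
    albumin_g_dl: float,
    inr: float,
    ascites: str,
    encephalopathy: str,
) -> int:
    """Child-Pugh score (5-15) from the standard five 1-3-point components.

    Cut-offs: bilirubin <2 / 2-3 / >3 mg/dL; albumin >3.5 / 2.8-3.5 / <2.8
    g/dL; INR <1.7 / 1.7-2.3 / >2.3; ascites none / slight / moderate+;
    encephalopathy none / grade 1-2 / grade 3-4.  Missing components raise.
    """
    comps = (total_bilirubin_mg_dl, albumin_g_dl, inr, ascites, encephalopathy)
    if any(c is None for c in comps):
        raise ValueError("all five Child-Pugh components must be present")
    if ascites not in _ASCITES:
        raise ValueError(f"ascites must be one of {_ASCITES}")
    if encephalopathy not in _ENCEPH:
        raise ValueError(f"encephalopathy must be one of {_ENCEPH}")
    pts = 0
    pts += 1 if total_bilirubin_mg_dl < 2 else (2 if total_bilirubin_mg_dl <= 3 else 3)
    pts += 1 if albumin_g_dl > 3.5 else (2 if albumin_g_dl >= 2.8 else 3)
    pts += 1 if inr < 1.7 else (2 if inr <= 2.3 else 3)
    pts += 1 + _ASCITES.index(ascites)
    pts += 1 + _ENCEPH.index(encephalopathy)
    return pts


@dataclass
class LabPanel:
    """One time point's liver panel; any field may be missing (None)."""

    ast: Optional[float] = None
    alt: Optional[float] = None
    alp: Optional[float] = None
    total_bilirubin: Optional[float] = None  # mg/dL
    albumin: Optional[float] = None  # g/dL
    inr: Optional[float] = None

    def __post_init__(self):
        for name in ("ast", "alt", "alp", "total_bilirubin", "albumin"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when present (got {v!r})")
        if self.inr is not None and self.inr < 0.5:
            raise ValueError(f"inr must be >= 0.5 when present (got {self.inr!r})")

    def albi_score(self) -> Optional[float]:
        if self.total_bilirubin is None or self.albumin is None:
            return None
        return albi_score_conventional(self.total_bilirubin, self.albumin)


@dataclass
class PatientRecord:
    """One patient's clinical, laboratory, fractionation and DVH data."""

    patient_id: str
    age: float
    sex: str  # "male" / "female"
    hepatitis_b: bool
    hepatitis_c: bool
    main_pvt: bool
    prior_surgery: bool
    prior_tace: bool
    tumor_diameter: float  # cm
    tumor_volume: float  # cm3
    normal_liver_volume: float  # cm3
    total_dose: float  # Gy
    n_fractions: int
    technique: str  # "3D-CRT" / "IMRT/VMAT" / "SBRT"
    baseline_labs: LabPanel
    worst_labs: LabPanel
    baseline_albi_score: float
    baseline_albi_grade: int
    baseline_cp: Optional[int] = None
    worst_cp: Optional[int] = None
    dvh: Optional[DifferentialDVH] = None
    geud_profile: Optional[dict] = None  # precomputed {a: gEUD}, EQD2-corrected

    def __post_init__(self):
        if self.baseline_albi_grade not in (1, 2):
            raise ValueError("baseline ALBI grade must be 1 or 2 (grade 3 excluded)")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if not self.total_dose > 0:
            raise ValueError("total_dose must be > 0")
        for name in ("tumor_volume", "normal_liver_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class EndpointLabels:
    """Binary toxicity endpoints; None marks an endpoint that could not be graded."""

    albi1plus: Optional[bool]
    cp2plus: Optional[bool] = None
    ctcae2plus: Optional[bool] = None


def _ctcae_enzyme(baseline: Optional[float], worst: Optional[float], uln: float) -> Optional[bool]:
    if baseline is None or worst is None:
        return None
    if baseline <= uln:
        return worst >= 3.0 * uln
    return worst >= 3.0 * baseline


def classify_endpoints(
    r: PatientRecord,
    uln_ast: float = DEFAULT_ULN_AST,
    uln_alt: float = DEFAULT_ULN_ALT,
) -> EndpointLabels:
    """Grade the ALBI1+, CP2+ and CTCAE2+ endpoints for one patient.

    Endpoints whose required worst values are absent come back as None
    (unavailable), never silently False.
    """
    worst_score = r.worst_labs.albi_score()
    if worst_score is None:
        albi1 = None
    else:
        albi1 = albi_grade(worst_score) - r.baseline_albi_grade >= 1

    if r.baseline_cp is not None and r.worst_cp is not None:
        cp2 = r.worst_cp - r.baseline_cp >= 2
    else:
        cp2 = None

    flags = [
        _ctcae_enzyme(r.baseline_labs.ast, r.worst_labs.ast, uln_ast),
        _ctcae_enzyme(r.baseline_labs.alt, r.worst_labs.alt, uln_alt),
    ]
    known = [f for f in flags if f is not None]
    ctcae2 = (any(known) if known else None)
    # one enzyme positive decides the endpoint even if the other is missing;
    # both missing leaves it ungradeable
    if ctcae2 is False and None in flags:
        ctcae2 = None
    return EndpointLabels(albi1plus=albi1, cp2plus=cp2, ctcae2plus=ctcae2)


def impute_missing(table: pd.DataFrame, high_missingness: float = 0.5):
    """Single-pass per-column linear-regression imputation.

    Each numeric column with gaps is regressed (ordinary least squares, with
    intercept) on all other numeric columns, temporarily mean-filled, using
    the rows where the target column is observed; predictions for the missing
    cells are clamped to the column's observed range.  Columns are processed
    in fixed (left-to-right) order with no chaining, so the result is
    deterministic and observed cells are untouched.  Non-numeric columns are
    filled with their mode.

    Returns ``(completed_table, report)`` where report maps column name to
    ``{"n_missing", "method", "high_missingness"}``.
    """
    out = table.copy()
    report: dict = {}
    num_cols = [c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])]
    for c in out.columns:
        if not out[c].isna().any():
            continue
        n_miss = int(out[c].isna().sum())
        if n_miss == len(out):
            raise ValueError(f"column {c!r} is entirely missing; cannot impute")
        flag = n_miss / len(out) > high_missingness
        if c not in num_cols:
            mode = table[c].mode(dropna=True).iloc[0]
            out.loc[out[c].isna(), c] = mode
            report[c] = {"n_missing": n_miss, "method": "mode", "high_missingness": flag}
            continue
        predictors = [p for p in num_cols if p != c]
        obs = table[c].notna()
        if obs.sum() < 2:  # too few observations to regress: fall back to the mean
            out.loc[~obs, c] = table.loc[obs, c].astype(float).mean()
            report[c] = {"n_missing": n_miss, "method": "mean", "high_missingness": flag}
            continue
        if predictors:
            Xfull = table[predictors].astype(float)
            Xfull = Xfull.fillna(Xfull.mean())
            X = np.column_stack([np.ones(len(table)), Xfull.to_numpy()])
            beta, *_ = np.linalg.lstsq(X[obs.to_numpy()], table.loc[obs, c].astype(float), rcond=None)
            pred = X[(~obs).to_numpy()] @ beta
        else:
            pred = np.full(n_miss, table.loc[obs, c].astype(float).mean())
        lo, hi = table.loc[obs, c].min(), table.loc[obs, c].max()
        out.loc[~obs, c] = np.clip(pred, lo, hi)
        report[c] = {"n_missing": n_miss, "method": "ols", "high_missingness": flag}
    return out, report


def _geud_lookup(r: PatientRecord, a: float, radbio: RadbioParams) -> float:
    """EQD2-corrected gEUD at volume-effect a for one record (DVH or cached profile)."""
    if r.geud_profile is not None and float(a) in r.geud_profile:
        return float(r.geud_profile[float(a)])
    if r.dvh is None:
        raise ValueError(f"patient {r.patient_id}: no DVH or precomputed gEUD at a={a}")
    p = RadbioParams(alpha_beta=radbio.alpha_beta, n_fractions=r.n_fractions, a_values=radbio.a_values)
    return geud(eqd2_transform(r.dvh, p), a)


def _opt(v):
    return np.nan if v is None else v


# name -> extractor(record, radbio)
FEATURE_VOCABULARY = {
    "age": lambda r, rb: r.age,
    "sex_female": lambda r, rb: float(r.sex == "female"),
    "hepatitis_b": lambda r, rb: float(r.hepatitis_b),
    "hepatitis_c": lambda r, rb: float(r.hepatitis_c),
    "main_pvt": lambda r, rb: float(r.main_pvt),
    "prior_surgery": lambda r, rb: float(r.prior_surgery),
    "prior_tace": lambda r, rb: float(r.prior_tace),
    "tumor_diameter": lambda r, rb: r.tumor_diameter,
    "tumor_volume": lambda r, rb: r.tumor_volume,
    "normal_liver_volume": lambda r, rb: r.normal_liver_volume,
    "total_dose": lambda r, rb: r.total_dose,
    "n_fractions": lambda r, rb: float(r.n_fractions),
    "dose_per_fraction": lambda r, rb: r.total_dose / r.n_fractions,
    "technique_3dcrt": lambda r, rb: float(r.technique == "3D-CRT"),
    "technique_imrt_vmat": lambda r, rb: float(r.technique == "IMRT/VMAT"),
    "technique_sbrt": lambda r, rb: float(r.technique == "SBRT"),
    "ast": lambda r, rb: _opt(r.baseline_labs.ast),
    "alt": lambda r, rb: _opt(r.baseline_labs.alt),
    "alp": lambda r, rb: _opt(r.baseline_labs.alp),
    "total_bilirubin": lambda r, rb: _opt(r.baseline_labs.total_bilirubin),
    "albumin": lambda r, rb: _opt(r.baseline_labs.albumin),
    "inr": lambda r, rb: _opt(r.baseline_labs.inr),
    "baseline_cp": lambda r, rb: _opt(r.baseline_cp),
    "baseline_albi_score": lambda r, rb: r.baseline_albi_score,
    "baseline_albi_grade": lambda r, rb: float(r.baseline_albi_grade),
    "albi_score_until_next_grade": lambda r, rb: albi_score_until_next_grade(
        r.baseline_albi_score, r.baseline_albi_grade
    ),
    "mld": lambda r, rb: _geud_lookup(r, 1.0, rb),
}
for _a in DEFAULT_A_VALUES:
    if _a != 1.0:
        FEATURE_VOCABULARY[f"geud_a{_a:g}"] = (
            lambda r, rb, _a=_a: _geud_lookup(r, _a, rb)
        )

#: Named feature presets: per-family selected input sets and the univariate baseline.
FEATURE_PRESETS = {
    "univariate_albi": ("albi_score_until_next_grade",),
    "selected_plr": (
        "age",
        "albi_score_until_next_grade",
        "baseline_albi_grade",
        "total_bilirubin",
        "main_pvt",
        "total_dose",
        "mld",
    ),
    "selected_tree": (
        "ast",
        "albi_score_until_next_grade",
        "baseline_albi_score",
        "total_bilirubin",
        "normal_liver_volume",
        "mld",
    ),
}


@dataclass(frozen=True)
class FeatureSetSpec:
    """Ordered, validated list of feature names from the canonical vocabulary."""

    names: tuple

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        unknown = [n for n in names if n not in FEATURE_VOCABULARY]
        if unknown:
            raise ValueError(
                f"unknown feature name(s) {unknown}; vocabulary: {sorted(FEATURE_VOCABULARY)}"
            )

    @classmethod
    def from_preset(cls, name: str) -> "FeatureSetSpec":
        if name not in FEATURE_PRESETS:
            raise ValueError(f"unknown preset {name!r}; presets: {sorted(FEATURE_PRESETS)}")
        return cls(FEATURE_PRESETS[name])

    def __iter__(self):
        return iter(self.names)

    def __len__(self):
        return len(self.names)


def build_feature_matrix(
    records: Sequence[PatientRecord],
    spec,
    radbio: Optional[RadbioParams] = None,
    impute: bool = True,
) -> pd.DataFrame:
    """Assemble the model-ready numeric matrix (patients x features).

    Derived features (ALBI distance, MLD, gEUD sweep entries) are computed on
    the fly; categorical fields arrive as 0/1 indicators.  With
    ``impute=True`` (default) remaining gaps are filled by
    :func:`impute_missing`, so the result has no missing entries.
    """
    if not isinstance(spec, FeatureSetSpec):
        spec = FeatureSetSpec(tuple(spec))
    radbio = radbio or RadbioParams()
    rows = {
        r.patient_id: [FEATURE_VOCABULARY[name](r, radbio) for name in spec]
        for r in records
    }
    X = pd.DataFrame.from_dict(rows, orient="index", columns=list(spec)).astype(float)
    X.index.name = "patient_id"
    if impute and X.isna().any().any():
        X, _ = impute_missing(X)
    return X
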