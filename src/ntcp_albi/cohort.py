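"""Synthetic hepatocellular-carcinoma cohort generator.

Emulates the marginal structure of a real liver-radiotherapy cohort
(n=201-scale: age 61.7 +/- 11.7 y, mean liver dose 17.6 +/- 8.0 Gy, normal
liver volume 1231.3 +/- 455.6 cm3, ~21% baseline ALBI grade 1, ALBI1+
prevalence 43.1%) together with a *known* logistic dose-toxicity mechanism,
so that every downstream stage — DVH reduction, feature engineering,
endpoint grading, model fitting — can be exercised and audited without
patient data.

The toxicity mechanism acts on standardized model features

    eta_i = beta . z_i ,   z = standardized (mld, albi-distance, bilirubin, AST, liver volume)

with per-patient risk the Gauss-Hermite marginal over unmeasured
heterogeneity eps ~ N(0, noise_scale^2):

    true_risk_i = E_eps sigmoid(intercept + eta_i + eps)

The intercept is calibrated by bisection so that the mean risk equals the
target prevalence (default 0.431), and labels are Bernoulli(true_risk).
Outcome labels are *not* attached directly: worst-case labs are constructed
so that the real endpoint classifier reproduces the Bernoulli draw, keeping
the full code path under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .dvh import DifferentialDVH, RadbioParams, eqd2_transform, geud
from .clinical import (
    ALBI_GRADE1_MAX,
    ALBI_GRADE2_MAX,
    BILIRUBIN_MGDL_TO_UMOLL,
    LabPanel,
    PatientRecord,
    albi_grade,
    albi_score_conventional,
    albi_score_until_next_grade,
    child_pugh_points,
    classify_endpoints,
    build_feature_matrix,
)

__all__ = [
    "Marginal",
    "CohortSpec",
    "RiskMechanism",
    "EXTERNAL_SHIFT_PRESET",
    "generate_dvh",
    "calibrate_intercept",
    "generate_cohort",
    "cohort_to_frame",
]

_sigmoid = lambda x: 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class Marginal:
    """Truncated-normal marginal: target mean, SD, admissible (lo, hi) range.

    ``mean`` is the mean of the *truncated* distribution: the underlying
    normal's location is solved so that truncation does not bias the
    realized mean (asymmetric ranges would otherwise shift it).  The SD is
    the untruncated scale; truncation shrinks the realized SD slightly.
    """

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("SD must be > 0")
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")
        if not self.lo < self.mean < self.hi:
            raise ValueError("mean must lie inside (lo, hi)")

    def _location(self) -> float:
        from scipy.optimize import brentq
        from scipy.stats import truncnorm

        def truncated_mean(loc):
            a, b = (self.lo - loc) / self.sd, (self.hi - loc) / self.sd
            return truncnorm.mean(a, b, loc=loc, scale=self.sd) - self.mean

        lo, hi = self.mean - 4 * self.sd, self.mean + 4 * self.sd
        return float(brentq(truncated_mean, lo, hi, xtol=1e-10))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Rejection-sample the mean-corrected truncated normal."""
        loc = self._location()
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            draw = rng.normal(loc, self.sd, todo.size)
            ok = (draw >= self.lo) & (draw <= self.hi)
            out[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return out


#: fractionation menu entries: (total dose Gy, n fractions, probability)
_CONV_MENU = ((30.0, 10, 0.55), (40.0, 10, 0.20), (45.0, 15, 0.15), (60.0, 25, 0.10))
_SBRT_MENU = ((50.0, 5, 0.55), (40.0, 5, 0.25), (33.0, 3, 0.20))


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration: marginals, category probabilities, fractionation menu.

    Continuous-covariate defaults reproduce the marginal moments of a
    representative real-world liver-radiotherapy cohort.  The albumin marginal
    (no reported value exists) is
    set so that the implied baseline ALBI score is ~ -2.28 +/- 0.43 with
    ~21% grade 1: ALBI score and grade are *computed* from the sampled labs,
    never sampled directly, so the lab/score coupling is exact.
    """

    n_patients: int = 201
    age: Marginal = field(default=Marginal(61.7, 11.7, 18.0, 90.0))
    tumor_diameter: Marginal = field(default=Marginal(7.8, 4.1, 0.8, 22.0))
    normal_liver_volume: Marginal = field(default=Marginal(1231.3, 455.6, 300.0, 3200.0))
    mld: Marginal = field(default=Marginal(17.6, 8.0, 0.5, 42.0))
    ast: Marginal = field(default=Marginal(68.6, 41.8, 12.0, 320.0))
    alt: Marginal = field(default=Marginal(44.7, 28.8, 6.0, 240.0))
    alp: Marginal = field(default=Marginal(120.0, 60.0, 35.0, 500.0))
    total_bilirubin: Marginal = field(default=Marginal(1.4, 0.7, 0.25, 4.5))
    albumin: Marginal = field(default=Marginal(3.72, 0.48, 2.1, 5.2))
    inr: Marginal = field(default=Marginal(1.10, 0.12, 0.85, 1.9))
    p_male: float = 0.846
    p_hepatitis_b: float = 0.493
    p_hepatitis_c: float = 0.189
    p_main_pvt: float = 0.378
    p_prior_surgery: float = 0.124
    p_prior_tace: float = 0.632
    technique_probs: tuple = (("3D-CRT", 0.328), ("IMRT/VMAT", 0.463), ("SBRT", 0.209))
    conventional_menu: tuple = _CONV_MENU
    sbrt_menu: tuple = _SBRT_MENU
    ascites_probs: tuple = (("none", 0.88), ("slight", 0.10), ("moderate+", 0.02))
    enceph_probs: tuple = (("none", 0.96), ("grade1-2", 0.03), ("grade3-4", 0.01))
    target_prevalence: float = 0.431
    missingness_rate: float = 0.05
    missing_lab_fields: tuple = ("alt", "alp", "inr")

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for p in (
            self.p_male, self.p_hepatitis_b, self.p_hepatitis_c, self.p_main_pvt,
            self.p_prior_surgery, self.p_prior_tace, self.missingness_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        for menu in (self.technique_probs, self.ascites_probs, self.enceph_probs):
            if abs(sum(p for _, p in menu) - 1.0) > 1e-9:
                raise ValueError(f"category probabilities must sum to 1: {menu}")
        for menu in (self.conventional_menu, self.sbrt_menu):
            if abs(sum(p for *_, p in menu) - 1.0) > 1e-9:
                raise ValueError(f"fractionation menu probabilities must sum to 1: {menu}")


@dataclass(frozen=True)
class RiskMechanism:
    """Known logistic toxicity mechanism on standardized cohort features.

    Slope signs are fixed by domain knowledge: dose (mld) and lab burden
    (bilirubin, AST) raise risk, proximity to the next ALBI grade raises
    risk (hence the *negative* coefficient on the distance feature), larger
    spared liver volume is protective.  ``noise_scale`` is the SD of the
    unmeasured-heterogeneity term; the default was fixed once so the oracle
    discrimination of true_risk against its own Bernoulli labels is ~0.82.
    """

    coefficients: tuple = (
        ("mld", 0.9),
        ("albi_score_until_next_grade", -1.2),
        ("total_bilirubin", 0.5),
        ("ast", 0.4),
        ("normal_liver_volume", -0.4),
    )
    noise_scale: float = 0.8
    intercept: Optional[float] = None  # calibrated when None

    def __post_init__(self):
        coefs = dict(self.coefficients)
        for name in ("mld", "total_bilirubin", "ast"):
            if name in coefs and coefs[name] < 0:
                raise ValueError(f"{name} coefficient must be >= 0")
        if coefs.get("normal_liver_volume", -1.0) > 0:
            raise ValueError("normal_liver_volume must enter with protective (<= 0) sign")
        if coefs.get("albi_score_until_next_grade", -1.0) > 0:
            raise ValueError("albi_score_until_next_grade coefficient must be <= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @property
    def feature_names(self) -> tuple:
        return tuple(name for name, _ in self.coefficients)

    def linear_predictor(self, z: pd.DataFrame) -> np.ndarray:
        """beta . z over standardized features (no intercept)."""
        eta = np.zeros(len(z))
        for name, beta in self.coefficients:
            eta += beta * z[name].to_numpy()
        return eta

    def risk(self, eta: np.ndarray, intercept: Optional[float] = None) -> np.ndarray:
        """Marginal per-patient risk E_eps sigmoid(intercept + eta + eps)."""
        a = self.intercept if intercept is None else intercept
        if a is None:
            raise ValueError("intercept not set; calibrate first")
        if self.noise_scale == 0:
            return _sigmoid(a + eta)
        # Gauss-Hermite quadrature for eps ~ N(0, noise_scale^2)
        nodes, weights = np.polynomial.hermite.hermgauss(31)
        eps = math.sqrt(2.0) * self.noise_scale * nodes
        w = weights / math.sqrt(math.pi)
        return _sigmoid(a + eta[:, None] + eps[None, :]) @ w


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean) / sd with population (ddof=0) SD."""
    sd = X.std(ddof=0).replace(0.0, 1.0)
    return (X - X.mean()) / sd


def calibrate_intercept(
    m: RiskMechanism,
    covariates: pd.DataFrame,
    target_prevalence: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """Bisection for the intercept making mean mechanism risk hit the target.

    ``covariates`` must be the *standardized* mechanism features.  Mean risk
    is monotone increasing in the intercept, so plain bisection converges.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0, 1)")
    eta = m.linear_predictor(covariates)
    lo, hi = -30.0, 30.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mean_risk = float(m.risk(eta, intercept=mid).mean())
        if abs(mean_risk - target_prevalence) < tol:
            return mid
        if mean_risk < target_prevalence:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("intercept calibration did not converge; mechanism misconfigured")


def generate_dvh(
    target_mld: float,
    seed_or_rng,
    peak_dose: Optional[float] = None,
) -> DifferentialDVH:
    """Two-component normal-liver DVH with physical mean dose == target_mld.

    A low-dose spared component (exponentially weighted bins below ~0.3 x
    peak) and an irradiated component concentrated near a sampled peak dose
    are mixed with the unique weight that makes the mean dose equal the
    target exactly, so gEUD(a=1) round-trips to the target to float
    precision.
    """
    if target_mld < 0:
        raise ValueError("target mean liver dose must be >= 0")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    if target_mld == 0:
        return DifferentialDVH(np.array([0.0]), np.array([1.0]))
    P = peak_dose if peak_dose is not None else target_mld * rng.uniform(1.4, 2.2) + 1.0
    # raise the peak when the target demands it, so the cluster means bracket the target
    P = float(max(P, 1.25 * target_mld + 0.25))
    lo_doses = np.linspace(0.02 * target_mld, 0.30 * target_mld, 7)
    lo_w = np.exp(-np.linspace(0.0, 2.5, 7) * rng.uniform(0.8, 1.2))
    lo_w /= lo_w.sum()
    hi_doses = np.linspace(0.82 * P, P, 7)
    hi_w = np.exp(-0.5 * ((hi_doses - rng.uniform(0.88, 0.97) * P) / (0.05 * P)) ** 2)
    hi_w /= hi_w.sum()
    m_lo = float(lo_w @ lo_doses)
    m_hi = float(hi_w @ hi_doses)
    w = (target_mld - m_lo) / (m_hi - m_lo)
    if not 0.0 <= w <= 1.0:  # pragma: no cover - guarded by the clip above
        raise ValueError(f"target {target_mld} unattainable with peak {P}")
    return DifferentialDVH(
        np.concatenate([lo_doses, hi_doses]),
        np.concatenate([(1.0 - w) * lo_w, w * hi_w]),
    )


def _choice(rng, menu):
    idx = rng.choice(len(menu), p=[m[-1] for m in menu])
    return menu[idx][0]


def _sample_baseline_labs(spec: CohortSpec, rng, n: int):
    """Sample bilirubin/albumin, rejecting baseline ALBI grade-3 draws (exclusion rule)."""
    bili = spec.total_bilirubin.sample(rng, n)
    alb = spec.albumin.sample(rng, n)
    score = np.array([albi_score_conventional(b, a) for b, a in zip(bili, alb)])
    bad = score > ALBI_GRADE2_MAX
    while bad.any():
        k = int(bad.sum())
        bili[bad] = spec.total_bilirubin.sample(rng, k)
        alb[bad] = spec.albumin.sample(rng, k)
        score[bad] = [albi_score_conventional(b, a) for b, a in zip(bili[bad], alb[bad])]
        bad = score > ALBI_GRADE2_MAX
    return bili, alb, score


def _worst_albi_labs(rng, bili, alb, score, grade, positive):
    """Construct worst bilirubin/albumin realising the drawn ALBI1+ outcome.

    Positive patients are pushed just past their next grade threshold with an
    exponential overshoot; negatives drift within grade.  The score change is
    split between a bilirubin rise and an albumin fall, both solved exactly
    from the ALBI formula.
    """
    threshold = ALBI_GRADE1_MAX if grade == 1 else ALBI_GRADE2_MAX
    distance = threshold - score
    if positive:
        target = threshold + rng.exponential(0.15) + 1e-6
    else:
        target = score + rng.uniform(-0.25, 0.90) * distance
    delta = target - score
    f = rng.uniform(0.3, 0.7)  # bilirubin share of the score change
    new_bili_umol = bili * BILIRUBIN_MGDL_TO_UMOLL * 10 ** (f * delta / 0.66)
    new_alb_gl = alb * 10.0 - (1.0 - f) * delta / 0.085
    if new_alb_gl < 15.0:  # clamp albumin, push the remainder into bilirubin
        short = (15.0 - new_alb_gl) * 0.085
        new_alb_gl = 15.0
        new_bili_umol *= 10 ** (short / 0.66)
    return new_bili_umol / BILIRUBIN_MGDL_TO_UMOLL, new_alb_gl / 10.0


def generate_cohort(spec: CohortSpec, m: Optional[RiskMechanism] = None, seed: int = 0):
    """Generate a cohort of PatientRecords with DVHs, labels and true risks.

    Returns ``(records, labels, true_risks)`` where ``labels`` is a DataFrame
    of graded endpoints (via :func:`classify_endpoints` — the generator never
    writes the ALBI1+ column directly) and ``true_risks`` the mechanism's
    per-patient risk.  Fully reproducible from ``seed``.
    """
    m = m or RiskMechanism()
    rng = np.random.default_rng(seed)
    n = spec.n_patients

    age = spec.age.sample(rng, n)
    sex = np.where(rng.random(n) < spec.p_male, "male", "female")
    hbv = rng.random(n) < spec.p_hepatitis_b
    hcv = rng.random(n) < spec.p_hepatitis_c
    pvt = rng.random(n) < spec.p_main_pvt
    surgery = rng.random(n) < spec.p_prior_surgery
    tace = rng.random(n) < spec.p_prior_tace
    diam = spec.tumor_diameter.sample(rng, n)
    tumor_vol = (np.pi / 6.0) * diam**3 * np.exp(rng.normal(0.0, 0.30, n))
    liver_vol = spec.normal_liver_volume.sample(rng, n)
    ast = spec.ast.sample(rng, n)
    alt = spec.alt.sample(rng, n)
    alp = spec.alp.sample(rng, n)
    inr = spec.inr.sample(rng, n)
    bili, alb, score = _sample_baseline_labs(spec, rng, n)
    grade = np.array([albi_grade(s) for s in score])

    tech_names = [t for t, _ in spec.technique_probs]
    tech_probs = [p for _, p in spec.technique_probs]
    technique = np.array([tech_names[rng.choice(len(tech_names), p=tech_probs)] for _ in range(n)])
    total_dose = np.empty(n)
    n_fx = np.empty(n, dtype=int)
    for i in range(n):
        menu = spec.sbrt_menu if technique[i] == "SBRT" else spec.conventional_menu
        probs = [p for *_, p in menu]
        j = rng.choice(len(menu), p=probs)
        total_dose[i], n_fx[i] = menu[j][0], menu[j][1]
    ascites = np.array([_choice(rng, spec.ascites_probs) for _ in range(n)])
    enceph = np.array([_choice(rng, spec.enceph_probs) for _ in range(n)])

    mld_target = spec.mld.sample(rng, n)
    # peak near the prescription dose; generate_dvh raises the peak for the
    # rare plans whose sampled MLD demands a hotter maximum
    dvhs = [generate_dvh(mld_target[i], rng, peak_dose=total_dose[i]) for i in range(n)]

    # mechanism features (EQD2-corrected MLD), standardized within the cohort
    eqd2_mld = np.array(
        [
            geud(eqd2_transform(dvhs[i], RadbioParams(n_fractions=int(n_fx[i]))), 1.0)
            for i in range(n)
        ]
    )
    distance = np.array(
        [albi_score_until_next_grade(score[i], int(grade[i])) for i in range(n)]
    )
    feats = pd.DataFrame(
        {
            "mld": eqd2_mld,
            "albi_score_until_next_grade": distance,
            "total_bilirubin": bili,
            "ast": ast,
            "normal_liver_volume": liver_vol,
        }
    )
    z = standardize(feats[list(m.feature_names)])
    if m.intercept is None:
        m = replace(m, intercept=calibrate_intercept(m, z, spec.target_prevalence))
    true_risk = m.risk(m.linear_predictor(z))
    y = rng.random(n) < true_risk

    worst = [_worst_albi_labs(rng, bili[i], alb[i], score[i], int(grade[i]), bool(y[i])) for i in range(n)]
    worst_bili = np.array([wb for wb, _ in worst])
    worst_alb = np.array([wa for _, wa in worst])
    worst_ast = ast * np.exp(rng.normal(0.15 + 0.55 * y, 0.35, n))
    worst_alt = alt * np.exp(rng.normal(0.15 + 0.55 * y, 0.35, n))
    worst_inr = inr * np.exp(rng.normal(0.02 + 0.08 * y, 0.05, n))

    miss = {
        f: rng.random(n) < spec.missingness_rate for f in spec.missing_lab_fields
    }

    records, label_rows = [], []
    for i in range(n):
        base_vals = {"ast": ast[i], "alt": alt[i], "alp": alp[i], "inr": inr[i]}
        for f in spec.missing_lab_fields:
            if miss[f][i]:
                base_vals[f] = None
        baseline = LabPanel(
            ast=base_vals["ast"], alt=base_vals["alt"], alp=base_vals["alp"],
            total_bilirubin=bili[i], albumin=alb[i], inr=base_vals["inr"],
        )
        worst_panel = LabPanel(
            ast=worst_ast[i], alt=worst_alt[i], alp=alp[i] * 1.1,
            total_bilirubin=worst_bili[i], albumin=worst_alb[i], inr=worst_inr[i],
        )
        rec = PatientRecord(
            patient_id=f"SYN{i:05d}",
            age=age[i],
            sex=str(sex[i]),
            hepatitis_b=bool(hbv[i]),
            hepatitis_c=bool(hcv[i]),
            main_pvt=bool(pvt[i]),
            prior_surgery=bool(surgery[i]),
            prior_tace=bool(tace[i]),
            tumor_diameter=diam[i],
            tumor_volume=tumor_vol[i],
            normal_liver_volume=liver_vol[i],
            total_dose=total_dose[i],
            n_fractions=int(n_fx[i]),
            technique=str(technique[i]),
            baseline_labs=baseline,
            worst_labs=worst_panel,
            baseline_albi_score=score[i],
            baseline_albi_grade=int(grade[i]),
            baseline_cp=child_pugh_points(bili[i], alb[i], inr[i], str(ascites[i]), str(enceph[i])),
            worst_cp=child_pugh_points(worst_bili[i], worst_alb[i], worst_inr[i], str(ascites[i]), str(enceph[i])),
            dvh=dvhs[i],
        )
        records.append(rec)
        lab = classify_endpoints(rec)
        label_rows.append(
            {
                "patient_id": rec.patient_id,
                "albi1plus": lab.albi1plus,
                "cp2plus": lab.cp2plus,
                "ctcae2plus": lab.ctcae2plus,
            }
        )
    labels = pd.DataFrame(label_rows).set_index("patient_id")
    return records, labels, pd.Series(true_risk, index=labels.index, name="true_risk")


#: marginal shifts emulating a later, externally recruited validation cohort
EXTERNAL_SHIFT_PRESET = {
    "n_patients": 44,
    "age": Marginal(63.5, 11.0, 18.0, 90.0),
    "ast": Marginal(55.0, 35.0, 12.0, 320.0),
    "total_bilirubin": Marginal(1.1, 0.6, 0.25, 4.5),
    "albumin": Marginal(3.9, 0.45, 2.1, 5.2),
    "mld": Marginal(15.0, 7.0, 0.5, 42.0),
}


def external_cohort_spec(base: Optional[CohortSpec] = None) -> CohortSpec:
    """CohortSpec preset with shifted marginals for external-validation emulation."""
    base = base or CohortSpec()
    return replace(base, **EXTERNAL_SHIFT_PRESET)


def cohort_to_frame(records) -> pd.DataFrame:
    """Flatten PatientRecords into the canonical delimited cohort table."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "hepatitis_b": r.hepatitis_b,
                "hepatitis_c": r.hepatitis_c,
                "main_pvt": r.main_pvt,
                "prior_surgery": r.prior_surgery,
                "prior_tace": r.prior_tace,
                "tumor_diameter": r.tumor_diameter,
                "tumor_volume": r.tumor_volume,
                "normal_liver_volume": r.normal_liver_volume,
                "total_dose": r.total_dose,
                "n_fractions": r.n_fractions,
                "technique": r.technique,
                "baseline_ast": r.baseline_labs.ast,
                "baseline_alt": r.baseline_labs.alt,
                "baseline_alp": r.baseline_labs.alp,
                "baseline_total_bilirubin": r.baseline_labs.total_bilirubin,
                "baseline_albumin": r.baseline_labs.albumin,
                "baseline_inr": r.baseline_labs.inr,
                "worst_ast": r.worst_labs.ast,
                "worst_alt": r.worst_labs.alt,
                "worst_total_bilirubin": r.worst_labs.total_bilirubin,
                "worst_albumin": r.worst_labs.albumin,
                "worst_inr": r.worst_labs.inr,
                "baseline_albi_score": r.baseline_albi_score,
                "baseline_albi_grade": r.baseline_albi_grade,
                "baseline_cp": r.baseline_cp,
                "worst_cp": r.worst_cp,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
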