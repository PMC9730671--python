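"""ALBI scoring and grading, Child-Pugh points, endpoints, imputation, features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ntcp_albi.clinical import (
    ALBI_GRADE1_MAX,
    ALBI_GRADE2_MAX,
    FeatureSetSpec,
    LabPanel,
    PatientRecord,
    albi_grade,
    albi_score,
    albi_score_conventional,
    albi_score_until_next_grade,
    build_feature_matrix,
    child_pugh_points,
    classify_endpoints,
    impute_missing,
)
from ntcp_albi.dvh import DifferentialDVH, RadbioParams, eqd2_transform, geud


def make_record(**overrides):
    base = dict(
        patient_id="P1",
        age=60.0,
        sex="male",
        hepatitis_b=True,
        hepatitis_c=False,
        main_pvt=False,
        prior_surgery=False,
        prior_tace=True,
        tumor_diameter=6.0,
        tumor_volume=120.0,
        normal_liver_volume=1200.0,
        total_dose=30.0,
        n_fractions=10,
        technique="IMRT/VMAT",
        baseline_labs=LabPanel(ast=30.0, alt=25.0, alp=100.0, total_bilirubin=1.0, albumin=4.0, inr=1.1),
        worst_labs=LabPanel(ast=50.0, alt=40.0, alp=110.0, total_bilirubin=3.0, albumin=2.5, inr=1.2),
        baseline_albi_score=albi_score_conventional(1.0, 4.0),
        baseline_albi_grade=2,
        baseline_cp=5,
        worst_cp=6,
        dvh=DifferentialDVH(np.array([2.0, 28.0]), np.array([0.5, 0.5])),
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestALBIScore:
    @pytest.mark.parametrize(
        "bili_umol, alb_gl, expected",
        [(10.0, 40.0, -2.74), (17.1, 40.0, 0.66 * np.log10(17.1) - 3.4), (10.0, 50.0, -3.59)],
    )
    def test_hand_values(self, bili_umol, alb_gl, expected):
        assert albi_score(bili_umol, alb_gl) == pytest.approx(expected, abs=1e-4)

    def test_conventional_units_wrapper(self):
        # 1.0 mg/dL = 17.1 umol/L, 4.0 g/dL = 40 g/L
        assert albi_score_conventional(1.0, 4.0) == pytest.approx(albi_score(17.1, 40.0))
        assert albi_score_conventional(1.0, 4.0) == pytest.approx(-2.5862, abs=1e-3)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            albi_score(0.0, 40.0)
        with pytest.raises(ValueError):
            albi_score(10.0, -1.0)

    @given(st.floats(2.0, 300.0), st.floats(15.0, 55.0), st.floats(1.01, 1.5))
    def test_monotone_in_both_arguments(self, bili, alb, factor):
        s = albi_score(bili, alb)
        assert albi_score(bili * factor, alb) > s
        assert albi_score(bili, alb * factor) < s


class TestALBIGrade:
    @pytest.mark.parametrize(
        "score, grade",
        [(-2.70, 1), (-2.60, 1), (-2.00, 2), (-1.39, 2), (-1.00, 3)],
    )
    def test_grading_with_closed_lower_boundaries(self, score, grade):
        assert albi_grade(score) == grade

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            albi_grade(float("nan"))

    def test_bisection_recovers_printed_thresholds(self):
        for lo_grade, lo, hi in [(1, -4.0, -2.0), (2, -2.5, -0.5)]:
            a, b = lo, hi
            for _ in range(60):
                mid = 0.5 * (a + b)
                if albi_grade(mid) <= lo_grade:
                    a = mid
                else:
                    b = mid
            target = ALBI_GRADE1_MAX if lo_grade == 1 else ALBI_GRADE2_MAX
            assert 0.5 * (a + b) == pytest.approx(target, abs=1e-3)


class TestScoreUntilNextGrade:
    @pytest.mark.parametrize(
        "score, grade, expected",
        [(-3.0, 1, 0.4), (-2.24, 2, 0.85), (-1.39, 2, 0.0)],
    )
    def test_distance_values(self, score, grade, expected):
        assert albi_score_until_next_grade(score, grade) == pytest.approx(expected)

    def test_grade3_and_mismatch_rejected(self):
        with pytest.raises(ValueError):
            albi_score_until_next_grade(-1.0, 3)
        with pytest.raises(ValueError):
            albi_score_until_next_grade(-3.0, 2)  # -3.0 is grade 1

    @given(st.floats(-5.0, -1.3901))
    def test_distance_nonnegative_for_admissible_scores(self, score):
        g = albi_grade(score)
        if g == 3:
            return
        assert albi_score_until_next_grade(score, g) >= 0.0


class TestChildPugh:
    def test_all_best_components_score_five(self):
        assert child_pugh_points(1.0, 4.0, 1.0, "none", "none") == 5

    def test_all_worst_components_score_fifteen(self):
        assert child_pugh_points(4.0, 2.0, 3.0, "moderate+", "grade3-4") == 15

    def test_mixed_hand_value(self):
        # 2 + 2 + 2 + 2 + 1 on the standard table
        assert child_pugh_points(2.5, 3.0, 1.8, "slight", "none") == 9

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            child_pugh_points(None, 4.0, 1.0, "none", "none")
        with pytest.raises(ValueError):
            child_pugh_points(1.0, 4.0, 1.0, "lots", "none")


class TestEndpoints:
    def test_albi_grade_increase_detected(self):
        r = make_record()  # baseline grade 2; worst: bili 3.0, alb 2.5 -> grade 3
        lab = classify_endpoints(r)
        assert lab.albi1plus is True

    def test_stable_grade_is_negative(self):
        r = make_record(worst_labs=LabPanel(ast=35.0, alt=30.0, total_bilirubin=1.1, albumin=3.9, inr=1.1))
        assert classify_endpoints(r).albi1plus is False

    def test_missing_worst_labs_leave_endpoint_unavailable(self):
        r = make_record(worst_labs=LabPanel(ast=50.0), worst_cp=None)
        lab = classify_endpoints(r)
        assert lab.albi1plus is None
        assert lab.cp2plus is None

    def test_cp2plus_from_recorded_scores(self):
        assert classify_endpoints(make_record(baseline_cp=5, worst_cp=7)).cp2plus is True
        assert classify_endpoints(make_record(baseline_cp=5, worst_cp=6)).cp2plus is False

    def test_ctcae_normal_baseline_uses_uln(self):
        r = make_record(
            baseline_labs=LabPanel(ast=30.0, alt=20.0, total_bilirubin=1.0, albumin=4.0),
            worst_labs=LabPanel(ast=130.0, alt=30.0, total_bilirubin=1.0, albumin=4.0),
        )
        assert classify_endpoints(r, uln_ast=40.0).ctcae2plus is True  # 130 >= 3*40

    def test_ctcae_abnormal_baseline_uses_threefold_baseline(self):
        r = make_record(
            baseline_labs=LabPanel(ast=68.0, alt=20.0, total_bilirubin=1.0, albumin=4.0),
            worst_labs=LabPanel(ast=150.0, alt=25.0, total_bilirubin=1.0, albumin=4.0),
        )
        assert classify_endpoints(r, uln_ast=40.0).ctcae2plus is False  # 150 < 3*68

    @given(st.floats(0.3, 3.0), st.floats(2.0, 5.0))
    def test_worsening_worst_labs_never_flips_positive_to_negative(self, bili, alb):
        base = make_record()
        lab1 = classify_endpoints(
            make_record(worst_labs=LabPanel(total_bilirubin=bili, albumin=alb))
        )
        worse = classify_endpoints(
            make_record(worst_labs=LabPanel(total_bilirubin=bili * 2, albumin=alb))
        )
        if lab1.albi1plus:
            assert worse.albi1plus


class TestImputation:
    def test_complete_table_returned_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out, report = impute_missing(df)
        pd.testing.assert_frame_equal(out, df)
        assert report == {}

    def test_exact_linear_dependence_recovered(self):
        x = np.arange(10, dtype=float)
        y = 2.0 * x
        y_miss = y.copy()
        y_miss[4] = np.nan
        out, report = impute_missing(pd.DataFrame({"x": x, "y": y_miss}))
        assert out.loc[4, "y"] == pytest.approx(8.0, abs=1e-9)
        assert report["y"]["n_missing"] == 1

    def test_observed_cells_bit_identical_and_deterministic(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        df.loc[rng.choice(30, 6, replace=False), "c"] = np.nan
        out1, _ = impute_missing(df)
        out2, _ = impute_missing(df)
        pd.testing.assert_frame_equal(out1, out2)
        obs = df["c"].notna()
        assert (out1.loc[obs, "c"] == df.loc[obs, "c"]).all()
        # imputed cells clamped to the observed range
        assert out1["c"].between(df["c"].min(), df["c"].max()).all()

    def test_high_missingness_flagged_and_all_missing_rejected(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": [1.0] + [np.nan] * 9})
        out, report = impute_missing(df)
        assert report["b"]["high_missingness"] is True
        with pytest.raises(ValueError, match="'b'"):
            impute_missing(pd.DataFrame({"a": np.arange(3.0), "b": [np.nan] * 3}))

    def test_categorical_mode_fill(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "g": ["x", None, "x"]})
        out, report = impute_missing(df)
        assert out.loc[1, "g"] == "x"
        assert report["g"]["method"] == "mode"


class TestFeatureMatrix:
    def test_named_presets_have_expected_widths(self):
        recs = [make_record(patient_id=f"P{i}") for i in range(4)]
        gbt = build_feature_matrix(recs, FeatureSetSpec.from_preset("selected_tree"))
        plr = build_feature_matrix(recs, FeatureSetSpec.from_preset("selected_plr"))
        assert gbt.shape == (4, 6)
        assert plr.shape == (4, 7)
        assert not gbt.isna().any().any()

    def test_unknown_feature_name_rejected_with_vocabulary(self):
        with pytest.raises(ValueError, match="foo"):
            FeatureSetSpec(("age", "foo"))
        with pytest.raises(ValueError):
            FeatureSetSpec(("age", "age"))

    def test_mld_column_matches_manual_eqd2_geud(self):
        rec = make_record()
        X = build_feature_matrix([rec], ("mld", "geud_a2"))
        manual = eqd2_transform(rec.dvh, RadbioParams(n_fractions=rec.n_fractions))
        assert X.loc["P1", "mld"] == pytest.approx(geud(manual, 1.0))
        assert X.loc["P1", "geud_a2"] == pytest.approx(geud(manual, 2.0))

    def test_derived_distance_feature_and_indicators(self):
        rec = make_record()
        X = build_feature_matrix([rec], ("albi_score_until_next_grade", "sex_female", "technique_sbrt"))
        assert X.loc["P1", "albi_score_until_next_grade"] == pytest.approx(
            ALBI_GRADE2_MAX - rec.baseline_albi_score
        )
        assert X.loc["P1", "sex_female"] == 0.0
        assert X.loc["P1", "technique_sbrt"] == 0.0

    def test_missing_labs_imputed_in_matrix(self):
        recs = [make_record(patient_id=f"P{i}") for i in range(5)]
        recs[2].baseline_labs.inr = None
        X = build_feature_matrix(recs, ("age", "inr", "total_bilirubin"))
        assert not X.isna().any().any()

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_record(baseline_albi_grade=3)
        with pytest.raises(ValueError):
            make_record(n_fractions=0)
        with pytest.raises(ValueError):
            make_record(total_dose=-5.0)
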