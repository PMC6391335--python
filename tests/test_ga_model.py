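import json
import math

import numpy as np
import pandas as pd
import pytest

from alcv.ga_model import (
    GAModel,
    bland_altman,
    classify_hittner_grade,
    fit_mixed_model,
    hittner_grade_range,
    load_model,
    predict_ga,
    variance_inflation,
)
from alcv.synthetic_eye import DEFAULT_COHORT_FEATURES, simulate_cohort

ZERO_FEATURES = {
    "branch_length_max": 0.0,
    "branch_width_max": 0.0,
    "branch_width_min": 0.0,
    "branch_thickness_max": 0.0,
    "branch_thickness_min": 0.0,
    "density": 0.0,
}


class TestPredictGA:
    def test_intercept_at_zero_features(self):
        assert predict_ga(load_model(), ZERO_FEATURES) == pytest.approx(34.406, abs=1e-12)

    def test_density_unit_step(self):
        f = dict(ZERO_FEATURES, density=1.0)
        assert predict_ga(load_model(), f) == pytest.approx(34.406 - 0.124, abs=1e-12)

    def test_linearity_doubling(self):
        model = load_model()
        rng = np.random.default_rng(0)
        f1 = {k: float(v) for k, v in zip(ZERO_FEATURES, rng.uniform(0, 10, 6))}
        f2 = {k: 2 * v for k, v in f1.items()}
        d1 = predict_ga(model, f1) - model.intercept
        d2 = predict_ga(model, f2) - model.intercept
        assert d2 == pytest.approx(2 * d1, abs=1e-9)

    def test_matches_independent_dot_product(self):
        model = load_model()
        rng = np.random.default_rng(1)
        for _ in range(100):
            feats = {k: float(v) for k, v in zip(ZERO_FEATURES, rng.normal(0, 5, 6))}
            expected = model.intercept
            for term, coef in model.coefficients.items():
                expected += coef * feats[model.mapping[term]]
            assert predict_ga(model, feats) == pytest.approx(expected, abs=1e-12)

    def test_missing_feature_named(self):
        f = dict(ZERO_FEATURES)
        del f["density"]
        with pytest.raises(KeyError, match="density"):
            predict_ga(load_model(), f)

    def test_nan_feature_named(self):
        f = dict(ZERO_FEATURES, branch_width_min=float("nan"))
        with pytest.raises(ValueError, match="branch_width_min"):
            predict_ga(load_model(), f)


class TestLoadModel:
    def test_shipped_coefficients(self):
        m = load_model()
        assert m.intercept == 34.406
        assert m.coefficients == {
            "branch_length_max": 0.022,
            "branch_width_max": -0.092,
            "branch_width_min": 0.155,
            "branch_thickness_max": -0.122,
            "branch_thickness_min": -1.667,
            "density": -0.124,
        }
        assert m.version

    def test_custom_file_roundtrip(self, tmp_path):
        payload = {
            "version": "test",
            "feature_units": "pixels",
            "intercept": 30.0,
            "coefficients": {"density": -0.5},
            "mapping": {"density": "density"},
        }
        p = tmp_path / "coef.json"
        p.write_text(json.dumps(payload))
        m = load_model(p)
        assert predict_ga(m, {"density": 2.0}) == pytest.approx(29.0)

    def test_invalid_mapping_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            GAModel(intercept=1.0, coefficients={"x": 1.0}, mapping={"x": "not_a_feature"})
        with pytest.raises(ValueError, match="mapping lacks"):
            GAModel(intercept=1.0, coefficients={"density": 1.0}, mapping={})

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            GAModel(intercept=float("inf"), coefficients={}, mapping={})


BETA = [34.0, 0.5, -0.3, 0.2, 0.1, -0.4, 0.25]
TERMS = list(DEFAULT_COHORT_FEATURES)


class TestMixedModel:
    def test_noiseless_equals_ols(self):
        df = simulate_cohort(10, 3, BETA, 0.0, 0.0, seed=4)
        fit = fit_mixed_model(df, TERMS)
        X = np.column_stack([np.ones(len(df))] + [df[t] for t in TERMS])
        ols = np.linalg.lstsq(X, df["ultrasound_ga"], rcond=None)[0]
        got = np.array(list(fit.fixed_effects.values()))
        assert np.allclose(got, ols, atol=1e-6)
        assert fit.sigma_subject == pytest.approx(0.0, abs=1e-4)

    def test_recovers_beta_roughly(self):
        df = simulate_cohort(60, 3, BETA, 1.0, 0.8, seed=5)
        fit = fit_mixed_model(df, TERMS)
        got = np.array(list(fit.fixed_effects.values()))
        assert np.allclose(got, BETA, atol=0.5)
        assert fit.sigma_subject == pytest.approx(1.0, abs=0.4)
        assert fit.sigma_resid == pytest.approx(0.8, abs=0.3)

    def test_duplicated_rows_gls_invariance(self):
        # at the matched variance ratio (lambda/2), duplicated-row GLS fixed
        # effects equal the originals exactly; the fully re-optimized ML
        # estimate lands close but not identically (ratio re-estimated).
        from alcv.ga_model import _profile_negll

        df = simulate_cohort(24, 3, BETA, 1.0, 0.8, seed=6)
        fit1 = fit_mixed_model(df, TERMS)
        lam1 = (fit1.sigma_subject / fit1.sigma_resid) ** 2
        df2 = pd.concat([df, df], ignore_index=True)
        X = np.column_stack([np.ones(len(df2))] + [df2[t] for t in TERMS])
        y = df2["ultrasound_ga"].to_numpy()
        groups = [
            (X[df2["subject_id"] == s], y[df2["subject_id"] == s])
            for s in pd.unique(df2["subject_id"])
        ]
        _, beta2, _, _ = _profile_negll(math.log(lam1 / 2), groups, len(df2), len(TERMS) + 1, False)
        got1 = np.array(list(fit1.fixed_effects.values()))
        assert np.allclose(beta2, got1, atol=1e-6)
        fit2 = fit_mixed_model(df2, TERMS)
        got2 = np.array(list(fit2.fixed_effects.values()))
        assert np.allclose(got2, got1, atol=0.1)

    def test_aic_bic_identities(self):
        df = simulate_cohort(12, 3, BETA, 1.0, 0.8, seed=7)
        fit = fit_mixed_model(df, TERMS)
        k = len(TERMS) + 1 + 2
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-10)
        assert fit.bic == pytest.approx(-2 * fit.loglik + k * math.log(fit.n_obs), abs=1e-10)
        assert fit.n_obs == 36 and fit.n_subjects == 12
        assert fit.sigma_subject >= 0 and fit.sigma_resid > 0

    def test_refinement_does_not_reduce_loglik(self):
        from alcv.ga_model import _profile_negll

        df = simulate_cohort(20, 3, BETA, 1.2, 0.6, seed=8)
        fit = fit_mixed_model(df, TERMS)
        X = np.column_stack([np.ones(len(df))] + [df[t] for t in TERMS])
        y = df["ultrasound_ga"].to_numpy()
        groups = [
            (X[df["subject_id"] == s], y[df["subject_id"] == s])
            for s in pd.unique(df["subject_id"])
        ]
        p = len(TERMS) + 1
        coarse = min(
            -_profile_negll(g, groups, len(df), p, False)[0] for g in np.linspace(-12, 8, 41)
        )
        assert fit.loglik >= coarse - 1e-9

    def test_rank_deficient_design_rejected(self):
        df = simulate_cohort(10, 3, BETA, 1.0, 0.8, seed=9)
        df["dup"] = df[TERMS[0]]
        with pytest.raises(ValueError, match="collinear"):
            fit_mixed_model(df, TERMS + ["dup"])

    def test_too_few_subjects(self):
        df = simulate_cohort(2, 3, BETA, 1.0, 0.8, seed=10)
        df = df[df["subject_id"] == df["subject_id"].iloc[0]]
        with pytest.raises(ValueError):
            fit_mixed_model(df, TERMS)

    def test_reml_switch_runs(self):
        df = simulate_cohort(15, 3, BETA, 1.0, 0.8, seed=11)
        ml = fit_mixed_model(df, TERMS, reml=False)
        reml = fit_mixed_model(df, TERMS, reml=True)
        assert reml.reml and not ml.reml
        # REML variance estimates are >= ML (bias correction)
        assert reml.sigma_resid >= ml.sigma_resid - 1e-9


class TestVIF:
    def test_independent_features_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((5000, 4)), columns=list("abcd"))
        vifs = variance_inflation(df, list("abcd"))
        for v in vifs.values():
            assert v == pytest.approx(1.0, abs=0.2)

    def test_duplicate_term_infinite(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.standard_normal(50)})
        df["b"] = df["a"]
        vifs = variance_inflation(df, ["a", "b"])
        assert math.isinf(vifs["a"]) and math.isinf(vifs["b"])

    def test_near_collinear_matches_closed_form(self):
        rng = np.random.default_rng(2)
        x1 = rng.standard_normal(500)
        x2 = x1 + rng.normal(0, 0.05, 500)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        vifs = variance_inflation(df, ["x1", "x2"])
        r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        assert vifs["x2"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)
        assert vifs["x2"] > 10

    def test_too_few_rows(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            variance_inflation(df, ["a", "b"])


class TestBlandAltman:
    def test_identity(self):
        s = bland_altman([30.0, 31.0, 32.0], [30.0, 31.0, 32.0])
        assert s.bias == 0.0 and s.sd_diff == 0.0
        assert s.pct_within_1wk == 100.0 and s.pct_within_2wk == 100.0

    def test_hand_computed_example(self):
        ref = [30.0, 31.0, 32.0, 33.0]
        pred = [29.0, 31.0, 33.0, 35.0]  # diffs -1, 0, 1, 2
        s = bland_altman(pred, ref)
        assert s.bias == pytest.approx(0.5, abs=1e-12)
        assert s.sd_diff == pytest.approx(math.sqrt(5.0 / 3.0), abs=1e-12)  # ~1.291
        assert s.loa_low == pytest.approx(0.5 - 1.96 * s.sd_diff, abs=1e-12)
        assert s.loa_high == pytest.approx(0.5 + 1.96 * s.sd_diff, abs=1e-12)
        assert s.loa_low == pytest.approx(-2.03, abs=0.01)
        assert s.loa_high == pytest.approx(3.03, abs=0.01)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(28, 37, 30)
        pred = ref + rng.normal(0, 1, 30)
        s0 = bland_altman(pred, ref)
        s2 = bland_altman(pred + 2.0, ref)
        assert s2.bias == pytest.approx(s0.bias + 2.0, abs=1e-12)
        assert s2.sd_diff == pytest.approx(s0.sd_diff, abs=1e-12)

    def test_pearson_matches_two_pass_formula(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(28, 37, 50)
        pred = 0.8 * ref + rng.normal(0, 1, 50) + 6
        s = bland_altman(pred, ref)
        mx, my = pred.mean(), ref.mean()
        num = np.sum((pred - mx) * (ref - my))
        den = math.sqrt(np.sum((pred - mx) ** 2) * np.sum((ref - my) ** 2))
        assert s.pearson_r == pytest.approx(num / den, abs=1e-12)

    def test_pct_within_ordering(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(28, 37, 100)
        pred = ref + rng.normal(0, 1.5, 100)
        s = bland_altman(pred, ref)
        assert 0 <= s.pct_within_1wk <= s.pct_within_2wk <= 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            bland_altman([1.0, 2.0], [1.0])


class TestHittner:
    @pytest.mark.parametrize(
        "grade,expected",
        [("I", (33, 34)), ("II", (31, 32)), ("III", (29, 30)), ("IV", (27, 28))],
    )
    def test_printed_ranges(self, grade, expected):
        assert hittner_grade_range(grade) == expected

    def test_unknown_grade(self):
        with pytest.raises(ValueError):
            hittner_grade_range("V")

    def test_inverse_classifier(self):
        assert classify_hittner_grade(30.0) == "III"
        assert classify_hittner_grade(27.0) == "IV"
        assert classify_hittner_grade(34.9) == "I"

    def test_midpoints_round_trip(self):
        for grade in ("I", "II", "III", "IV"):
            lo, hi = hittner_grade_range(grade)
            assert classify_hittner_grade((lo + hi) / 2) == grade

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_hittner_grade(26.0)
        with pytest.raises(ValueError):
            classify_hittner_grade(35.0)
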