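"""Cohort statistics: comparisons, agreement, correlation, logistic, ROC,
nomogram, calibration.

The 2×2 contingency tables printed for the modeled 57-patient cohort fully
determine the patient-level data for binary covariates, so the published
univariate odds ratios serve as exact oracles for the logistic fitter.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from drcsi import stats as st
from drcsi.cohort_reference import CONTINGENCY_TABLES, table_for_logit
from drcsi.synthetic import CohortSpec, make_cohort

# covariate -> odds ratio published for the cohort (cross-product identity)
PUBLISHED_UNIVARIATE_OR = {
    "sex": 0.744,
    "cT": 4.278,
    "HG": 2.229,
    "TSR": 1.983,
    "PNI": 3.733,
    "Ki67": 0.398,
    "p53": 1.179,
}


class TestCompareGroups:
    def test_chi2_on_printed_ct_stage_table(self):
        res = st.compare_groups(CONTINGENCY_TABLES["cT"], kind="categorical")
        assert res.test == "chi2"
        assert res.p_value == pytest.approx(0.015, abs=5e-4)

    def test_identical_groups_mannwhitney_p_one(self):
        # heavily skewed values fail the normality gate, landing in the U-test
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 9.0, 80.0])
        res = st.compare_groups((x, x.copy()), "continuous")
        assert res.test == "mannwhitney_u"
        assert res.p_value == pytest.approx(1.0)

    def test_large_normal_shift_uses_t_test_with_tiny_p(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(0.5, 1, 10_000)
        res = st.compare_groups((a, b), "continuous")
        assert res.test == "welch_t"
        assert res.p_value < 1e-10

    def test_skewed_data_gated_to_mannwhitney(self):
        rng = np.random.default_rng(3)
        a = rng.exponential(1.0, 200)
        b = rng.exponential(1.5, 200)
        assert st.compare_groups((a, b), "continuous").test == "mannwhitney_u"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.compare_groups((np.array([1.0]), np.array([1.0, 2.0])), "continuous")


class TestIcc:
    def test_identical_raters_icc_one_excellent(self):
        r = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        icc, band = st.icc_agreement(r)
        assert icc == pytest.approx(1.0, abs=1e-9)
        assert band == "excellent"

    def test_band_labels_at_published_cutpoints(self):
        assert st.icc_band(0.874) == "excellent"
        assert st.icc_band(0.3) == "poor"
        assert st.icc_band(0.5) == "fair"
        assert st.icc_band(0.7) == "good"
        assert st.icc_band(0.75) == "good"

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(8)
        r = rng.normal(size=(2, 200))
        icc, _ = st.icc_agreement(r)
        assert abs(icc) < 0.15

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            st.icc_agreement(np.ones((2, 2)))


class TestCorrelate:
    def test_perfect_2x2_phi(self):
        assert st.phi_coefficient([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_pni_clnm_phi_from_printed_counts(self):
        phi = st.phi_coefficient(CONTINGENCY_TABLES["PNI"])
        # brute-force (ad − bc)/√ of margins on the printed counts
        assert phi == pytest.approx((14 * 24 - 10 * 9) / np.sqrt(24 * 33 * 23 * 34))
        assert phi == pytest.approx(0.31, abs=0.005)

    def test_identity_continuous_correlation(self, rng):
        x = rng.normal(size=50)
        assert st.correlate(x, x) == pytest.approx(1.0)

    def test_point_biserial_equals_pearson_on_coded_data(self, rng):
        x = rng.normal(size=200)
        y = (x + rng.normal(size=200) > 0).astype(float)
        assert st.correlate(x, y, ("continuous", "binary")) == pytest.approx(
            sps.pearsonr(x, y).statistic
        )

    def test_binary_binary_matches_phi_table(self):
        y, x = table_for_logit("PNI")
        phi_direct = st.correlate(x, y, ("binary", "binary"))
        assert phi_direct == pytest.approx(st.phi_coefficient(CONTINGENCY_TABLES["PNI"]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.correlate(np.ones(10), np.arange(10.0))


class TestUnivariateLogistic:
    @pytest.mark.parametrize("name,expected", sorted(PUBLISHED_UNIVARIATE_OR.items()))
    def test_published_odds_ratios_reproduced_exactly(self, name, expected):
        y, x = table_for_logit(name)
        term = st.univariate_logistic(y, x, name).terms[0]
        t = CONTINGENCY_TABLES[name].astype(float)
        cross_product = (t[1, 1] * t[0, 0]) / (t[1, 0] * t[0, 1])
        assert term.odds_ratio == pytest.approx(cross_product, rel=1e-6)
        assert round(term.odds_ratio, 3) == expected

    def test_pni_wald_interval_matches_published(self):
        y, x = table_for_logit("PNI")
        term = st.univariate_logistic(y, x, "PNI").terms[0]
        assert round(term.ci_low, 3) == 1.223
        assert round(term.ci_high, 3) == 11.396

    def test_uninformative_predictor_or_one(self):
        y = np.array([0, 0, 1, 1] * 10)
        x = np.array([0, 1, 0, 1] * 10)
        term = st.univariate_logistic(y, x).terms[0]
        assert term.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            st.univariate_logistic(np.zeros(10), np.arange(10))

    def test_complete_separation_flagged(self):
        y = np.array([0] * 10 + [1] * 10)
        x = y.astype(float)
        term = st.univariate_logistic(y, x).terms[0]
        assert term.flagged


class TestMultivariateLogistic:
    def test_single_predictor_equals_univariate(self):
        y, x = table_for_logit("cT")
        uni = st.univariate_logistic(y, x, "cT").terms[0]
        mv = st.multivariate_logistic(y, pd.DataFrame({"cT": x})).terms[0]
        assert mv.odds_ratio == pytest.approx(uni.odds_ratio, rel=1e-9)

    def test_duplicate_predictor_flagged_singular(self, rng):
        y = rng.integers(0, 2, 100)
        x = rng.normal(size=100)
        fit = st.multivariate_logistic(y, pd.DataFrame({"a": x, "b": x}))
        assert all(t.flagged for t in fit.terms)

    def test_recovers_generating_odds_ratios(self):
        df = make_cohort(CohortSpec(n=1000, seed=42))
        fit = st.multivariate_logistic(df.CLNM, df[["V_B", "DOI"]])
        assert fit.term("V_B").odds_ratio == pytest.approx(1.079, rel=0.15)
        assert fit.term("DOI").odds_ratio == pytest.approx(3.394, rel=0.15)

    def test_backward_selection_drops_noise_keeps_signal(self):
        df = make_cohort(CohortSpec(n=800, seed=9))
        rng = np.random.default_rng(0)
        df["noise"] = rng.normal(size=len(df))
        fit, kept = st.backward_selection(df.CLNM, df[["V_B", "DOI", "noise"]])
        assert "V_B" in kept
        assert "noise" not in kept


class TestVif:
    def test_two_predictor_closed_form(self, rng):
        # construct a pair with exact sample correlation r = 0.31
        n = 500
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std()
        xs = (x - x.mean()) / x.std()
        z_orth = z - (z @ xs) / (xs @ xs) * xs
        z_orth /= z_orth.std()
        for r, expected in [(0.31, 1.106), (0.9, 5.263)]:
            y = r * xs + np.sqrt(1 - r**2) * z_orth
            out = st.vif(pd.DataFrame({"a": xs, "b": y}))
            assert out["a"] == pytest.approx(1 / (1 - r**2), rel=1e-6)
            assert round(out["a"], 3) == expected

    def test_orthogonal_predictors_vif_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        out = st.vif(pd.DataFrame({"a": x, "b": y}))
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_perfect_collinearity_infinite(self, rng):
        x = rng.normal(size=50)
        out = st.vif(pd.DataFrame({"a": x, "b": 2 * x}))
        assert np.isinf(out["a"])


class TestRoc:
    def test_perfect_separation(self):
        y = np.array([0] * 20 + [1] * 20)
        s = y.astype(float)
        res = st.roc_analysis(y, s)
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(1.0)

    def test_uninformative_score_near_half(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 2000)
        s = rng.normal(size=2000)
        assert st.roc_analysis(y, s).auc == pytest.approx(0.5, abs=0.04)

    def test_auc_equals_normalized_mannwhitney_u(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            s = rng.normal(size=60) + 0.3 * y
            auc = st.roc_analysis(y, s).auc
            u = sps.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
            assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()), abs=1e-12)

    def test_constant_score_degenerate(self):
        y = np.array([0, 1] * 10)
        res = st.roc_analysis(y, np.ones(20))
        assert res.degenerate and res.auc == 0.5

    def test_delong_interval_contains_auc(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200) + y
        res = st.roc_analysis(y, s)
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.ci_high - res.ci_low < 0.3

    def test_youden_cutoff_maximizes_j(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 300)
        s = rng.normal(size=300) + 1.2 * y
        res = st.roc_analysis(y, s)
        j_at_cut = (s[y == 1] >= res.cutoff).mean() + (s[y == 0] < res.cutoff).mean() - 1
        # exhaustive threshold sweep as the oracle
        best = max(
            (s[y == 1] >= c).mean() + (s[y == 0] < c).mean() - 1 for c in np.unique(s)
        )
        assert j_at_cut == pytest.approx(best, abs=1e-12)


class TestCombinedModel:
    def test_combined_beats_or_matches_singles_when_one_informative(self):
        df = make_cohort(CohortSpec(n=600, seed=17, or_doi=1.0))
        _, _, roc_combined = st.combined_model(df.CLNM, df)
        auc_vb = st.roc_analysis(df.CLNM, df.V_B).auc
        auc_doi = st.roc_analysis(df.CLNM, df.DOI).auc
        assert roc_combined.auc >= max(auc_vb, auc_doi) - 0.02

    def test_pure_noise_predictors_near_half(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "CLNM": rng.integers(0, 2, 800),
                "DOI": rng.normal(size=800),
                "V_B": rng.normal(size=800),
            }
        )
        _, _, roc = st.combined_model(df.CLNM, df)
        assert roc.auc == pytest.approx(0.5, abs=0.06)

    def test_deterministic_threshold_outcome_gives_auc_one(self):
        rng = np.random.default_rng(6)
        vb = rng.uniform(0, 40, 200)
        df = pd.DataFrame(
            {"V_B": vb, "DOI": rng.normal(1.5, 0.5, 200), "CLNM": (vb > 15).astype(int)}
        )
        _, _, roc = st.combined_model(df.CLNM, df)
        assert roc.auc == pytest.approx(1.0)


class TestNomogram:
    @pytest.fixture()
    def fitted(self):
        df = make_cohort(CohortSpec(n=300, seed=23))
        fit = st.multivariate_logistic(df.CLNM, df[["DOI", "V_B"]])
        ranges = {
            "DOI": (df.DOI.min(), df.DOI.max()),
            "V_B": (df.V_B.min(), df.V_B.max()),
        }
        return df, fit, st.build_nomogram(fit, ranges)

    def test_round_trip_risk_equals_model_probability(self, fitted):
        df, fit, nomo = fitted
        pts = nomo.points(df)
        np.testing.assert_allclose(
            nomo.risk_from_points(pts["total"]), fit.predict_proba(df), atol=1e-9
        )

    def test_range_min_scores_zero_points(self, fitted):
        df, fit, nomo = fitted
        probe = pd.DataFrame(
            {"DOI": [nomo.ranges["DOI"][0]], "V_B": [nomo.ranges["V_B"][0]]}
        )
        pts = nomo.points(probe)
        # both coefficients are positive here, so range-min → 0 points
        assert pts["DOI"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert pts["V_B"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_dominant_variable_spans_hundred_points(self, fitted):
        df, fit, nomo = fitted
        widths = {
            t.name: abs(t.coef) * (nomo.ranges[t.name][1] - nomo.ranges[t.name][0])
            for t in fit.terms
        }
        top = max(widths, key=widths.get)
        probe = pd.DataFrame({k: [v[1]] for k, v in nomo.ranges.items()})
        assert nomo.points(probe)[top].iloc[0] == pytest.approx(100.0)

    def test_zero_width_range_rejected(self, fitted):
        _, fit, _ = fitted
        with pytest.raises(ValueError):
            st.build_nomogram(fit, {"DOI": (1.0, 1.0), "V_B": (0.0, 40.0)})


class TestCalibration:
    def test_well_calibrated_simulation_tracks_diagonal(self):
        df = make_cohort(CohortSpec(n=5000, seed=31))
        fit = st.multivariate_logistic(df.CLNM, df[["V_B", "DOI"]])
        cal = st.calibration_curve(fit, df, bins=10, bootstrap_reps=20, seed=1)
        assert (cal.observed - cal.predicted).abs().max() < 0.05

    def test_same_seed_reproducible(self):
        df = make_cohort(CohortSpec(n=400, seed=2))
        fit = st.multivariate_logistic(df.CLNM, df[["V_B", "DOI"]])
        a = st.calibration_curve(fit, df, bootstrap_reps=10, seed=7)
        b = st.calibration_curve(fit, df, bootstrap_reps=10, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_parameters_rejected(self):
        df = make_cohort(CohortSpec(n=100, seed=2))
        fit = st.multivariate_logistic(df.CLNM, df[["V_B", "DOI"]])
        with pytest.raises(ValueError):
            st.calibration_curve(fit, df, bins=1)
        with pytest.raises(ValueError):
            st.calibration_curve(fit, df, bootstrap_reps=0)
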