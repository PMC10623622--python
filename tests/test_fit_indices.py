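"""Fit statistics: chi-square, RMSEA, SRMR, CFI/TLI, AIC/BIC, LR tests."""

import numpy as np
import pytest
from scipy import stats

import itemfx as fx
from itemfx._structure import saturated_neg2ll_complete
from itemfx.fit_indices import FitIndexReport


class TestChiSquare:
    def test_consistent_with_df_count_and_scale_option(self, fit3):
        chi2_n, df, p = fx.chi_square(fit3, scale="N")
        chi2_n1, _, _ = fx.chi_square(fit3, scale="N-1")
        assert df == fx.count_df(fit3.spec) == 85
        assert chi2_n1 == pytest.approx(chi2_n * (fit3.N_used - 1)
                                        / fit3.N_used, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(chi2_n, df), rel=1e-12)

    def test_perfect_fit_zero_statistic(self, fit3):
        im = fit3.implied()
        clone = fx.FittedModel(**{**fit3.__dict__})
        clone.sample = fx.SampleMoments(ybar=im.mu.copy(),
                                        S=im.Sigma.copy(), N=fit3.N_used)
        chi2, _, p = fx.chi_square(clone)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0)


class TestRmsea:
    def test_zero_when_chi2_at_or_below_df(self):
        assert fx.rmsea(85.0, 85, 2543) == 0.0
        assert fx.rmsea(50.0, 85, 2543) == 0.0

    def test_interval_brackets_point_estimate(self, fit3):
        chi2, df, _ = fx.chi_square(fit3)
        point = fx.rmsea(chi2, df, fit3.N_used)
        lo, hi = fx.rmsea_ci90(chi2, df, fit3.N_used)
        assert lo <= hi
        if chi2 > df:
            assert lo <= point <= hi

    def test_requires_positive_df(self):
        with pytest.raises(ValueError):
            fx.rmsea(10.0, 0, 100)


class TestBaseline:
    def test_df_formula(self, fit3):
        _, df_b = fx.baseline_fit(fit3)
        assert df_b == 105  # p(p-1)/2 with p = 15

    def test_uncorrelated_sample_gives_zero_chi2(self):
        sm = fx.SampleMoments(ybar=np.zeros(4), S=np.diag([1.0, 2.0, 3.0,
                                                           4.0]), N=100)
        chi2_b, df_b = fx.baseline_fit(sm)
        assert chi2_b == pytest.approx(0.0, abs=1e-10)
        assert df_b == 6

    def test_baseline_far_exceeds_model_chi2(self, fit3):
        chi2, _, _ = fx.chi_square(fit3)
        chi2_b, _ = fx.baseline_fit(fit3)
        assert chi2_b > 50 * chi2


class TestIncrementalIndices:
    def test_cfi_edges(self):
        assert fx.cfi(85.0, 85, 1000.0, 105) == 1.0
        assert fx.cfi(1000.0, 105, 1000.0, 105) == 0.0
        assert fx.tli(1000.0, 105, 1000.0, 105) == 0.0

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError):
            fx.tli(10.0, 0, 100.0, 10)

    def test_cross_route_against_independent_loglik_chain(self, fit3,
                                                          panel2000, spec3):
        """Dual-route check: rebuild chi2 / CFI / TLI from scipy row-wise
        log-densities and closed-form saturated/baseline quantities."""
        Y = panel2000[list(spec3.design.observed_labels)].to_numpy()
        im = fit3.implied()
        ll_model = stats.multivariate_normal.logpdf(Y, im.mu,
                                                    im.Sigma).sum()
        sm = fit3.sample
        ll_sat = -0.5 * saturated_neg2ll_complete(sm.N, sm.S)
        chi2_alt = 2.0 * (ll_sat - ll_model)
        ll_base = stats.norm.logpdf(
            Y, sm.ybar, np.sqrt(np.diag(sm.S))).sum()
        chi2_b_alt = 2.0 * (ll_sat - ll_base)
        rep = fx.fit_report(fit3)
        assert rep.chi2 == pytest.approx(chi2_alt, rel=1e-6)
        assert rep.chi2_baseline == pytest.approx(chi2_b_alt, rel=1e-6)
        assert rep.cfi == pytest.approx(
            fx.cfi(chi2_alt, rep.df, chi2_b_alt, rep.df_baseline), abs=1e-9)
        assert rep.tli == pytest.approx(
            fx.tli(chi2_alt, rep.df, chi2_b_alt, rep.df_baseline), abs=1e-9)


class TestSrmr:
    def test_hand_arithmetic_two_variables(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        Sig = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert fx.srmr(Sig, S) == pytest.approx(np.sqrt(0.01 / 3.0),
                                                rel=1e-12)

    def test_zero_when_equal(self, fit3):
        assert fx.srmr(fit3.sample.S, fit3.sample.S) == 0.0

    @pytest.mark.parametrize("scale", [0.1, 3.0, 40.0])
    def test_invariant_under_common_rescaling(self, fit3, scale):
        S = fit3.sample.S
        Sig = fit3.implied().Sigma
        d = np.full(S.shape[0], scale)
        D = np.outer(d, d)
        assert fx.srmr(Sig * D, S * D) == pytest.approx(fx.srmr(Sig, S),
                                                        rel=1e-10)

    def test_zero_variance_rejected(self):
        S = np.diag([1.0, 0.0])
        with pytest.raises(ValueError):
            fx.srmr(S, S)


class TestModelComparison:
    def test_information_criteria_formulas(self, fit3):
        aic, bic = fx.information_criteria(fit3)
        assert aic == pytest.approx(-2 * fit3.loglik + 2 * 50, rel=1e-12)
        assert bic == pytest.approx(
            -2 * fit3.loglik + 50 * np.log(fit3.N_used), rel=1e-12)

    def test_lr_identical_fits_zero(self, fit3, spec3, panel2000):
        refit = fx.fit(spec3, panel2000)
        stat, ddf, p = fx.lr_test(fit3, refit)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert ddf == 0 and p == 1.0

    def test_lr_variants_ddf_18(self, fit_states, fit3):
        stat, ddf, p = fx.lr_test(fit_states, fit3)
        assert ddf == 18
        assert stat > 0
        assert p < 1e-10  # deltas were generated with large variance

    def test_aic_prefers_item_effects_under_true_item_effects(self, spec3,
                                                              spec_states,
                                                              truth):
        wins = 0
        for r in range(20):
            df = fx.simulate_panel(fx.SimConfig(
                spec=spec3, params=truth, n=500, seed=6000 + r))
            aic_fx, _ = fx.information_criteria(fx.fit(spec3, df))
            aic_st, _ = fx.information_criteria(fx.fit(spec_states, df))
            wins += aic_fx < aic_st
        assert wins >= 19


class TestReportAndClassifier:
    def test_report_invariants(self, fit3):
        rep = fx.fit_report(fit3)
        assert rep.rmsea >= 0 and 0 <= rep.cfi <= 1 and rep.srmr >= 0
        assert rep.rmsea_ci90[0] <= rep.rmsea_ci90[1]

    def test_well_specified_model_classified_good(self, fit3, fit_states):
        assert fx.classify_fit(fx.fit_report(fit3)) == "good"
        assert fx.classify_fit(fx.fit_report(fit_states)) == "poor"

    @pytest.mark.parametrize(
        "cfi_v, tli_v, rmsea_v, srmr_v, label",
        [
            (0.99, 0.98, 0.04, 0.02, "good"),
            (0.96, 0.955, 0.07, 0.08, "acceptable"),
            (0.96, 0.955, 0.09, 0.08, "poor"),
            (0.894, 0.892, 0.111, 0.06, "poor"),
        ],
    )
    def test_threshold_classifier(self, cfi_v, tli_v, rmsea_v, srmr_v,
                                  label):
        rep = FitIndexReport(
            chi2=100.0, df=85, p_value=0.5, rmsea=rmsea_v,
            rmsea_ci90=(rmsea_v, rmsea_v), srmr=srmr_v, cfi=cfi_v,
            tli=tli_v, aic=0.0, bic=0.0, chi2_baseline=1000.0,
            df_baseline=105, N=2543,
        )
        assert fx.classify_fit(rep) == label

    def test_fiml_report_close_to_listwise_under_mcar(self, spec3, truth):
        df = fx.simulate_panel(fx.SimConfig(
            spec=spec3, params=truth, n=2500, wave_missing_rate=0.2,
            seed=71))
        rep_f = fx.fit_report(fx.fit(spec3, df, estimator="fiml"))
        rep_l = fx.fit_report(fx.fit(spec3, df, estimator="listwise"))
        assert rep_f.df == rep_l.df == 85
        assert abs(rep_f.cfi - rep_l.cfi) < 0.02
        assert abs(rep_f.rmsea - rep_l.rmsea) < 0.02
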