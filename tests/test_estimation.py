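"""ML/FIML estimation: discrepancy, likelihood identities, recovery, SEs."""

import numpy as np
import pytest
from scipy import stats

import itemfx as fx
from itemfx.estimation import listwise, panel_matrix
from itemfx.model_spec import ImpliedMoments


class TestSampleMoments:
    def test_identical_rows_zero_covariance(self):
        sm = fx.sample_moments(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert np.allclose(sm.S, 0.0)

    def test_hand_arithmetic(self):
        sm = fx.sample_moments(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert np.allclose(sm.ybar, [1.0, 1.0])
        assert np.allclose(sm.S, [[1.0, 1.0], [1.0, 1.0]])

    def test_missing_values_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="fiml|listwise"):
            fx.sample_moments(np.array([[1.0, np.nan], [1.0, 2.0]]))

    def test_converges_to_population_covariance(self, spec3, truth):
        im = fx.implied_moments(spec3, truth)
        dists = []
        for n in (500, 50_000):
            df = fx.simulate_panel(
                fx.SimConfig(spec=spec3, params=truth, n=n, seed=3))
            sm = fx.sample_moments(df.to_numpy())
            dists.append(np.linalg.norm(sm.S - im.Sigma))
        assert dists[1] < dists[0] / 3


class TestDiscrepancy:
    def test_zero_iff_moments_match(self, fit3):
        im = fit3.implied()
        sm = fit3.sample
        exact = fx.SampleMoments(ybar=im.mu.copy(), S=im.Sigma.copy(),
                                 N=sm.N)
        assert fx.fml_discrepancy(im, exact) == pytest.approx(0.0, abs=1e-12)
        assert fx.fml_discrepancy(im, sm) > 0

    def test_scalar_closed_form(self):
        im = ImpliedMoments(mu=np.array([0.0]), Sigma=np.array([[2.0]]))
        sm = fx.SampleMoments(ybar=np.array([0.0]), S=np.array([[1.0]]), N=10)
        expected = np.log(2.0) + 0.5 - 1.0
        assert fx.fml_discrepancy(im, sm) == pytest.approx(expected,
                                                           rel=1e-12)

    def test_times_n_equals_chi_square(self, fit3):
        chi2, _, _ = fx.chi_square(fit3)
        assert chi2 == pytest.approx(fit3.N_used * fit3.fml_value, rel=1e-10)


class TestLikelihood:
    def test_neg2ll_equals_n_fml_plus_constant(self, fit3):
        """-2 loglik = N (F_ML + ln|S| + p + p ln 2pi) algebraically."""
        sm = fit3.sample
        p = sm.S.shape[0]
        const = np.linalg.slogdet(sm.S)[1] + p + p * np.log(2 * np.pi)
        lhs = -2.0 * fit3.loglik
        rhs = sm.N * (fit3.fml_value + const)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_loglik_matches_scipy_rowwise_densities(self, spec3, truth):
        """Independent oracle: summed scipy multivariate-normal
        log-densities equal the moment-based log-likelihood."""
        df = fx.simulate_panel(
            fx.SimConfig(spec=spec3, params=truth, n=150, seed=21))
        Y = df.to_numpy()
        im = fx.implied_moments(spec3, truth)
        direct = stats.multivariate_normal.logpdf(Y, im.mu, im.Sigma).sum()
        assert fx.fiml_loglik(spec3, truth, df) == pytest.approx(
            direct, rel=1e-12)

    def test_fiml_equals_ml_on_complete_data(self, spec3, fit3, panel2000):
        ll = fx.fiml_loglik(spec3, fit3.params,
                            panel2000[list(spec3.design.observed_labels)])
        assert abs(ll - fit3.loglik) <= 1e-8 * abs(fit3.loglik)

    def test_single_observed_entry_contributes_univariate_density(
            self, spec3, truth):
        df = fx.simulate_panel(
            fx.SimConfig(spec=spec3, params=truth, n=20, seed=5))
        base = fx.fiml_loglik(spec3, truth, df)
        extra = df.iloc[:1].copy()
        extra.iloc[0, 1:] = np.nan
        y0 = extra.iloc[0, 0]
        im = fx.implied_moments(spec3, truth)
        expected = stats.norm.logpdf(y0, im.mu[0], np.sqrt(im.Sigma[0, 0]))
        combined = fx.fiml_loglik(spec3, truth,
                                  __import__("pandas").concat([df, extra]))
        assert combined - base == pytest.approx(expected, rel=1e-10)

    def test_row_without_observations_rejected(self, spec3, truth):
        df = fx.simulate_panel(
            fx.SimConfig(spec=spec3, params=truth, n=5, seed=5))
        df.iloc[2, :] = np.nan
        with pytest.raises(ValueError, match="at least one observed"):
            fx.fiml_loglik(spec3, truth, df)


class TestFit:
    def test_single_sample_recovery_within_3_se(self, fit3, truth):
        se = fit3.se()
        true_natural = np.concatenate([
            truth.kappa, truth.Phi[np.tril_indices(7)], truth.theta,
        ])
        z = np.abs(fit3.natural - true_natural) / se
        assert np.mean(z <= 3.0) >= 0.95

    def test_loglik_invariant_to_reference_item(self, fit3, fit5):
        rel = abs(fit3.loglik - fit5.loglik) / abs(fit3.loglik)
        assert rel <= 1e-6

    def test_near_saturated_data_gives_near_zero_discrepancy(self, spec3,
                                                             truth):
        tiny = truth.copy()
        tiny.theta = np.full_like(tiny.theta, 1e-4)
        df = fx.simulate_panel(
            fx.SimConfig(spec=spec3, params=tiny, n=3000, seed=13))
        fitted = fx.fit(spec3, df)
        assert fitted.fml_value < 0.05

    def test_nonconvergence_is_flagged_not_raised(self, spec3, panel2000):
        fitted = fx.fit(spec3, panel2000, max_iter=1, gtol=1e-12)
        assert fitted.converged is False
        assert np.isfinite(fitted.loglik)

    def test_listwise_equals_ml_on_complete_subset(self, spec3, truth):
        df = fx.simulate_panel(fx.SimConfig(
            spec=spec3, params=truth, n=1500, wave_missing_rate=0.25,
            seed=31))
        fitted_lw = fx.fit(spec3, df, estimator="listwise")
        complete = df.dropna()
        fitted_ml = fx.fit(spec3, complete)
        assert fitted_lw.N_used == len(complete)
        assert fitted_lw.loglik == pytest.approx(fitted_ml.loglik, rel=1e-10)

    def test_ml_rejects_missing_data(self, spec3, truth):
        df = fx.simulate_panel(fx.SimConfig(
            spec=spec3, params=truth, n=200, wave_missing_rate=0.3, seed=1))
        with pytest.raises(ValueError, match="fiml|listwise"):
            fx.fit(spec3, df, estimator="ml")


class TestStandardErrors:
    def test_doubled_sample_shrinks_se_by_sqrt2(self, spec3, panel2000,
                                                fit3):
        doubled = __import__("pandas").concat([panel2000, panel2000],
                                              ignore_index=True)
        fitted2 = fx.fit(spec3, doubled)
        ratio = fitted2.se() / fit3.se()
        assert np.allclose(ratio, 1.0 / np.sqrt(2.0), atol=5e-3)

    def test_fixed_parameters_not_in_vcov(self, fit3):
        assert fit3.vcov is None or fit3.vcov.shape == (50, 50)
        vc = fx.standard_errors(fit3)
        assert vc.shape == (fit3.n_free, fit3.n_free)
        assert not any(name.startswith(("lambda", "alpha"))
                       for name in fit3.param_names)

    def test_vcov_positive_diagonal(self, fit3):
        assert np.all(np.diag(fx.standard_errors(fit3)) > 0)


def test_panel_matrix_validates_columns(spec3, truth):
    df = fx.simulate_panel(fx.SimConfig(spec=spec3, params=truth, n=5,
                                        seed=2))
    with pytest.raises(ValueError, match="missing panel columns"):
        panel_matrix(df.drop(columns=["item1_w1"]), spec3.design)
    assert listwise(panel_matrix(df, spec3.design)).shape == (5, 15)
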