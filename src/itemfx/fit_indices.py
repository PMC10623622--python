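"""Model-fit statistics and model-comparison criteria.

The model chi-square is ``N * F_ML`` at the estimate (the ``N-1``
multiplier is available as an option); for FIML fits it is the
likelihood-ratio statistic against the saturated model, obtained by an
EM fit of the unstructured mean/covariance.  RMSEA always uses ``N-1``
in its denominator (the classic formula); its 90% confidence interval
inverts the noncentral chi-square distribution for the noncentrality
parameter.  The baseline model for CFI/TLI is the independence model
with free means and variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._structure import (
    em_saturated,
    independence_structure,
    saturated_neg2ll_complete,
)
from .estimation import FittedModel, SampleMoments
from .model_spec import count_df

__all__ = [
    "FitIndexReport",
    "chi_square",
    "rmsea",
    "rmsea_ci90",
    "baseline_fit",
    "cfi",
    "tli",
    "srmr",
    "information_criteria",
    "lr_test",
    "fit_report",
    "classify_fit",
]

GOOD_CUTOFFS = {"cfi": 0.97, "tli": 0.97, "rmsea": 0.05, "srmr": 0.05}
ACCEPTABLE_CUTOFFS = {"cfi": 0.95, "tli": 0.95, "rmsea": 0.08, "srmr": 0.10}


@dataclass
class FitIndexReport:
    chi2: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    cfi: float
    tli: float
    aic: float
    bic: float
    chi2_baseline: float
    df_baseline: int
    N: int


def _chi2_multiplier(N: int, scale: str) -> float:
    if scale == "N":
        return float(N)
    if scale in ("N-1", "N1", "nm1"):
        return float(N - 1)
    raise ValueError("chi2 scale must be 'N' or 'N-1'")


def _saturated_neg2ll(fitted: FittedModel) -> float:
    if fitted.sample is not None:
        return saturated_neg2ll_complete(fitted.sample.N, fitted.sample.S)
    p = fitted.structure.p
    _, _, f = em_saturated(fitted.patterns, p)
    return f


def chi_square(
    fitted: FittedModel, *, scale: str = "N"
) -> tuple[float, int, float]:
    """Likelihood-ratio test of the model against the saturated model."""
    df = count_df(fitted.spec) if hasattr(fitted.spec, "design") else (
        fitted.structure.p * (fitted.structure.p + 3) // 2 - fitted.n_free
    )
    if fitted.sample is not None:
        stat = _chi2_multiplier(fitted.N_used, scale) * fitted.fml_value
    else:
        stat = -2.0 * fitted.loglik - _saturated_neg2ll(fitted)
    stat = max(float(stat), 0.0)
    p_value = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p_value


def rmsea(chi2: float, df: int, N: int) -> float:
    """Point RMSEA: sqrt(max(chi2 - df, 0) / (df * (N - 1)))."""
    if df <= 0 or N <= 1:
        raise ValueError("rmsea requires df > 0 and N > 1")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (N - 1))))


def _ncp_bound(chi2: float, df: int, q: float) -> float:
    """Noncentrality lambda with ncx2.cdf(chi2, df, lambda) = q."""
    if stats.ncx2.cdf(chi2, df, 0.0) < q:
        return 0.0
    hi = max(chi2 * 10.0, 10.0)
    while stats.ncx2.cdf(chi2, df, hi) > q:
        hi *= 2.0
    return float(optimize.brentq(
        lambda lam: stats.ncx2.cdf(chi2, df, lam) - q, 0.0, hi, xtol=1e-8
    ))


def rmsea_ci90(chi2: float, df: int, N: int) -> tuple[float, float]:
    """90% confidence interval for RMSEA via the noncentral chi-square."""
    if df <= 0 or N <= 1:
        raise ValueError("rmsea requires df > 0 and N > 1")
    lo = _ncp_bound(chi2, df, 0.95)
    hi = _ncp_bound(chi2, df, 0.05)
    scale = df * (N - 1)
    return (float(np.sqrt(lo / scale)), float(np.sqrt(hi / scale)))


def baseline_fit(
    fitted_or_sample, *, scale: str = "N", patterns=None
) -> tuple[float, int]:
    """Independence-model fit (free means/variances, zero covariances)."""
    if isinstance(fitted_or_sample, SampleMoments):
        sample = fitted_or_sample
        p = sample.S.shape[0]
        with np.errstate(divide="raise"):
            chi2_b = _chi2_multiplier(sample.N, scale) * float(
                np.sum(np.log(np.diag(sample.S)))
                - np.linalg.slogdet(sample.S)[1]
            )
        return max(chi2_b, 0.0), p * (p - 1) // 2
    fitted: FittedModel = fitted_or_sample
    if fitted.sample is not None:
        return baseline_fit(fitted.sample, scale=scale)
    # FIML baseline: optimize the independence structure casewise
    p = fitted.structure.p
    structure = independence_structure(fitted.structure.obs_labels)
    means = np.zeros(p)
    var = np.ones(p)
    cnt = np.zeros(p)
    msum = np.zeros(p)
    vsum = np.zeros(p)
    for pat in fitted.patterns:
        msum[pat.idx] += pat.n * pat.ybar
        cnt[pat.idx] += pat.n
    means = msum / cnt
    for pat in fitted.patterns:
        d = pat.ybar - means[pat.idx]
        vsum[pat.idx] += pat.n * (np.diag(pat.S) + d ** 2)
    var = np.maximum(vsum / cnt, 1e-6)
    x0 = structure.x_from_components(
        np.zeros(0), np.zeros((0, 0)), (), means, var
    )
    N = fitted.N_used

    def obj(x):
        f, g = structure.neg2ll_grad(x, fitted.patterns)
        return f / N, g / N

    res = optimize.minimize(obj, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12})
    neg2ll_b = structure.neg2ll(res.x, fitted.patterns)
    chi2_b = max(neg2ll_b - _saturated_neg2ll(fitted), 0.0)
    return float(chi2_b), p * (p - 1) // 2


def cfi(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    """Comparative fit index."""
    if df_b <= 0:
        raise ValueError("baseline df must be positive")
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    return 1.0 if den == 0.0 else float(1.0 - num / den)


def tli(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    """Tucker-Lewis index (non-normed fit index)."""
    if df == 0 or df_b == 0:
        raise ValueError("TLI undefined for df = 0")
    ratio_b = chi2_b / df_b
    if ratio_b == 1.0:
        raise ValueError("TLI undefined when baseline chi2/df = 1")
    return float((ratio_b - chi2 / df) / (ratio_b - 1.0))


def srmr(Sigma_hat: np.ndarray, S: np.ndarray) -> float:
    """Standardized root mean square residual over the covariance cells.

    Root mean square of (s_ij - sigma_ij) / sqrt(s_ii s_jj) over the
    p(p+1)/2 lower-triangle cells (diagonal included); mean residuals
    are not part of the index.
    """
    Sigma_hat = np.asarray(Sigma_hat, float)
    S = np.asarray(S, float)
    if Sigma_hat.shape != S.shape:
        raise ValueError("dimension mismatch")
    d = np.diag(S)
    if np.any(d <= 0):
        raise ValueError("zero or negative sample variance")
    denom = np.sqrt(np.outer(d, d))
    resid = (S - Sigma_hat) / denom
    iu = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def information_criteria(fitted: FittedModel) -> tuple[float, float]:
    """(AIC, BIC) = (-2 loglik + 2q, -2 loglik + q ln N)."""
    neg2 = -2.0 * fitted.loglik
    q = fitted.n_free
    return (float(neg2 + 2 * q), float(neg2 + q * np.log(fitted.N_used)))


def lr_test(
    fit_nested: FittedModel, fit_full: FittedModel
) -> tuple[float, int, float]:
    """Log-likelihood difference test between nested fits on the same data."""
    if fit_nested.N_used != fit_full.N_used:
        raise ValueError("fits must use the same data")
    ddf = fit_full.n_free - fit_nested.n_free
    if ddf < 0:
        raise ValueError("models are not nested (full model must have at "
                         "least as many free parameters)")
    stat = 2.0 * (fit_full.loglik - fit_nested.loglik)
    if ddf == 0:
        return float(stat), 0, 1.0
    p = float(stats.chi2.sf(max(stat, 0.0), ddf))
    return float(stat), int(ddf), p


def fit_report(fitted: FittedModel, *, scale: str = "N") -> FitIndexReport:
    """All fit statistics of one model in a single report."""
    chi2_val, df, p_value = chi_square(fitted, scale=scale)
    chi2_b, df_b = baseline_fit(fitted, scale=scale)
    N = fitted.N_used
    if fitted.sample is not None:
        srmr_val = srmr(fitted.implied().Sigma, fitted.sample.S)
    else:
        # standardize against the EM-saturated covariance
        _, S_em, _ = em_saturated(fitted.patterns, fitted.structure.p)
        srmr_val = srmr(fitted.implied().Sigma, S_em)
    aic, bic = information_criteria(fitted)
    return FitIndexReport(
        chi2=chi2_val,
        df=df,
        p_value=p_value,
        rmsea=rmsea(chi2_val, df, N),
        rmsea_ci90=rmsea_ci90(chi2_val, df, N),
        srmr=srmr_val,
        cfi=cfi(chi2_val, df, chi2_b, df_b),
        tli=tli(chi2_val, df, chi2_b, df_b),
        aic=aic,
        bic=bic,
        chi2_baseline=chi2_b,
        df_baseline=df_b,
        N=N,
    )


def classify_fit(report: FitIndexReport) -> str:
    """'good' / 'acceptable' / 'poor' per the conventional cutoffs."""
    def ok(cuts):
        return (report.cfi >= cuts["cfi"] and report.tli >= cuts["tli"]
                and report.rmsea <= cuts["rmsea"]
                and report.srmr <= cuts["srmr"])

    if ok(GOOD_CUTOFFS):
        return "good"
    if ok(ACCEPTABLE_CUTOFFS):
        return "acceptable"
    return "poor"
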