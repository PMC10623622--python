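"""Maximum-likelihood estimation of the measurement models.

Complete data are fitted by normal-theory ML on the sample moments;
incomplete data either by listwise deletion (an explicit preprocessing
option mirroring complete-case analyses) or by full-information maximum
likelihood (FIML), which sums each respondent's normal log-density over
their observed subvector and is valid under MAR missingness.

The optimizer is a deterministic quasi-Newton (L-BFGS-B) run from
moment-based starting values with analytic gradients; the latent
covariance is parameterized by its log-Cholesky factor and residual
variances by their logs, so every iterate is admissible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from ._structure import MomentStructure, Pattern, pattern_moments
from .model_spec import (
    ImpliedMoments,
    LSTSpec,
    ParameterVector,
    count_free_parameters,
    loading_matrix,
)

__all__ = [
    "SampleMoments",
    "FittedModel",
    "sample_moments",
    "fml_discrepancy",
    "fiml_loglik",
    "fit",
    "standard_errors",
    "listwise",
    "panel_matrix",
]


@dataclass
class SampleMoments:
    """Observed mean vector and covariance matrix (divisor N)."""

    ybar: np.ndarray
    S: np.ndarray
    N: int


@dataclass
class FittedModel:
    """A converged (or flagged) model fit.

    ``natural`` holds the free parameters in their natural scale in the
    order given by ``param_names``; ``vcov`` is the observed-information
    covariance of that vector (computed lazily by
    :func:`standard_errors`).
    """

    spec: object
    structure: MomentStructure
    x_hat: np.ndarray
    natural: np.ndarray
    param_names: list[str]
    params: ParameterVector | None
    loglik: float
    n_free: int
    converged: bool
    grad_norm: float
    n_iter: int
    message: str
    N_used: int
    estimator: str
    sample: SampleMoments | None
    patterns: list[Pattern]
    vcov: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def fml_value(self) -> float:
        """ML discrepancy F at the estimate (complete-data fits only)."""
        if self.sample is None:
            raise ValueError("F_ML requires complete-data sample moments")
        c = self.structure.components(self.x_hat)
        return fml_discrepancy(
            ImpliedMoments(mu=c["mu"], Sigma=c["Sigma"]), self.sample
        )

    def implied(self) -> ImpliedMoments:
        c = self.structure.components(self.x_hat)
        return ImpliedMoments(mu=c["mu"], Sigma=c["Sigma"])

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(standard_errors(self)))

    def param_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({"parameter": self.param_names,
                            "estimate": self.natural})
        try:
            tab["se"] = self.se()
        except ValueError:
            tab["se"] = np.nan
        return tab


# ---- data handling ----------------------------------------------------


def panel_matrix(data, design) -> np.ndarray:
    """Extract the I*T panel columns in canonical order as a float array."""
    if isinstance(data, pd.DataFrame):
        missing_cols = [c for c in design.observed_labels
                        if c not in data.columns]
        if missing_cols:
            raise ValueError(f"data is missing panel columns: {missing_cols}")
        return data.loc[:, list(design.observed_labels)].to_numpy(dtype=float)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != design.p:
        raise ValueError(f"expected {design.p} columns in canonical order")
    return arr


def listwise(Y: np.ndarray) -> np.ndarray:
    """Complete-case subset (rows without any missing value)."""
    Y = np.asarray(Y, dtype=float)
    return Y[~np.isnan(Y).any(axis=1)]


def sample_moments(data) -> SampleMoments:
    """Mean vector and covariance (divisor N) of complete data."""
    Y = np.asarray(data, dtype=float)
    if np.isnan(Y).any():
        raise ValueError(
            "data contain missing values; use estimator='fiml' or apply "
            "listwise deletion first"
        )
    N = Y.shape[0]
    ybar = Y.mean(axis=0)
    dev = Y - ybar
    return SampleMoments(ybar=ybar, S=dev.T @ dev / N, N=N)


# ---- discrepancy and casewise likelihood ------------------------------


def fml_discrepancy(implied: ImpliedMoments, sample: SampleMoments) -> float:
    """Normal-theory ML discrepancy between implied and sample moments.

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p + (ybar-mu)' Sigma^-1 (ybar-mu)
    """
    Sigma, S = implied.Sigma, sample.S
    p = S.shape[0]
    try:
        cf = linalg.cho_factor(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("implied covariance is singular") from exc
    logdet_sigma = 2.0 * np.log(np.diag(cf[0])).sum()
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular")
    A = linalg.cho_solve(cf, np.eye(p))
    d = sample.ybar - implied.mu
    return float(
        logdet_sigma + np.sum(A * S) - logdet_s - p + d @ A @ d
    )


def structure_for_spec(spec: LSTSpec) -> MomentStructure:
    """Translate an :class:`LSTSpec` into the generic moment structure."""
    design = spec.design
    T = design.n_occasions
    if spec.variant == "item_effects":
        Lambda0 = loading_matrix(spec)
        lam_cells: list = []
        alpha_cells: list = []
    else:
        Lambda0 = np.zeros((design.p, spec.m))
        for t in range(1, T + 1):
            Lambda0[design.index(spec.reference_item, t), t - 1] = 1.0
        lam_cells = [
            (f"lambda[{design.item_labels[i - 1]}]",
             [(design.index(i, t), t - 1) for t in range(1, T + 1)])
            for i in range(1, design.n_items + 1)
            if i != spec.reference_item
        ]
        alpha_cells = [
            (f"alpha[{design.item_labels[i - 1]}]",
             [design.index(i, t) for t in range(1, T + 1)])
            for i in range(1, design.n_items + 1)
            if i != spec.reference_item
        ]
    return MomentStructure(
        obs_labels=design.observed_labels,
        latent_labels=spec.latent_labels,
        Lambda0=Lambda0,
        lam_cells=lam_cells,
        alpha0=np.zeros(design.p),
        alpha_cells=alpha_cells,
    )


def x_from_params(
    structure: MomentStructure, spec: LSTSpec, params: ParameterVector
) -> np.ndarray:
    params.validate(spec)
    free_items = [i for i in range(1, spec.design.n_items + 1)
                  if i != spec.reference_item]
    if spec.variant == "states_only":
        lam_vals = [params.lam[i - 1] for i in free_items]
        alpha_vals = [params.alpha[i - 1] for i in free_items]
    else:
        lam_vals, alpha_vals = [], []
    return structure.x_from_components(
        params.kappa, params.Phi, lam_vals, alpha_vals, params.theta
    )


def params_from_x(
    structure: MomentStructure, spec: LSTSpec, x: np.ndarray
) -> ParameterVector:
    c = structure.components(x)
    I = spec.design.n_items
    lam = np.ones(I)
    alpha = np.zeros(I)
    if spec.variant == "states_only":
        free_items = [i for i in range(1, I + 1) if i != spec.reference_item]
        for v, i in zip(c["lam"], free_items):
            lam[i - 1] = v
        for v, i in zip(c["alpha"], free_items):
            alpha[i - 1] = v
    return ParameterVector(
        kappa=c["kappa"], Phi=c["Phi"], lam=lam, alpha=alpha, theta=c["theta"]
    )


def fiml_loglik(spec: LSTSpec, params: ParameterVector, data) -> float:
    """Casewise (full-information) log-likelihood at fixed parameters."""
    Y = panel_matrix(data, spec.design)
    patterns = pattern_moments(Y)
    structure = structure_for_spec(spec)
    x = x_from_params(structure, spec, params)
    return -0.5 * structure.neg2ll(x, patterns)


# ---- starting values --------------------------------------------------


def _available_case_moments(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ybar = np.nanmean(Y, axis=0)
        masked = np.ma.masked_invalid(Y)
        S = np.asarray(np.ma.cov(masked, rowvar=False, bias=True))
    # pairwise-complete covariances can be NaN if a pair never co-occurs
    S = np.where(np.isnan(S), 0.0, S)
    return ybar, S


def start_values(spec: LSTSpec, ybar: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Deterministic method-of-moments starting vector.

    State means come from the reference item's observed means; the state
    covariance block from the reference item's cross-occasion
    covariances (its across-time covariance is error-free under the
    model); item-effect moments from mean/variance of the item-minus-
    reference contrasts; residual variances start at half the observed
    variances.
    """
    design = spec.design
    T, r = design.n_occasions, spec.reference_item
    m = spec.m
    ref_idx = [design.index(r, t) for t in range(1, T + 1)]
    kappa = np.zeros(m)
    kappa[:T] = ybar[ref_idx]
    Phi = np.zeros((m, m))
    ref_cov = S[np.ix_(ref_idx, ref_idx)]
    for t in range(T):
        off = [ref_cov[t, u] for u in range(T) if u != t]
        Phi[t, t] = max(float(np.mean(off)), 0.1)
        for u in range(T):
            if u != t:
                Phi[t, u] = ref_cov[t, u]
    if spec.variant == "item_effects":
        for j, i in enumerate(spec.delta_items):
            col = T + j
            diffs_mean = []
            diffs_var = []
            for t in range(1, T + 1):
                a, b = design.index(i, t), design.index(r, t)
                diffs_mean.append(ybar[a] - ybar[b])
                diffs_var.append(S[a, a] + S[b, b] - 2.0 * S[a, b])
            kappa[col] = float(np.mean(diffs_mean))
            Phi[col, col] = max(0.5 * float(np.mean(diffs_var)), 0.05)
    # ensure PD
    w, V = np.linalg.eigh(0.5 * (Phi + Phi.T))
    Phi = (V * np.maximum(w, 1e-3)) @ V.T
    theta = np.maximum(0.5 * np.diag(S), 1e-3)
    structure = structure_for_spec(spec)
    if spec.variant == "states_only":
        n_fi = design.n_items - 1
        free_items = [i for i in range(1, design.n_items + 1) if i != r]
        lam_vals = np.ones(n_fi)
        alpha_vals = np.array([
            float(np.mean([ybar[design.index(i, t)] - ybar[design.index(r, t)]
                           for t in range(1, T + 1)]))
            for i in free_items
        ])
    else:
        lam_vals = np.zeros(0)
        alpha_vals = np.zeros(0)
    return structure.x_from_components(kappa, Phi, lam_vals, alpha_vals, theta)


# ---- the fitting driver ----------------------------------------------


def _optimize(structure, x0, patterns, N, max_iter, gtol, ftol):
    # L-BFGS-B can declare an ftol stop on a plateau well before the
    # gradient criterion holds; restarting from the last iterate clears
    # its memory and reliably escapes, so iterate until the gradient is
    # small or restarts stop improving.
    def obj(x):
        f, g = structure.neg2ll_grad(x, patterns)
        return f / N, g / N

    x = np.asarray(x0, dtype=float)
    best = None
    f_prev = np.inf
    for _ in range(6):
        res = optimize.minimize(
            obj, x, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                     "ftol": ftol, "gtol": gtol / 10.0, "maxcor": 30},
        )
        f, g = obj(res.x)
        grad_norm = float(np.max(np.abs(g)))
        best = res
        x = res.x
        if grad_norm < gtol:
            break
        if np.isfinite(f_prev) and abs(f_prev - f) <= 1e-12 * max(1.0, abs(f)):
            break
        f_prev = f
    if grad_norm >= gtol:
        x, grad_norm = _polish_newton(structure, x, patterns, N, gtol)
        best.x = x
    return best, grad_norm


def _polish_newton(structure, x, patterns, N, gtol, max_steps=5):
    """Damped Newton steps in the natural parameterization to drive the
    gradient below tolerance when L-BFGS leaves a small residual."""
    v = structure.natural_from_x(x)
    f, g = structure.neg2ll_grad_natural(v, patterns)
    grad_norm = float(np.max(np.abs(g))) / N
    for _ in range(max_steps):
        if grad_norm < gtol:
            break
        H = structure.hessian_natural(v, patterns)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            break
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
            v_try = v - damp * step
            try:
                structure.x_from_natural(v_try)  # admissibility check
            except (np.linalg.LinAlgError, ValueError):
                continue
            f_try, g_try = structure.neg2ll_grad_natural(v_try, patterns)
            if np.isfinite(f_try) and f_try <= f + 1e-10 * max(1.0, abs(f)):
                v, f, g = v_try, f_try, g_try
                grad_norm = float(np.max(np.abs(g))) / N
                improved = True
                break
        if not improved:
            break
    try:
        return structure.x_from_natural(v), grad_norm
    except (np.linalg.LinAlgError, ValueError):
        return x, grad_norm


def fit(
    spec: LSTSpec,
    data,
    *,
    estimator: str = "ml",
    max_iter: int = 500,
    gtol: float = 1e-5,
    ftol: float = 1e-11,
    start: np.ndarray | None = None,
) -> FittedModel:
    """Fit a measurement model by ML, listwise ML, or FIML.

    Non-convergence is reported through ``converged=False`` plus the
    optimizer message, not as an exception; near-boundary residual
    variances are recorded as warnings.
    """
    if estimator not in ("ml", "fiml", "listwise"):
        raise ValueError("estimator must be 'ml', 'fiml' or 'listwise'")
    Y = panel_matrix(data, spec.design)
    sample: SampleMoments | None = None
    if estimator == "listwise":
        Y = listwise(Y)
        estimator_used = "ml"
    else:
        estimator_used = estimator
    if estimator_used == "ml":
        if np.isnan(Y).any():
            raise ValueError(
                "estimator='ml' requires complete data; use 'fiml' or "
                "'listwise'"
            )
        sample = sample_moments(Y)
        if sample.N < spec.design.p + 1:
            raise ValueError("need N >= p+1 respondents for complete-case ML")
        patterns = [Pattern(idx=np.arange(spec.design.p), n=sample.N,
                            ybar=sample.ybar, S=sample.S)]
        ybar_s, S_s = sample.ybar, sample.S
    else:
        patterns = pattern_moments(Y)
        ybar_s, S_s = _available_case_moments(Y)
    structure = structure_for_spec(spec)
    x0 = start if start is not None else start_values(spec, ybar_s, S_s)
    N = Y.shape[0]
    res, grad_norm = _optimize(structure, x0, patterns, N, max_iter,
                               gtol, ftol)
    x_hat = res.x
    loglik = -0.5 * structure.neg2ll(x_hat, patterns)
    converged = bool(res.success and grad_norm < gtol
                     and np.isfinite(loglik))
    warns = []
    c = structure.components(x_hat)
    if np.any(c["theta"] < 1e-4):
        warns.append("residual variance near the zero boundary")
    fitted = FittedModel(
        spec=spec,
        structure=structure,
        x_hat=x_hat,
        natural=structure.natural_from_x(x_hat),
        param_names=structure.param_names(),
        params=params_from_x(structure, spec, x_hat),
        loglik=float(loglik),
        n_free=structure.n_free,
        converged=converged,
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        message=str(res.message),
        N_used=N,
        estimator=estimator,
        sample=sample,
        patterns=patterns,
        warnings=warns,
    )
    assert fitted.n_free == count_free_parameters(spec)
    return fitted


def standard_errors(fitted: FittedModel) -> np.ndarray:
    """Observed-information covariance matrix of the free parameters.

    The Hessian of the negative log-likelihood is computed at the
    estimate in the natural parameterization; a (near-)singular
    information matrix raises, naming the flattest direction.
    """
    if fitted.vcov is not None:
        return fitted.vcov
    H = fitted.structure.hessian_natural(fitted.natural, fitted.patterns)
    info = 0.5 * H  # H is for -2 loglik
    w, V = np.linalg.eigh(info)
    if w.min() <= 1e-10 * max(w.max(), 1.0):
        worst = V[:, int(np.argmin(w))]
        name = fitted.param_names[int(np.argmax(np.abs(worst)))]
        raise ValueError(
            f"information matrix is singular; non-identified direction "
            f"loads mostly on {name}"
        )
    fitted.vcov = (V / w) @ V.T
    return fitted.vcov
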