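"""Latent-outcome regressions: incremental validity of item effects.

A manifest outcome composite Z (e.g. a psychological-distress or
mobility-problems index) is regressed on the latent variables of the
item-effects measurement model inside one simultaneous ML fit:

    Z = nu + sum_j gamma_j zeta_j + eps_Z,

where the predictor set is either the occasion states alone or the
states plus all item-effect variables.  The model-based R-squared is
gamma' Phi gamma / (gamma' Phi gamma + var(eps_Z)); standardized
coefficients are gamma_j * SD(zeta_j) / SD(Z) with the model-implied
outcome SD.  The full predictor set spans the same latent space under
every reference item, so its R-squared is reference-invariant; the
states-only R-squared is not, because the states themselves change
meaning with the reference item.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._structure import MomentStructure, Pattern, pattern_moments
from .estimation import (
    FittedModel,
    SampleMoments,
    _available_case_moments,
    _optimize,
    fit,
    listwise,
    sample_moments,
    structure_for_spec,
)
from .model_spec import LSTSpec

__all__ = [
    "StructuralSpec",
    "StructuralResult",
    "IncrementResult",
    "fit_structural",
    "compare_increment",
    "build_composite",
]

PREDICTOR_SETS = ("states_only", "states_plus_item_effects")


@dataclass(frozen=True)
class StructuralSpec:
    """Outcome-regression specification on top of an item-effects model."""

    base: LSTSpec
    outcome_label: str
    predictor_set: str

    def __post_init__(self) -> None:
        if self.base.variant != "item_effects":
            raise ValueError("structural models require an item_effects base")
        if self.predictor_set not in PREDICTOR_SETS:
            raise ValueError(f"predictor_set must be one of {PREDICTOR_SETS}")

    @property
    def predictors(self) -> tuple[str, ...]:
        T = self.base.design.n_occasions
        if self.predictor_set == "states_only":
            return self.base.latent_labels[:T]
        return self.base.latent_labels


@dataclass
class StructuralResult:
    """Standardized coefficients, R-squared and bookkeeping of one model."""

    spec: StructuralSpec
    fitted: FittedModel
    gamma: dict[str, float]
    betas_std: dict[str, float]
    nu: float
    resid_var: float
    r2: float
    sd_outcome: float
    loglik: float
    n_free: int
    converged: bool
    collinearity_flag: bool

    def to_frame(self, digits: int = 3) -> pd.DataFrame:
        rows = []
        ref = self.spec.base.reference_item
        for lab in self.spec.base.latent_labels:
            if lab in self.betas_std:
                rows.append((lab, round(self.betas_std[lab], digits)))
            elif lab.startswith("delta"):
                rows.append((lab, None))
        rows.append((f"delta{ref}", "ref"))
        frame = pd.DataFrame(rows, columns=["predictor", "beta_std"])
        frame.loc[len(frame)] = ("R2", round(self.r2, digits))
        return frame


@dataclass
class IncrementResult:
    """Incremental variance explained by the item-effect variables."""

    delta_r2: float
    lr_stat: float
    ddf: int
    p_value: float


def structure_for_structural(sspec: StructuralSpec) -> MomentStructure:
    base = sspec.base
    meas = structure_for_spec(base)
    p, m = meas.p, meas.m
    Lambda0 = np.vstack([meas.Lambda0, np.zeros((1, m))])
    col = {lab: k for k, lab in enumerate(base.latent_labels)}
    lam_cells = list(meas.lam_cells) + [
        (f"gamma[{lab}]", [(p, col[lab])]) for lab in sspec.predictors
    ]
    alpha_cells = list(meas.alpha_cells) + [("nu", [p])]
    return MomentStructure(
        obs_labels=meas.obs_labels + (sspec.outcome_label,),
        latent_labels=base.latent_labels,
        Lambda0=Lambda0,
        lam_cells=lam_cells,
        alpha0=np.concatenate([meas.alpha0, [0.0]]),
        alpha_cells=alpha_cells,
    )


def _structural_matrix(sspec: StructuralSpec, data) -> np.ndarray:
    base = sspec.base
    if not isinstance(data, pd.DataFrame):
        raise TypeError("structural fits require a DataFrame with the "
                        "outcome column")
    if sspec.outcome_label not in data.columns:
        raise ValueError(f"outcome column {sspec.outcome_label!r} not found")
    cols = list(base.design.observed_labels) + [sspec.outcome_label]
    Y = data.loc[:, cols].to_numpy(dtype=float)
    z = Y[:, -1]
    finite = z[~np.isnan(z)]
    if finite.size == 0 or np.var(finite) == 0.0:
        raise ValueError("outcome is constant or entirely missing")
    return Y


def fit_structural(
    sspec: StructuralSpec,
    data,
    *,
    estimator: str = "ml",
    max_iter: int = 500,
    gtol: float = 1e-5,
    ftol: float = 1e-11,
) -> StructuralResult:
    """Simultaneous ML fit of measurement model plus outcome regression."""
    base = sspec.base
    Y = _structural_matrix(sspec, data)
    if estimator == "listwise":
        Y = listwise(Y)
        estimator_used = "ml"
    else:
        estimator_used = estimator
    sample: SampleMoments | None = None
    if estimator_used == "ml":
        if np.isnan(Y).any():
            raise ValueError("estimator='ml' requires complete data; use "
                             "'fiml' or 'listwise'")
        sample = sample_moments(Y)
        patterns = [Pattern(idx=np.arange(Y.shape[1]), n=sample.N,
                            ybar=sample.ybar, S=sample.S)]
        ybar_s, S_s = sample.ybar, sample.S
    elif estimator_used == "fiml":
        patterns = pattern_moments(Y)
        ybar_s, S_s = _available_case_moments(Y)
    else:
        raise ValueError("estimator must be 'ml', 'fiml' or 'listwise'")

    structure = structure_for_structural(sspec)
    # Two-stage start: fit the measurement part first, then regress the
    # outcome on regression factor scores for the gamma start values.
    # Deterministic, and reliably inside the basin of the joint optimum.
    meas_est = "fiml" if np.isnan(Y[:, :-1]).any() else "ml"
    meas_fit = fit(base, Y[:, :-1], estimator=meas_est,
                   max_iter=max_iter, gtol=gtol, ftol=ftol)
    pv = meas_fit.params
    n_pred = len(sspec.predictors)
    gamma0 = np.zeros(n_pred)
    nu0 = float(ybar_s[-1])
    psi0 = max(float(S_s[-1, -1]), 1e-3)
    complete = Y[~np.isnan(Y).any(axis=1)]
    if complete.shape[0] >= 10 * (n_pred + 1):
        im = meas_fit.implied()
        Lam = structure_for_spec(base).Lambda0
        proj = pv.Phi @ Lam.T @ np.linalg.inv(im.Sigma)
        scores = pv.kappa + (complete[:, :-1] - im.mu) @ proj.T
        cols = [base.latent_labels.index(lab) for lab in sspec.predictors]
        X = np.column_stack([np.ones(complete.shape[0]),
                             scores[:, cols]])
        coef, *_ = np.linalg.lstsq(X, complete[:, -1], rcond=None)
        resid = complete[:, -1] - X @ coef
        nu0, gamma0 = float(coef[0]), coef[1:]
        psi0 = max(float(resid.var()), 0.05 * psi0)
    x0 = structure.x_from_components(
        pv.kappa, pv.Phi, gamma0, [nu0],
        np.concatenate([pv.theta, [psi0]]),
    )
    N = Y.shape[0]
    res, grad_norm = _optimize(structure, x0, patterns, N, max_iter,
                               gtol, ftol)
    loglik = -0.5 * structure.neg2ll(res.x, patterns)
    converged = bool(res.success and grad_norm < gtol
                     and np.isfinite(loglik))
    fitted = FittedModel(
        spec=sspec, structure=structure, x_hat=res.x,
        natural=structure.natural_from_x(res.x),
        param_names=structure.param_names(),
        params=None, loglik=float(loglik), n_free=structure.n_free,
        converged=converged, grad_norm=grad_norm, n_iter=int(res.nit),
        message=str(res.message), N_used=N, estimator=estimator,
        sample=sample, patterns=patterns,
    )
    c = structure.components(res.x)
    col = {lab: k for k, lab in enumerate(base.latent_labels)}
    gamma_full = np.zeros(base.m)
    gamma = {}
    for val, (name, _) in zip(c["lam"], structure.lam_cells):
        lab = name[name.index("[") + 1:-1]
        gamma[lab] = float(val)
        gamma_full[col[lab]] = float(val)
    Phi = c["Phi"]
    explained = float(gamma_full @ Phi @ gamma_full)
    resid_var = float(c["theta"][-1])
    var_z = explained + resid_var
    r2 = explained / var_z
    sd_z = float(np.sqrt(var_z))
    lat_sds = np.sqrt(np.diag(Phi))
    betas = {lab: gamma[lab] * lat_sds[col[lab]] / sd_z for lab in gamma}
    return StructuralResult(
        spec=sspec,
        fitted=fitted,
        gamma=gamma,
        betas_std=betas,
        nu=float(c["alpha"][-1]),
        resid_var=resid_var,
        r2=float(r2),
        sd_outcome=sd_z,
        loglik=float(loglik),
        n_free=structure.n_free,
        converged=converged,
        collinearity_flag=any(abs(b) > 1.0 for b in betas.values()),
    )


def compare_increment(
    res_reduced: StructuralResult, res_full: StructuralResult
) -> IncrementResult:
    """Delta R-squared (full minus reduced) plus the LR test between them."""
    if res_reduced.spec.outcome_label != res_full.spec.outcome_label:
        raise ValueError("results refer to different outcomes")
    if res_reduced.fitted.N_used != res_full.fitted.N_used:
        raise ValueError("results use different data")
    if not (res_reduced.spec.predictor_set == "states_only"
            and res_full.spec.predictor_set == "states_plus_item_effects"):
        raise ValueError("need a states_only model nested in a "
                         "states_plus_item_effects model")
    ddf = res_full.n_free - res_reduced.n_free
    stat = 2.0 * (res_full.loglik - res_reduced.loglik)
    p = float(stats.chi2.sf(max(stat, 0.0), ddf))
    return IncrementResult(
        delta_r2=float(res_full.r2 - res_reduced.r2),
        lr_stat=float(stat),
        ddf=int(ddf),
        p_value=p,
    )


def build_composite(
    data: pd.DataFrame, columns: list[str], label: str
) -> pd.Series:
    """Score a scale as the mean of the available item responses per row."""
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise ValueError(f"missing composite columns: {missing}")
    comp = data.loc[:, columns].mean(axis=1, skipna=True)
    comp.name = label
    return comp
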