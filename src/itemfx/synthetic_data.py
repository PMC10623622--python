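"""Synthetic panel generator with the statistical structure the models assume.

The generative model is the item-effects measurement model itself:
latent states and item effects are drawn from a multivariate normal
with the published latent moments of the SWLS in the LISS panel as the
default truth, residuals are independent normals, and observed
responses are composed as ``Y = alpha~ + Lambda zeta + eps``.  Outcome
composites are linear in the latents (optionally passed through a
monotone exponential transform to emulate the right skew of health
indices), and missingness removes whole waves per respondent (unit
nonresponse), never single items.

Responses are continuous by default — the analysis model is
linear-normal; ``discretize=True`` rounds and clips to the 1..7 scale
as a deliberate model-mismatch mode for robustness experiments.  All
randomness flows through one ``numpy.random.default_rng(seed)``
(PCG64), so a fixed seed reproduces tables bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_spec import (
    LSTSpec,
    ParameterVector,
    build_spec,
    intercept_vector,
    loading_matrix,
)

__all__ = [
    "OutcomeSpec",
    "SimConfig",
    "default_spec",
    "default_true_parameters",
    "mhi_outcome",
    "phi_outcome",
    "simulate_panel",
    "simulate_outcome",
    "inject_missingness",
]

# Default residual variances per item (constant over occasions in the
# generator, but freely estimated per item x occasion when fitting).
# Together with the latent truth below they put every observed item SD
# inside the 1.08-1.63 range reported for the SWLS items in the panel.
_DEFAULT_THETA_ITEM = (0.35, 0.35, 0.35, 0.35, 0.30)


@dataclass(frozen=True)
class OutcomeSpec:
    """A linear latent-outcome composite.

    gamma_std : standardized regression weights per latent label; raw
                weights are recovered as beta * sd / sd(latent).
    mean, sd  : target population mean and SD of the composite.
    skew      : monotone-transform strength; 0 keeps the composite
                normal, larger values produce stronger right skew while
                preserving the target mean and SD exactly in population.
    """

    label: str
    gamma_std: dict[str, float] = field(default_factory=dict)
    mean: float = 0.0
    sd: float = 1.0
    skew: float = 0.0


@dataclass
class SimConfig:
    spec: LSTSpec
    params: ParameterVector
    n: int
    outcomes: tuple[OutcomeSpec, ...] = ()
    wave_missing_rate: float = 0.0
    discretize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0.0 <= self.wave_missing_rate < 1.0:
            raise ValueError(
                "wave_missing_rate must be in [0, 1): every respondent "
                "must be able to keep at least one wave"
            )
        self.params.validate(self.spec)


def default_spec() -> LSTSpec:
    """5 SWLS items, 3 occasions, item-effects variant, reference item 3."""
    return build_spec("item_effects", reference_item=3)


def default_true_parameters() -> ParameterVector:
    """Admissible truth whose latent moments match the published SWLS
    estimates (reference item 3, first period) to the printed decimals."""
    from .published import SWLS_REF3_2008_2010 as src

    spec = default_spec()
    means = np.asarray(src["means"], dtype=float)
    sds = np.asarray(src["sds"], dtype=float)
    corr = np.asarray(src["corr"], dtype=float)
    Phi = corr * np.outer(sds, sds)
    Phi = 0.5 * (Phi + Phi.T)
    theta = np.tile(_DEFAULT_THETA_ITEM, spec.design.n_occasions)
    return ParameterVector(
        kappa=means,
        Phi=Phi,
        lam=np.ones(spec.design.n_items),
        alpha=np.zeros(spec.design.n_items),
        theta=theta,
    )


def mhi_outcome() -> OutcomeSpec:
    """Psychological-distress composite: mean 2.20, SD 0.82, right-skewed;
    standardized weights follow the published full-model magnitudes."""
    return OutcomeSpec(
        label="mhi",
        gamma_std={"eta1": -0.065, "eta2": -0.198, "eta3": -0.314,
                   "delta1": 0.022, "delta2": -0.083, "delta4": 0.084,
                   "delta5": -0.058},
        mean=2.20, sd=0.82, skew=0.5,
    )


def phi_outcome() -> OutcomeSpec:
    """Mobility-problems composite: mean 1.20, SD 0.34, right-skewed."""
    return OutcomeSpec(
        label="phi",
        gamma_std={"eta1": -0.120, "eta2": -0.100, "eta3": -0.101,
                   "delta1": 0.158, "delta2": -0.359, "delta4": 0.108,
                   "delta5": -0.062},
        mean=1.20, sd=0.34, skew=0.8,
    )


def _raw_gamma(
    ospec: OutcomeSpec, spec: LSTSpec, params: ParameterVector
) -> np.ndarray:
    col = {lab: k for k, lab in enumerate(spec.latent_labels)}
    lat_sds = np.sqrt(np.diag(params.Phi))
    gamma = np.zeros(spec.m)
    for lab, beta in ospec.gamma_std.items():
        if lab not in col:
            raise ValueError(f"unknown latent label {lab!r} in outcome spec")
        gamma[col[lab]] = beta * ospec.sd / lat_sds[col[lab]]
    return gamma


def simulate_outcome(
    latents: np.ndarray,
    ospec: OutcomeSpec,
    spec: LSTSpec,
    params: ParameterVector,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw the outcome composite for already-drawn latent scores."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    gamma = _raw_gamma(ospec, spec, params)
    explained = float(gamma @ params.Phi @ gamma)
    resid = ospec.sd ** 2 - explained
    if resid <= 0:
        raise ValueError(
            "standardized weights imply explained variance above the "
            "target outcome variance"
        )
    lin = latents @ gamma
    z = lin - float(gamma @ params.kappa) + rng.normal(
        0.0, np.sqrt(resid), size=latents.shape[0]
    )
    z_std = z / ospec.sd  # standard normal in population
    a = float(ospec.skew)
    if a > 0.0:
        # monotone convex transform with known normal moments, then
        # re-standardized so mean/SD targets hold exactly in population
        ez = np.exp(a * z_std)
        mean_t = np.exp(a * a / 2.0)
        sd_t = np.sqrt(np.exp(a * a) * (np.exp(a * a) - 1.0))
        z_std = (ez - mean_t) / sd_t
    return ospec.mean + ospec.sd * z_std


def inject_missingness(
    data: pd.DataFrame,
    spec_or_design,
    rate: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """MCAR unit nonresponse: blank whole waves at the given per-wave rate.

    Every respondent keeps at least one wave: a draw that would remove
    all waves retains one uniformly chosen wave instead.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1) so that at least one wave "
                         "can be kept")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    design = getattr(spec_or_design, "design", spec_or_design)
    out = data.copy()
    T = design.n_occasions
    n = len(out)
    drop = rng.random((n, T)) < rate
    all_dropped = drop.all(axis=1)
    keep_wave = rng.integers(0, T, size=n)
    drop[all_dropped, :] = True
    drop[np.arange(n)[all_dropped], keep_wave[all_dropped]] = False
    for t_idx, occ in enumerate(design.occasion_labels):
        cols = [f"{it}_w{occ}" for it in design.item_labels]
        mask = drop[:, t_idx]
        out.loc[mask, cols] = np.nan
    return out


def simulate_panel(
    config: SimConfig, *, return_latents: bool = False
):
    """Draw a wide-format panel dataset from the configured truth."""
    spec, params = config.spec, config.params
    rng = np.random.default_rng(config.seed)
    m, p = spec.m, spec.design.p
    L = np.linalg.cholesky(params.Phi)
    zeta = params.kappa + rng.standard_normal((config.n, m)) @ L.T
    eps = rng.standard_normal((config.n, p)) * np.sqrt(params.theta)
    Lam = loading_matrix(spec, params.lam)
    Y = intercept_vector(spec, params.alpha) + zeta @ Lam.T + eps
    if config.discretize:
        Y = np.clip(np.rint(Y), 1, 7)
    df = pd.DataFrame(Y, columns=list(spec.design.observed_labels))
    for ospec in config.outcomes:
        df[ospec.label] = simulate_outcome(zeta, ospec, spec, params, rng)
    if config.wave_missing_rate > 0.0:
        df = inject_missingness(df, spec, config.wave_missing_rate, rng)
    if return_latents:
        latents = pd.DataFrame(zeta, columns=list(spec.latent_labels))
        return df, latents
    return df
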