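"""Measurement-model specification for longitudinal multi-state models.

Two model variants for a scale with I items observed at T occasions:

``states_only``
    Each occasion t has a single latent state ``eta_t`` measured
    congenerically by all I items, with loadings and intercepts held
    constant over time (strong/scalar measurement invariance).  The
    reference item has its loading fixed to 1 and intercept fixed to 0.

``item_effects``
    All loadings are fixed to 1 and all intercepts to 0.  In addition to
    the occasion states ``eta_t`` (defined by the reference item's true
    score), every non-reference item i carries a time-constant latent
    difference variable ``delta_i`` — the person-specific item effect —
    so that ``Y_it = eta_t + delta_i + eps_it`` (``delta_r = 0``).

Observed variables are ordered item-major within occasion blocks:
``(item_1, t=1), ..., (item_I, t=1), (item_1, t=2), ...``.  All loading
and moment matrices in this package follow that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PanelDesign",
    "LSTSpec",
    "ParameterVector",
    "ImpliedMoments",
    "build_spec",
    "loading_matrix",
    "intercept_vector",
    "implied_moments",
    "count_free_parameters",
    "count_df",
]

VARIANTS = ("states_only", "item_effects")


@dataclass(frozen=True)
class PanelDesign:
    """Rectangular panel layout: I items measured at T occasions.

    At least three occasions are required: with T >= 3 the variance of a
    time-constant item effect is identified separately from occasion-
    specific residual variance.
    """

    n_items: int = 5
    n_occasions: int = 3
    item_labels: tuple[str, ...] = ()
    occasion_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise ValueError("need at least 2 items (I >= 2)")
        if self.n_occasions < 3:
            raise ValueError(
                "need at least 3 occasions (T >= 3): a time-constant item "
                "effect is not identified from fewer repeated measurements"
            )
        if not self.item_labels:
            object.__setattr__(
                self, "item_labels",
                tuple(f"item{i}" for i in range(1, self.n_items + 1)),
            )
        if not self.occasion_labels:
            object.__setattr__(
                self, "occasion_labels",
                tuple(str(t) for t in range(1, self.n_occasions + 1)),
            )
        if len(self.item_labels) != self.n_items:
            raise ValueError("item_labels length must equal n_items")
        if len(self.occasion_labels) != self.n_occasions:
            raise ValueError("occasion_labels length must equal n_occasions")

    @property
    def p(self) -> int:
        """Number of observed variables, I * T."""
        return self.n_items * self.n_occasions

    def index(self, item: int, occasion: int) -> int:
        """Row/column index of item i at occasion t (both 1-based)."""
        if not 1 <= item <= self.n_items:
            raise ValueError(f"item {item} out of range 1..{self.n_items}")
        if not 1 <= occasion <= self.n_occasions:
            raise ValueError(
                f"occasion {occasion} out of range 1..{self.n_occasions}"
            )
        return (occasion - 1) * self.n_items + (item - 1)

    @property
    def observed_labels(self) -> tuple[str, ...]:
        """Column labels ``<item>_w<occasion>`` in canonical order."""
        return tuple(
            f"{it}_w{occ}"
            for occ in self.occasion_labels
            for it in self.item_labels
        )


@dataclass(frozen=True)
class LSTSpec:
    """Declarative description of one measurement-model variant."""

    design: PanelDesign
    variant: str
    reference_item: int
    invariance: str = "strong"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 1 <= self.reference_item <= self.design.n_items:
            raise ValueError(
                f"reference_item {self.reference_item} out of range "
                f"1..{self.design.n_items}"
            )
        if self.invariance != "strong":
            raise ValueError("only strong (scalar) invariance is supported")

    @property
    def m(self) -> int:
        """Latent dimension: T states, plus I-1 item effects if modeled."""
        T = self.design.n_occasions
        if self.variant == "item_effects":
            return T + self.design.n_items - 1
        return T

    @property
    def delta_items(self) -> tuple[int, ...]:
        """1-based items carrying an item-effect variable (all but ref)."""
        if self.variant != "item_effects":
            return ()
        return tuple(
            i for i in range(1, self.design.n_items + 1)
            if i != self.reference_item
        )

    @property
    def latent_labels(self) -> tuple[str, ...]:
        states = tuple(
            f"eta{t}" for t in range(1, self.design.n_occasions + 1)
        )
        deltas = tuple(f"delta{i}" for i in self.delta_items)
        return states + deltas

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "reference_item": self.reference_item,
            "n_items": self.design.n_items,
            "n_occasions": self.design.n_occasions,
            "item_labels": list(self.design.item_labels),
            "occasion_labels": list(self.design.occasion_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSTSpec":
        design = PanelDesign(
            n_items=int(d["n_items"]),
            n_occasions=int(d["n_occasions"]),
            item_labels=tuple(d.get("item_labels", ())),
            occasion_labels=tuple(d.get("occasion_labels", ())),
        )
        return cls(
            design=design,
            variant=d["variant"],
            reference_item=int(d["reference_item"]),
        )


def build_spec(
    variant: str,
    reference_item: int = 3,
    design: PanelDesign | None = None,
    *,
    n_items: int = 5,
    n_occasions: int = 3,
) -> LSTSpec:
    """Construct an :class:`LSTSpec`, validating the identification rules."""
    if design is None:
        design = PanelDesign(n_items=n_items, n_occasions=n_occasions)
    return LSTSpec(design=design, variant=variant, reference_item=reference_item)


@dataclass
class ParameterVector:
    """All model parameters of an :class:`LSTSpec`, free and fixed.

    kappa : latent means, length m (states first, then item effects)
    Phi   : latent covariance matrix, m x m, symmetric positive definite
    lam   : per-item loadings, length I; the reference item's loading is
            fixed to 1; under ``item_effects`` all loadings are fixed to 1
    alpha : per-item intercepts, length I; fixed to 0 analogously
    theta : residual variances, length I*T (one per item x occasion)
    """

    kappa: np.ndarray
    Phi: np.ndarray
    lam: np.ndarray
    alpha: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.Phi = np.asarray(self.Phi, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)

    def validate(self, spec: LSTSpec) -> None:
        m, I, p = spec.m, spec.design.n_items, spec.design.p
        if self.kappa.shape != (m,):
            raise ValueError(f"kappa must have length {m}")
        if self.Phi.shape != (m, m):
            raise ValueError(f"Phi must be {m}x{m}")
        if not np.allclose(self.Phi, self.Phi.T):
            raise ValueError("Phi must be symmetric")
        if self.lam.shape != (I,) or self.alpha.shape != (I,):
            raise ValueError(f"lam and alpha must have length {I}")
        if self.theta.shape != (p,):
            raise ValueError(f"theta must have length {p}")
        if np.any(self.theta <= 0):
            raise ValueError("residual variances must be strictly positive")
        r = spec.reference_item - 1
        if self.lam[r] != 1.0 or self.alpha[r] != 0.0:
            raise ValueError("reference item must have loading 1, intercept 0")
        if spec.variant == "item_effects":
            if not (np.all(self.lam == 1.0) and np.all(self.alpha == 0.0)):
                raise ValueError(
                    "item_effects variant fixes all loadings to 1 and "
                    "intercepts to 0"
                )

    def copy(self) -> "ParameterVector":
        return ParameterVector(
            self.kappa.copy(), self.Phi.copy(), self.lam.copy(),
            self.alpha.copy(), self.theta.copy(),
        )


@dataclass
class ImpliedMoments:
    """Model-implied mean vector and covariance of the observed variables."""

    mu: np.ndarray
    Sigma: np.ndarray


def loading_matrix(spec: LSTSpec, lam: Sequence[float] | None = None) -> np.ndarray:
    """Loading matrix Lambda (p x m) in canonical variable order.

    Row (i, t) carries the item's loading in the column of ``eta_t`` and,
    under ``item_effects``, a 1 in the column of ``delta_i`` for i != r.
    ``lam`` supplies per-item loadings (default: all 1, which is the
    fixed pattern of the ``item_effects`` variant).
    """
    design = spec.design
    I, T, m = design.n_items, design.n_occasions, spec.m
    if lam is None:
        lam_arr = np.ones(I)
    else:
        lam_arr = np.asarray(lam, dtype=float)
        if lam_arr.shape != (I,):
            raise ValueError(f"lam must have length {I}")
    L = np.zeros((design.p, m))
    delta_col = {it: T + j for j, it in enumerate(spec.delta_items)}
    for t in range(1, T + 1):
        for i in range(1, I + 1):
            row = design.index(i, t)
            L[row, t - 1] = lam_arr[i - 1]
            if spec.variant == "item_effects" and i != spec.reference_item:
                L[row, delta_col[i]] = 1.0
    return L


def intercept_vector(spec: LSTSpec, alpha: Sequence[float] | None = None) -> np.ndarray:
    """Stacked intercepts (length p): item intercepts repeated per occasion."""
    I = spec.design.n_items
    if alpha is None:
        alpha_arr = np.zeros(I)
    else:
        alpha_arr = np.asarray(alpha, dtype=float)
        if alpha_arr.shape != (I,):
            raise ValueError(f"alpha must have length {I}")
    return np.tile(alpha_arr, spec.design.n_occasions)


def implied_moments(spec: LSTSpec, params: ParameterVector) -> ImpliedMoments:
    """mu = alpha~ + Lambda kappa;  Sigma = Lambda Phi Lambda' + diag(theta)."""
    params.validate(spec)
    w = np.linalg.eigvalsh(0.5 * (params.Phi + params.Phi.T))
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError("Phi is not positive semidefinite")
    Lam = loading_matrix(spec, params.lam)
    mu = intercept_vector(spec, params.alpha) + Lam @ params.kappa
    Sigma = Lam @ params.Phi @ Lam.T + np.diag(params.theta)
    Sigma = 0.5 * (Sigma + Sigma.T)
    return ImpliedMoments(mu=mu, Sigma=Sigma)


def count_free_parameters(spec: LSTSpec) -> int:
    """Number of free parameters q of the variant.

    states_only : (I-1) loadings + (I-1) intercepts + T state means
                  + T(T+1)/2 state (co)variances + I*T residual variances
    item_effects: m latent means + m(m+1)/2 latent (co)variances
                  + I*T residual variances   (loadings/intercepts all fixed)
    """
    I, T, p = spec.design.n_items, spec.design.n_occasions, spec.design.p
    if spec.variant == "states_only":
        return 2 * (I - 1) + T + T * (T + 1) // 2 + p
    m = spec.m
    return m + m * (m + 1) // 2 + p


def count_df(spec: LSTSpec) -> int:
    """Model test degrees of freedom: p(p+3)/2 observed moments minus q."""
    p = spec.design.p
    return p * (p + 3) // 2 - count_free_parameters(spec)
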