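"""Latent-variable summaries and the reference-item reparameterization.

Under the item-effects model the latent states are defined as the true
score of the reference item r, and each ``delta_i`` is the stable
person-specific difference between item i's true score and the
reference item's.  Choosing a different reference item s does not change
the model's fit — it is an exact linear change of latent coordinates:

    eta'_t  = eta_t + delta_s          (for every occasion t)
    delta'_i = delta_i - delta_s       (for i not in {r, s})
    delta'_r = -delta_s

This module extracts latent means, standard deviations, correlations
and Wald-test significance flags from a fitted model, and applies the
reference-switch map to any latent moment table — including tables
assembled from published estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FittedModel, standard_errors

__all__ = [
    "LatentMomentTable",
    "extract_latent_moments",
    "reference_switch",
    "switch_matrix",
    "wald_flags",
    "table_from_published",
]

Z_CRIT = float(stats.norm.ppf(0.975))


@dataclass
class LatentMomentTable:
    """Means, SDs and correlations of the latent variables.

    ``param_cov``, when present, is the covariance matrix of the
    vector (means, vech(cov)) with vech in row-major lower-triangle
    order; it travels through the reference switch so that significance
    flags stay available after reparameterization.
    """

    labels: tuple[str, ...]
    means: np.ndarray
    cov: np.ndarray
    reference_item: int
    n_occasions: int
    param_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        m = len(self.labels)
        if self.means.shape != (m,) or self.cov.shape != (m, m):
            raise ValueError("means/cov shapes must match labels")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        if np.any(np.diag(self.cov) <= 0):
            raise ValueError("latent variances must be positive")

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def corr(self) -> np.ndarray:
        sd = self.sds
        return self.cov / np.outer(sd, sd)

    @property
    def delta_items(self) -> tuple[int, ...]:
        return tuple(int(l.removeprefix("delta")) for l in self.labels
                     if l.startswith("delta"))

    def flags(self, alpha: float = 0.05):
        """(mean, sd, correlation) significance flags; needs param_cov."""
        if self.param_cov is None:
            raise ValueError("no parameter covariance attached")
        return _flags(self.means, self.cov, self.param_cov, alpha)

    def to_frame(self, digits: int = 3) -> pd.DataFrame:
        """Moment table in the conventional M / SD / correlations layout."""
        m = len(self.labels)
        corr = self.corr
        rows = {}
        rows["M"] = np.round(self.means, digits)
        rows["SD"] = np.round(self.sds, digits)
        frame = pd.DataFrame(rows, index=list(self.labels))
        for j, lab in enumerate(self.labels):
            col = [""] * m
            for i in range(m):
                if i < j:
                    col[i] = f"{corr[i, j]:.{digits}f}"
                elif i == j:
                    col[i] = "1"
            frame[lab] = col
        return frame


def _vech_positions(m: int) -> dict[tuple[int, int], int]:
    r, c = np.tril_indices(m)
    return {(int(i), int(j)): k for k, (i, j) in enumerate(zip(r, c))}


def _flags(means, cov, param_cov, alpha):
    m = means.size
    pos = _vech_positions(m)
    nmean = m
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    mean_se = np.sqrt(np.diag(param_cov)[:nmean])
    mean_flags = np.abs(means) / mean_se > z
    var_se = np.array([
        np.sqrt(param_cov[nmean + pos[(i, i)], nmean + pos[(i, i)]])
        for i in range(m)
    ])
    sd_flags = np.diag(cov) / var_se > z
    corr_flags = np.zeros((m, m), dtype=bool)
    corr = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
    for i in range(m):
        corr_flags[i, i] = True
        for j in range(i):
            idx = [nmean + pos[(i, j)], nmean + pos[(i, i)],
                   nmean + pos[(j, j)]]
            r = corr[i, j]
            grad = np.array([
                1.0 / np.sqrt(cov[i, i] * cov[j, j]),
                -r / (2.0 * cov[i, i]),
                -r / (2.0 * cov[j, j]),
            ])
            var_r = float(grad @ param_cov[np.ix_(idx, idx)] @ grad)
            if var_r <= 0:
                corr_flags[i, j] = corr_flags[j, i] = False
                continue
            # Fisher-z transformed Wald test
            if abs(r) >= 1.0:
                corr_flags[i, j] = corr_flags[j, i] = True
                continue
            se_z = np.sqrt(var_r) / (1.0 - r * r)
            stat = np.arctanh(r) / se_z if se_z > 0 else np.inf
            corr_flags[i, j] = corr_flags[j, i] = bool(abs(stat) > z)
    return mean_flags, sd_flags, corr_flags


def extract_latent_moments(
    fitted: FittedModel, *, compute_flags: bool = True
) -> LatentMomentTable:
    """Latent moment table of a converged item-effects fit."""
    spec = fitted.spec
    if getattr(spec, "variant", None) != "item_effects":
        raise ValueError("latent moment tables require an item_effects fit")
    m = spec.m
    nphi = m * (m + 1) // 2
    kappa = fitted.natural[:m]
    phiv = fitted.natural[m:m + nphi]
    cov = np.zeros((m, m))
    cov[np.tril_indices(m)] = phiv
    cov = cov + np.tril(cov, -1).T
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("estimated latent covariance is not positive "
                         "definite") from exc
    param_cov = None
    if compute_flags:
        vc = standard_errors(fitted)
        param_cov = vc[:m + nphi, :m + nphi]
    return LatentMomentTable(
        labels=spec.latent_labels,
        means=kappa,
        cov=cov,
        reference_item=spec.reference_item,
        n_occasions=spec.design.n_occasions,
        param_cov=param_cov,
    )


def switch_matrix(
    labels: tuple[str, ...],
    reference_item: int,
    new_reference: int,
    n_occasions: int,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Linear map A (and new labels) of the reference switch r -> s."""
    m = len(labels)
    col = {lab: k for k, lab in enumerate(labels)}
    s_lab = f"delta{new_reference}"
    if s_lab not in col:
        raise ValueError(
            f"item {new_reference} has no item-effect variable in this table"
        )
    old_deltas = [int(l.removeprefix("delta")) for l in labels
                  if l.startswith("delta")]
    new_deltas = sorted(set(old_deltas) - {new_reference} | {reference_item})
    new_labels = tuple(f"eta{t}" for t in range(1, n_occasions + 1)) + tuple(
        f"delta{i}" for i in new_deltas
    )
    A = np.zeros((m, m))
    sc = col[s_lab]
    for t in range(n_occasions):
        A[t, t] = 1.0
        A[t, sc] = 1.0
    for k, i in enumerate(new_deltas):
        row = n_occasions + k
        if i == reference_item:
            A[row, sc] = -1.0
        else:
            A[row, col[f"delta{i}"]] = 1.0
            A[row, sc] = -1.0
    return A, new_labels


def _vech_jacobian(A: np.ndarray) -> np.ndarray:
    """Jacobian of vech(A C A') with respect to vech(C)."""
    m = A.shape[0]
    pos = _vech_positions(m)
    n = len(pos)
    J = np.zeros((n, n))
    for (i, j), k in pos.items():
        E = np.zeros((m, m))
        E[i, j] = E[j, i] = 1.0
        out = A @ E @ A.T
        for (a, b), kk in pos.items():
            J[kk, k] = out[a, b]
    return J


def reference_switch(
    table: LatentMomentTable, new_reference: int
) -> LatentMomentTable:
    """Re-express a latent moment table under a different reference item."""
    if new_reference == table.reference_item:
        return replace(table)
    A, new_labels = switch_matrix(
        table.labels, table.reference_item, new_reference, table.n_occasions
    )
    means = A @ table.means
    cov = A @ table.cov @ A.T
    param_cov = None
    if table.param_cov is not None:
        m = len(table.labels)
        J = np.zeros_like(table.param_cov)
        J[:m, :m] = A
        J[m:, m:] = _vech_jacobian(A)
        param_cov = J @ table.param_cov @ J.T
    return LatentMomentTable(
        labels=new_labels,
        means=means,
        cov=0.5 * (cov + cov.T),
        reference_item=new_reference,
        n_occasions=table.n_occasions,
        param_cov=param_cov,
    )


def wald_flags(fitted: FittedModel, alpha: float = 0.05):
    """Significance flags for latent means, SDs and correlations.

    Means and variances use plain Wald z tests; correlations use the
    Fisher-z transform with a delta-method standard error.
    """
    table = extract_latent_moments(fitted, compute_flags=True)
    return table.flags(alpha)


def table_from_published(
    means,
    sds,
    corr,
    reference_item: int,
    n_occasions: int = 3,
    labels: tuple[str, ...] | None = None,
) -> LatentMomentTable:
    """Assemble a moment table from printed means, SDs and correlations."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    corr = np.asarray(corr, dtype=float)
    m = means.size
    if labels is None:
        n_deltas = m - n_occasions
        delta_items = [i for i in range(1, n_deltas + 2)
                       if i != reference_item][:n_deltas]
        labels = tuple(f"eta{t}" for t in range(1, n_occasions + 1)) + tuple(
            f"delta{i}" for i in delta_items
        )
    cov = corr * np.outer(sds, sds)
    return LatentMomentTable(
        labels=tuple(labels),
        means=means,
        cov=0.5 * (cov + cov.T),
        reference_item=reference_item,
        n_occasions=n_occasions,
    )
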