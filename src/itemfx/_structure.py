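"""Internal moment-structure engine.

A :class:`MomentStructure` describes a linear latent-variable moment
model for p observed variables and m latent variables,

    mu(x)    = alpha~ + Lambda kappa
    Sigma(x) = Lambda Phi Lambda' + diag(theta),

where ``Lambda`` has a fixed pattern plus optional free cells (possibly
tied across cells, e.g. time-invariant loadings), ``alpha~`` likewise,
``Phi`` is an unrestricted covariance matrix and ``theta`` holds one
residual variance per observed variable.  Both measurement variants and
the latent-outcome regression models are instances of this structure.

Likelihood evaluation works on "pattern moments": the data reduced to
per-missingness-pattern counts, means and covariance matrices.  Complete
data is the special case of a single all-variables pattern, so ordinary
ML and full-information ML (FIML) share one code path.  Analytic
gradients are provided in two coordinate systems:

* the unconstrained optimization vector ``x`` — latent covariance via a
  log-Cholesky factor and residual variances via logs, which keeps every
  iterate admissible; and
* the "natural" vector (kappa, vech(Phi), free loadings, free
  intercepts, theta), used for observed-information standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class Pattern:
    """Sufficient statistics of one missingness pattern.

    idx  : indices of the observed variables in the pattern
    n    : number of rows with this pattern
    ybar : sample mean of the observed subvector
    S    : sample covariance (divisor n) of the observed subvector
    """

    idx: np.ndarray
    n: int
    ybar: np.ndarray
    S: np.ndarray


def pattern_moments(Y: np.ndarray) -> list[Pattern]:
    """Group rows of ``Y`` (NaN = missing) into per-pattern moments."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("data must be 2-dimensional (rows = respondents)")
    obs = ~np.isnan(Y)
    if not obs.any(axis=1).all():
        raise ValueError("every row must have at least one observed entry")
    patterns: list[Pattern] = []
    # encode each row's pattern as bytes for grouping
    codes = np.packbits(obs, axis=1)
    _, inverse = np.unique(codes, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = Y[inverse == g]
        idx = np.flatnonzero(obs[inverse == g][0])
        sub = rows[:, idx]
        n = sub.shape[0]
        ybar = sub.mean(axis=0)
        dev = sub - ybar
        S = dev.T @ dev / n
        patterns.append(Pattern(idx=idx, n=n, ybar=ybar, S=S))
    return patterns


def _tril_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(m)


class MomentStructure:
    """Moment model with fixed/free loading and intercept cells."""

    def __init__(
        self,
        obs_labels: Sequence[str],
        latent_labels: Sequence[str],
        Lambda0: np.ndarray,
        lam_cells: Sequence[tuple[str, Sequence[tuple[int, int]]]] = (),
        alpha0: np.ndarray | None = None,
        alpha_cells: Sequence[tuple[str, Sequence[int]]] = (),
    ) -> None:
        self.obs_labels = tuple(obs_labels)
        self.latent_labels = tuple(latent_labels)
        self.p = len(self.obs_labels)
        self.m = len(self.latent_labels)
        self.Lambda0 = np.asarray(Lambda0, dtype=float).reshape(self.p, self.m)
        self.lam_cells = [(name, [tuple(c) for c in cells])
                          for name, cells in lam_cells]
        self.alpha0 = (np.zeros(self.p) if alpha0 is None
                       else np.asarray(alpha0, dtype=float))
        self.alpha_cells = [(name, list(rows)) for name, rows in alpha_cells]
        self.n_lam = len(self.lam_cells)
        self.n_alpha = len(self.alpha_cells)
        self._tril = _tril_indices(self.m)

    # ---- bookkeeping -------------------------------------------------

    @property
    def n_phi(self) -> int:
        return self.m * (self.m + 1) // 2

    @property
    def n_free(self) -> int:
        return self.m + self.n_phi + self.n_lam + self.n_alpha + self.p

    def param_names(self) -> list[str]:
        lab = self.latent_labels
        names = [f"kappa[{l}]" for l in lab]
        r, c = self._tril
        names += [f"phi[{lab[i]},{lab[j]}]" for i, j in zip(r, c)]
        names += [name for name, _ in self.lam_cells]
        names += [name for name, _ in self.alpha_cells]
        names += [f"theta[{l}]" for l in self.obs_labels]
        return names

    def _split(self, v: np.ndarray):
        m, nphi = self.m, self.n_phi
        k = 0
        kappa = v[k:k + m]; k += m
        phi_part = v[k:k + nphi]; k += nphi
        lam = v[k:k + self.n_lam]; k += self.n_lam
        alpha = v[k:k + self.n_alpha]; k += self.n_alpha
        theta = v[k:k + self.p]
        return kappa, phi_part, lam, alpha, theta

    # ---- coordinate transforms ---------------------------------------

    def x_from_components(
        self, kappa, Phi, lam_vals=(), alpha_vals=(), theta=None,
    ) -> np.ndarray:
        Phi = np.asarray(Phi, dtype=float).reshape(self.m, self.m)
        L = np.linalg.cholesky(Phi) if self.m else np.zeros((0, 0))
        Lv = L[self._tril].copy()
        diag_pos = self._diag_positions()
        Lv[diag_pos] = np.log(np.diag(L)) if self.m else Lv[diag_pos]
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0.0):
            raise ValueError("residual variances must be strictly positive")
        return np.concatenate([
            np.asarray(kappa, dtype=float).ravel(),
            Lv,
            np.asarray(lam_vals, dtype=float).ravel(),
            np.asarray(alpha_vals, dtype=float).ravel(),
            np.log(theta),
        ])

    def _diag_positions(self) -> np.ndarray:
        r, c = self._tril
        return np.flatnonzero(r == c)

    def components(self, x: np.ndarray) -> dict:
        kappa, Lv_packed, lam, alpha, ltheta = self._split(np.asarray(x, float))
        L = np.zeros((self.m, self.m))
        Lv = Lv_packed.copy()
        dp = self._diag_positions()
        # clip the log-scale entries so extreme line-search trial points
        # yield huge-but-finite moments instead of overflow
        Lv[dp] = np.exp(np.clip(Lv[dp], -150.0, 150.0))
        L[self._tril] = Lv
        Phi = L @ L.T
        theta = np.exp(np.clip(ltheta, -300.0, 300.0))
        Lam = self.Lambda0.copy()
        for val, (_, cells) in zip(lam, self.lam_cells):
            for (r, c) in cells:
                Lam[r, c] = val
        a = self.alpha0.copy()
        for val, (_, rows) in zip(alpha, self.alpha_cells):
            for r in rows:
                a[r] = val
        mu = a + Lam @ kappa
        Sigma = Lam @ Phi @ Lam.T + np.diag(theta)
        return {
            "kappa": kappa, "L": L, "Phi": Phi, "lam": lam, "alpha": alpha,
            "theta": theta, "Lambda": Lam, "alpha_full": a,
            "mu": mu, "Sigma": 0.5 * (Sigma + Sigma.T),
        }

    def natural_from_x(self, x: np.ndarray) -> np.ndarray:
        c = self.components(x)
        return np.concatenate([
            c["kappa"], c["Phi"][self._tril], c["lam"], c["alpha"], c["theta"],
        ])

    def x_from_natural(self, v: np.ndarray) -> np.ndarray:
        kappa, phiv, lam, alpha, theta = self._split(np.asarray(v, float))
        Phi = np.zeros((self.m, self.m))
        Phi[self._tril] = phiv
        Phi = Phi + np.tril(Phi, -1).T
        return self.x_from_components(kappa, Phi, lam, alpha, theta)

    # ---- likelihood core ---------------------------------------------

    def _accumulate(self, mu, Sigma, patterns):
        """-2 loglik and its derivative matrices w.r.t. (mu, Sigma)."""
        f = 0.0
        dmu = np.zeros(self.p)
        dSig = np.zeros((self.p, self.p))
        if not np.all(np.isfinite(Sigma)) or not np.all(np.isfinite(mu)):
            return np.inf, dmu, dSig
        for pat in patterns:
            o = pat.idx
            So = Sigma[np.ix_(o, o)]
            try:
                cf = linalg.cho_factor(So, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return np.inf, dmu, dSig
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            d = pat.ybar - mu[o]
            Stilde = pat.S + np.outer(d, d)
            A = linalg.cho_solve(cf, np.eye(len(o)), check_finite=False)
            f += pat.n * (len(o) * LOG_2PI + logdet
                          + float(np.sum(A * Stilde)))
            ASA = A @ Stilde @ A
            dSig[np.ix_(o, o)] += pat.n * (A - ASA)
            dmu[o] += -2.0 * pat.n * (A @ d)
        return f, dmu, dSig

    def neg2ll(self, x: np.ndarray, patterns: list[Pattern]) -> float:
        c = self.components(x)
        f, _, _ = self._accumulate(c["mu"], c["Sigma"], patterns)
        return f

    def _chain(self, c, dmu, dSig):
        """Chain (dmu, dSig) to gradients w.r.t. model matrices."""
        Lam, Phi, kappa = c["Lambda"], c["Phi"], c["kappa"]
        gkappa = Lam.T @ dmu
        M = Lam.T @ dSig @ Lam                      # dF/dPhi (full matrix)
        DLP = dSig @ Lam @ Phi
        glam = np.array([
            sum(2.0 * DLP[r, col] + dmu[r] * kappa[col] for (r, col) in cells)
            for _, cells in self.lam_cells
        ])
        galpha = np.array([
            sum(dmu[r] for r in rows) for _, rows in self.alpha_cells
        ])
        gtheta = np.diag(dSig).copy()
        return gkappa, M, glam, galpha, gtheta

    def neg2ll_grad(self, x, patterns):
        """(-2 loglik, gradient) in the unconstrained coordinates."""
        c = self.components(x)
        f, dmu, dSig = self._accumulate(c["mu"], c["Sigma"], patterns)
        if not np.isfinite(f):
            return f, np.zeros(self.n_free)
        gkappa, M, glam, galpha, gtheta = self._chain(c, dmu, dSig)
        GL = (M + M.T) @ c["L"]                     # dF/dL, Phi = L L'
        gL = GL[self._tril].copy()
        dp = self._diag_positions()
        gL[dp] *= np.diag(c["L"])                   # log-diagonal chain
        g = np.concatenate([gkappa, gL, glam, galpha, gtheta * c["theta"]])
        return f, g

    def neg2ll_grad_natural(self, v, patterns):
        """(-2 loglik, gradient) in natural coordinates (vech Phi, theta)."""
        kappa, phiv, lam, alpha, theta = self._split(np.asarray(v, float))
        Phi = np.zeros((self.m, self.m))
        Phi[self._tril] = phiv
        Phi = Phi + np.tril(Phi, -1).T
        Lam = self.Lambda0.copy()
        for val, (_, cells) in zip(lam, self.lam_cells):
            for (r, cc) in cells:
                Lam[r, cc] = val
        a = self.alpha0.copy()
        for val, (_, rows) in zip(alpha, self.alpha_cells):
            for r in rows:
                a[r] = val
        mu = a + Lam @ kappa
        Sigma = Lam @ Phi @ Lam.T + np.diag(theta)
        c = {"Lambda": Lam, "Phi": Phi, "kappa": kappa}
        f, dmu, dSig = self._accumulate(mu, 0.5 * (Sigma + Sigma.T), patterns)
        if not np.isfinite(f):
            return f, np.zeros(self.n_free)
        gkappa, M, glam, galpha, gtheta = self._chain(c, dmu, dSig)
        r, cix = self._tril
        gphi = np.where(r == cix, M[r, cix], 2.0 * M[r, cix])
        return f, np.concatenate([gkappa, gphi, glam, galpha, gtheta])

    def hessian_natural(self, v, patterns, rel_step=1e-5):
        """Hessian of -2 loglik at ``v`` by central differences of the
        analytic natural gradient; symmetrized."""
        v = np.asarray(v, dtype=float)
        q = v.size
        H = np.empty((q, q))
        for j in range(q):
            h = rel_step * max(1.0, abs(v[j]))
            vp = v.copy(); vp[j] += h
            vm = v.copy(); vm[j] -= h
            _, gp = self.neg2ll_grad_natural(vp, patterns)
            _, gm = self.neg2ll_grad_natural(vm, patterns)
            H[:, j] = (gp - gm) / (2.0 * h)
        return 0.5 * (H + H.T)


# ---- saturated / baseline helpers ------------------------------------


def saturated_neg2ll_complete(N: int, S: np.ndarray) -> float:
    """-2 loglik of the saturated model for complete data."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular")
    return N * (p * LOG_2PI + logdet + p)


def em_saturated(
    patterns: list[Pattern],
    p: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Saturated (unstructured) MVN fit to incomplete data via EM.

    Returns (mu, Sigma, -2 loglik).  Initialized from available-case
    moments; convergence on the relative -2 loglik change.
    """
    N = sum(pat.n for pat in patterns)
    # available-case start
    wsum = np.zeros(p)
    cnt = np.zeros(p)
    for pat in patterns:
        wsum[pat.idx] += pat.n * pat.ybar
        cnt[pat.idx] += pat.n
    if np.any(cnt == 0):
        raise ValueError("some variable is never observed")
    mu = wsum / cnt
    Sigma = np.eye(p)
    for pat in patterns:
        Sigma[np.ix_(pat.idx, pat.idx)] = np.maximum(
            Sigma[np.ix_(pat.idx, pat.idx)], 0)
    # seed variances from available cases
    var = np.ones(p)
    vcnt = np.zeros(p)
    vsum = np.zeros(p)
    for pat in patterns:
        d = pat.ybar - mu[pat.idx]
        vsum[pat.idx] += pat.n * (np.diag(pat.S) + d ** 2)
        vcnt[pat.idx] += pat.n
    var = np.maximum(vsum / vcnt, 1e-6)
    Sigma = np.diag(var)

    prev = np.inf
    f = np.inf
    for _ in range(max_iter):
        sum_y = np.zeros(p)
        sum_yy = np.zeros((p, p))
        f = 0.0
        for pat in patterns:
            o = pat.idx
            mset = np.setdiff1d(np.arange(p), o, assume_unique=True)
            Soo = Sigma[np.ix_(o, o)]
            cf = linalg.cho_factor(Soo, lower=True, check_finite=False)
            d = pat.ybar - mu[o]
            Stilde = pat.S + np.outer(d, d)
            A = linalg.cho_solve(cf, np.eye(len(o)), check_finite=False)
            f += pat.n * (len(o) * LOG_2PI
                          + 2.0 * np.log(np.diag(cf[0])).sum()
                          + float(np.sum(A * Stilde)))
            n = pat.n
            W = n * Stilde                      # sum of (y_o-mu_o)(y_o-mu_o)'
            sy_o = n * pat.ybar
            syy_oo = n * (pat.S + np.outer(pat.ybar, pat.ybar))
            sum_y[o] += sy_o
            sum_yy[np.ix_(o, o)] += syy_oo
            if mset.size:
                B = Sigma[np.ix_(mset, o)] @ A
                C = Sigma[np.ix_(mset, mset)] - B @ Sigma[np.ix_(o, mset)]
                mu_m = mu[mset]
                ym_hat_sum = n * mu_m + B @ (n * d)
                sum_y[mset] += ym_hat_sum
                cross = (np.outer(sy_o, mu_m)
                         + (syy_oo - np.outer(sy_o, mu[o])) @ B.T)
                sum_yy[np.ix_(o, mset)] += cross
                sum_yy[np.ix_(mset, o)] += cross.T
                mm = (n * np.outer(mu_m, mu_m)
                      + np.outer(mu_m, B @ (n * d))
                      + np.outer(B @ (n * d), mu_m)
                      + B @ W @ B.T + n * C)
                sum_yy[np.ix_(mset, mset)] += mm
        mu = sum_y / N
        Sigma = sum_yy / N - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        if np.isfinite(prev) and abs(prev - f) <= tol * max(1.0, abs(f)):
            break
        prev = f
    return mu, Sigma, f


def independence_structure(labels: Sequence[str]) -> MomentStructure:
    """Baseline (null) model: free means and variances, zero covariances."""
    p = len(labels)
    return MomentStructure(
        obs_labels=labels,
        latent_labels=(),
        Lambda0=np.zeros((p, 0)),
        alpha0=np.zeros(p),
        alpha_cells=[(f"mean[{l}]", [i]) for i, l in enumerate(labels)],
    )
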