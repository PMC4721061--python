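"""Bivariate polygenic decomposition of a phenotypic correlation.

Two continuous traits y_i, y_j measured on the same pedigree are modelled
jointly with genetic covariance rho_G*sqrt(s2_gi*s2_gj)*A and environmental
covariance rho_E*sqrt(s2_ei*s2_ej)*I.  In the eigenbasis of A the likelihood
factorises over eigencomponents with 2x2 covariances C_k = d_k*Sigma_G +
Sigma_E, so evaluation is O(n); fixed effects for both traits are profiled
out by joint GLS at each covariance evaluation.  Correlations are searched
through atanh transforms (variances through logs) to keep the optimiser in
the interior of the parameter space.

The fitted decomposition satisfies, by construction of its own fields,

    rho_P = rho_G * sqrt(h2_i h2_j) + rho_E * sqrt((1 - h2_i)(1 - h2_j)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .polygenic import EigenRelationship, decompose_relationship

__all__ = ["BivariateFit", "fit_bivariate", "correlation_test", "residual_phenotypic_corr"]


@dataclass
class BivariateFit:
    h2_i: float
    h2_j: float
    rho_g: float
    rho_e: float
    logL: float
    n: int
    converged: bool
    sigma2: tuple = ()  # (s2_gi, s2_ei, s2_gj, s2_ej)
    p_rho_g: float | None = None
    p_rho_e: float | None = None

    @property
    def rho_p(self) -> float:
        """Implied phenotypic correlation from the fit's own components."""
        return self.rho_g * np.sqrt(self.h2_i * self.h2_j) + self.rho_e * np.sqrt(
            (1.0 - self.h2_i) * (1.0 - self.h2_j)
        )


def _unpack(theta, fix_g=None, fix_e=None):
    s2 = np.exp(theta[:4])  # s2_gi, s2_ei, s2_gj, s2_ej
    k = 4
    if fix_g is None:
        rg = np.tanh(theta[k]); k += 1
    else:
        rg = fix_g
    re_ = np.tanh(theta[k]) if fix_e is None else fix_e
    return s2, rg, re_


def _neg_loglik(theta, yt, Xt, d, fix_g=None, fix_e=None):
    (s2gi, s2ei, s2gj, s2ej), rg, re_ = _unpack(theta, fix_g, fix_e)
    cg = rg * np.sqrt(s2gi * s2gj)
    ce = re_ * np.sqrt(s2ei * s2ej)
    n, p = Xt.shape
    # per-component 2x2 covariances
    c11 = d * s2gi + s2ei
    c22 = d * s2gj + s2ej
    c12 = d * cg + ce
    det = c11 * c22 - c12 * c12
    if np.any(det <= 1e-300) or np.any(c11 <= 0) or np.any(c22 <= 0):
        return 1e10
    i11, i22, i12 = c22 / det, c11 / det, -c12 / det
    # joint GLS for (b_i, b_j)
    M = np.empty((2 * p, 2 * p))
    M[:p, :p] = Xt.T @ (Xt * i11[:, None])
    M[p:, p:] = Xt.T @ (Xt * i22[:, None])
    M[:p, p:] = Xt.T @ (Xt * i12[:, None])
    M[p:, :p] = M[:p, p:].T
    r1 = Xt.T @ (yt[:, 0] * i11 + yt[:, 1] * i12)
    r2 = Xt.T @ (yt[:, 1] * i22 + yt[:, 0] * i12)
    try:
        b = np.linalg.solve(M, np.concatenate([r1, r2]))
    except np.linalg.LinAlgError:
        return 1e10
    e1 = yt[:, 0] - Xt @ b[:p]
    e2 = yt[:, 1] - Xt @ b[p:]
    quad = np.sum(e1 * e1 * i11 + e2 * e2 * i22 + 2.0 * e1 * e2 * i12)
    return 0.5 * (np.sum(np.log(det)) + quad) + n * np.log(2.0 * np.pi)


def _fit(yt, Xt, d, fix_g=None, fix_e=None):
    v1, v2 = np.var(yt[:, 0]), np.var(yt[:, 1])
    starts = []
    for h in (0.2, 0.5, 0.8):
        th = [np.log(h * v1), np.log((1 - h) * v1), np.log(h * v2), np.log((1 - h) * v2)]
        if fix_g is None:
            th.append(0.0)
        if fix_e is None:
            th.append(0.0)
        starts.append(np.array(th))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_loglik, x0, args=(yt, Xt, d, fix_g, fix_e),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_bivariate(y_i, y_j, X, A, families=None) -> BivariateFit:
    """ML fit of the bivariate polygenic model; returns the decomposition.

    ``X`` (including an intercept) is shared by both traits.  Non-PSD trial
    covariances encountered during the search are rejected by penalising the
    objective, which reprojects the optimiser into the feasible region.
    """
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(A, families)
    yt = np.column_stack([eig.rotate(np.asarray(y_i, float)),
                          eig.rotate(np.asarray(y_j, float))])
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    Xt = eig.rotate(Xv)
    res = _fit(yt, Xt, eig.d)
    (s2gi, s2ei, s2gj, s2ej), rg, re_ = _unpack(res.x)
    return BivariateFit(
        h2_i=float(s2gi / (s2gi + s2ei)),
        h2_j=float(s2gj / (s2gj + s2ej)),
        rho_g=float(rg),
        rho_e=float(re_),
        logL=float(-res.fun),
        n=yt.shape[0],
        converged=bool(res.success or res.fun < 1e9),
        sigma2=(float(s2gi), float(s2ei), float(s2gj), float(s2ej)),
    )


def correlation_test(fit: BivariateFit, y_i, y_j, X, A, which: str,
                     families=None) -> float:
    """LRT p-value against the model with rho_G or rho_E constrained to 0."""
    if which not in ("genetic", "environmental"):
        raise ValueError("which must be 'genetic' or 'environmental'")
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(A, families)
    yt = np.column_stack([eig.rotate(np.asarray(y_i, float)),
                          eig.rotate(np.asarray(y_j, float))])
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    Xt = eig.rotate(Xv)
    res0 = _fit(yt, Xt, eig.d,
                fix_g=0.0 if which == "genetic" else None,
                fix_e=0.0 if which == "environmental" else None)
    lam = 2.0 * (fit.logL - (-res0.fun))
    if lam < -1e-4:
        raise FloatingPointError(
            f"constrained fit beat the unconstrained one (LRT = {lam:.3g})"
        )
    return float(stats.chi2.sf(max(lam, 0.0), 1))


def residual_phenotypic_corr(y_i, y_j, X) -> tuple[float, float]:
    """Raw phenotypic correlation after covariate adjustment.

    Pearson correlation of the OLS residuals of each trait on X, with its
    p-value; this is the model-free companion to the decomposition's
    implied rho_P.
    """
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    H = Xv @ np.linalg.pinv(Xv)
    r1 = np.asarray(y_i, float) - H @ np.asarray(y_i, float)
    r2 = np.asarray(y_j, float) - H @ np.asarray(y_j, float)
    r, p = stats.pearsonr(r1, r2)
    return float(r), float(p)
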