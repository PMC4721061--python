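"""Univariate polygenic variance-component model on pedigree data.

The model for a continuous trait is

    y ~ MVN(X b,  sigma2_g * A + sigma2_e * I)

with A the additive relationship matrix.  The likelihood is maximised by
eigendecomposing A once (blockwise by family when family labels are given),
rotating y and X into the eigenbasis where the covariance is diagonal,
profiling out b (GLS) and the total variance in closed form, and optimising
the one remaining parameter h2 = sigma2_g / (sigma2_g + sigma2_e) on [0, 1].

Binary traits are handled under the liability-threshold model: the 0/1
indicator is fitted with the same mixed model on the observed scale, and
estimates are mapped to the latent liability scale with the classical
threshold-model factors (see ``_liability_factors``).  Likelihood-ratio tests
are carried out on the observed scale, where they are valid regardless of the
trait distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EigenRelationship",
    "VCFit",
    "decompose_relationship",
    "fit_polygenic",
    "heritability_test",
    "fixed_effect_test",
]

_H2_GRID = np.linspace(0.0, 1.0, 21)
_LOGL_TOL = 1e-8


@dataclass
class EigenRelationship:
    """Eigendecomposition A = U diag(d) U', reused across fits and scans."""

    U: np.ndarray
    d: np.ndarray

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M


def decompose_relationship(A, families=None) -> EigenRelationship:
    """Eigendecompose the relationship matrix.

    When per-sample family labels are given the decomposition is done block
    by block (A is block-diagonal by family), which is both faster and exact
    about cross-family zeros.
    """
    Av = np.asarray(A, dtype=float)
    n = Av.shape[0]
    if families is None:
        d, U = np.linalg.eigh(Av)
        return EigenRelationship(U, np.clip(d, 0.0, None))
    fam = np.asarray(families)
    U = np.zeros((n, n))
    d = np.zeros(n)
    for f in pd.unique(fam):
        idx = np.flatnonzero(fam == f)
        db, Ub = np.linalg.eigh(Av[np.ix_(idx, idx)])
        U[np.ix_(idx, idx)] = Ub
        d[idx] = db
    return EigenRelationship(U, np.clip(d, 0.0, None))


@dataclass
class VCFit:
    """Maximum-likelihood polygenic fit.

    For ``kind="liability"`` the variance components are on the observed 0/1
    scale while ``h2``, ``beta`` and ``se`` are mapped to the latent liability
    scale; ``h2_observed`` and ``prevalence`` retain the raw quantities.
    """

    sigma2_g: float
    sigma2_e: float
    h2: float
    beta: pd.Series
    se: pd.Series
    logL: float
    n: int
    converged: bool
    kind: str = "continuous"
    h2_observed: float | None = None
    prevalence: float | None = None
    message: str = ""


def _check_design(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j] if names is not None else j)
        raise np.linalg.LinAlgError(
            f"covariate matrix is rank-deficient; collinear columns: {bad}"
        )


def _profile(h2: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Profile log-likelihood at h2, with GLS b and ML total variance.

    Returns (logL, beta, cov_beta, sigma2_total).
    """
    n = yt.shape[0]
    w = h2 * d + (1.0 - h2)
    w = np.maximum(w, 1e-12)
    sw = 1.0 / np.sqrt(w)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logL = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + np.sum(np.log(w)) + n)
    cov = sigma2 * np.linalg.inv(XtX)
    return logL, beta, cov, sigma2


def _maximise_h2(yt, Xt, d):
    """Grid search plus bounded refinement of the 1-D profile likelihood."""
    grid_ll = np.array([_profile(h, yt, Xt, d)[0] for h in _H2_GRID])
    k = int(np.argmax(grid_ll))
    lo = _H2_GRID[max(k - 1, 0)]
    hi = _H2_GRID[min(k + 1, len(_H2_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda h: -_profile(h, yt, Xt, d)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    h2 = float(res.x)
    # keep the better of the refined point and the grid point
    if -res.fun < grid_ll[k]:
        h2 = float(_H2_GRID[k])
    flat = float(grid_ll.max() - grid_ll.min()) < _LOGL_TOL
    return h2, flat


def _liability_factors(prevalence: float):
    """Threshold t and the observed->liability conversion constants.

    For a binary trait with prevalence K generated by thresholding a standard
    normal liability at t = Phi^-1(1 - K), a small liability-scale effect
    b_liab moves the observed-scale mean by phi(t) * b_liab, and the
    observed-scale heritability relates to the liability-scale one by
    h2_obs = h2_liab * phi(t)^2 / (K (1 - K)).
    """
    t = stats.norm.ppf(1.0 - prevalence)
    z = stats.norm.pdf(t)
    return t, z, prevalence * (1.0 - prevalence) / (z * z)


def fit_polygenic(y, X, A, kind: str = "continuous", families=None,
                  prevalence: float | None = None) -> VCFit:
    """ML fit of the polygenic model y ~ MVN(Xb, sigma2_g A + sigma2_e I).

    ``A`` may be a matrix (optionally with ``families`` labels for blockwise
    eigendecomposition) or a precomputed :class:`EigenRelationship`.
    ``kind="liability"`` expects y in {0, 1} with both classes present and
    reports h2 and coefficients on the liability scale.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    n = y.shape[0]
    if kind == "liability":
        classes = np.unique(y)
        if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
            raise ValueError("liability trait must be 0/1 with both classes present")
    elif kind != "continuous":
        raise ValueError(f"unknown trait kind {kind!r}")
    _check_design(Xv, names)
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(A, families)
    yt = eig.rotate(y)
    Xt = eig.rotate(Xv)
    h2, flat = _maximise_h2(yt, Xt, d=eig.d)
    logL, beta, cov, sigma2 = _profile(h2, yt, Xt, eig.d)
    se = np.sqrt(np.diag(cov))
    converged = np.isfinite(logL) and not flat and (n - Xv.shape[1]) >= 2
    msg = "" if converged else "variance components not identifiable (flat likelihood or too few residual degrees of freedom)"
    idx = names if names is not None else [f"x{j}" for j in range(Xv.shape[1])]
    fit = VCFit(
        sigma2_g=h2 * sigma2,
        sigma2_e=(1.0 - h2) * sigma2,
        h2=h2,
        beta=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        logL=float(logL),
        n=n,
        converged=bool(converged),
        kind=kind,
        message=msg,
    )
    if kind == "liability":
        K = float(np.mean(y)) if prevalence is None else float(prevalence)
        _, z, h2_factor = _liability_factors(K)
        fit.h2_observed = h2
        fit.prevalence = K
        fit.h2 = float(np.clip(h2 * h2_factor, 0.0, 1.0))
        fit.beta = fit.beta / z
        fit.se = fit.se / z
    return fit


def _refit_at(h2_fixed, y, X, eig) -> tuple[float, np.ndarray]:
    yt = eig.rotate(np.asarray(y, dtype=float))
    Xt = eig.rotate(np.asarray(X, dtype=float))
    logL, beta, _, _ = _profile(h2_fixed, yt, Xt, eig.d)
    return float(logL), beta


def heritability_test(fit: VCFit, y, X, A, families=None) -> float:
    """LRT p-value for H0: h2 = 0 against the fitted polygenic model.

    The statistic 2*(logL_full - logL_null) is referred to the boundary
    mixture 0.5*chi2_0 + 0.5*chi2_1 (so p = 0.5 at a zero statistic).
    """
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(A, families)
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    logL0, _ = _refit_at(0.0, y, Xv, eig)
    lam = 2.0 * (fit.logL - logL0)
    if lam < -1e-6:
        raise FloatingPointError(
            f"constrained log-likelihood exceeds unconstrained (LRT = {lam:.3g}); optimiser failure"
        )
    lam = max(lam, 0.0)
    return float(0.5 * stats.chi2.sf(lam, 1)) if lam > 0 else 0.5


def fixed_effect_test(y, X, A, focal, kind: str = "continuous", families=None,
                      prevalence: float | None = None):
    """LRT for a single fixed effect within the polygenic model.

    Both the full and the reduced model re-estimate the variance components.
    Returns ``(b, se, p)`` with the coefficient and its SE taken from the
    unconstrained fit (liability scale when ``kind="liability"``).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        j = names.index(focal) if not isinstance(focal, int) else focal
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        j = int(focal)
        names = None
    col = Xv[:, j]
    if np.all(col == 0.0):
        return 0.0, np.nan, 1.0
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(A, families)
    Xfull = pd.DataFrame(Xv, columns=names) if names is not None else Xv
    full = fit_polygenic(y, Xfull, eig, kind=kind, prevalence=prevalence)
    keep = [k for k in range(Xv.shape[1]) if k != j]
    Xnull = Xv[:, keep]
    ynull = np.asarray(y, dtype=float)
    yt = eig.rotate(ynull)
    Xt = eig.rotate(Xnull)
    h2_null, _ = _maximise_h2(yt, Xt, eig.d)
    logL0, _, _, _ = _profile(h2_null, yt, Xt, eig.d)
    lam = 2.0 * (full.logL - logL0)
    if lam < -1e-6:
        raise FloatingPointError(
            f"constrained log-likelihood exceeds unconstrained (LRT = {lam:.3g})"
        )
    lam = max(lam, 0.0)
    p = float(stats.chi2.sf(lam, 1))
    b = float(full.beta.iloc[j])
    se = float(full.se.iloc[j])
    return b, se, p
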