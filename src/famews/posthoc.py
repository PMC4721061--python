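"""Follow-up analyses for significant sites: mediation and model information.

Sobel mediation quantifies how much of a methylation site's association with
an outcome (e.g. type 2 diabetes) passes through an intermediate phenotype
(e.g. HTGW) as the product of the site->mediator and mediator->outcome
coefficients, with the delta-method standard error
sqrt(a^2 s_b^2 + b^2 s_a^2).  Model information is compared with the
likelihood-based Kullback-Leibler R^2 = 1 - exp(-2 (logL_full - logL_null)/n),
which reduces to the classical OLS R^2 for Gaussian linear models, applied in
a forward-stepwise ladder over sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .polygenic import (
    EigenRelationship,
    _maximise_h2,
    _profile,
    decompose_relationship,
    fit_polygenic,
)

__all__ = ["MediationResult", "ModelComparison", "sobel_mediation", "kl_r2", "stepwise_kl"]


@dataclass
class MediationResult:
    a: float        # site -> mediator coefficient
    se_a: float
    b: float        # mediator -> outcome coefficient, site-adjusted
    se_b: float
    product: float  # a * b, the mediation parameter
    se: float       # Sobel delta-method SE
    z: float
    p: float


@dataclass
class ModelComparison:
    """Forward-stepwise ladder of nested models with K-L R^2 per step."""

    labels: list
    r2: list
    delta_r2: list
    p_step: list
    n: int
    failures: dict


def sobel_z(a: float, se_a: float, b: float, se_b: float):
    """Sobel product, delta-method SE, z and two-sided normal p."""
    product = a * b
    se = float(np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a))
    if se == 0.0:
        z = 0.0
    else:
        z = product / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return product, se, z, p


def sobel_mediation(site, mediator, outcome, X, A, mediator_kind="liability",
                    outcome_kind="liability", families=None) -> MediationResult:
    """Mediation of a methylation site's effect on the outcome via the mediator.

    Two polygenic models are fitted: mediator ~ site + X (path a) and
    outcome ~ mediator + site + X (path b); the mediation parameter is a*b
    with the Sobel standard error.  Failure of either component model raises
    with the failing path named.
    """
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(A, families)
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    s = np.asarray(site, dtype=float)
    m = np.asarray(mediator, dtype=float)
    o = np.asarray(outcome, dtype=float)
    try:
        X1 = np.column_stack([s, Xv])
        fit1 = fit_polygenic(m, X1, eig, kind=mediator_kind)
    except Exception as exc:
        raise RuntimeError(f"mediation path a (site -> mediator) failed: {exc}") from exc
    try:
        X2 = np.column_stack([m, s, Xv])
        fit2 = fit_polygenic(o, X2, eig, kind=outcome_kind)
    except Exception as exc:
        raise RuntimeError(f"mediation path b (mediator -> outcome) failed: {exc}") from exc
    a, se_a = float(fit1.beta.iloc[0]), float(fit1.se.iloc[0])
    b, se_b = float(fit2.beta.iloc[0]), float(fit2.se.iloc[0])
    product, se, z, p = sobel_z(a, se_a, b, se_b)
    return MediationResult(a, se_a, b, se_b, product, se, z, p)


def kl_r2(fit_full, fit_null, n: int) -> float:
    """Kullback-Leibler R^2 = 1 - exp(-2 (logL_full - logL_null) / n).

    Arguments may be fitted models exposing ``.logL`` (or statsmodels
    ``.llf``) or plain log-likelihood values.  For a Gaussian linear model
    against its intercept-only null this equals the classical OLS R^2; more
    generally it measures the information gained by the full model over the
    nested null.
    """
    def _ll(obj):
        for attr in ("logL", "llf"):
            if hasattr(obj, attr):
                return float(getattr(obj, attr))
        return float(obj)

    diff = _ll(fit_full) - _ll(fit_null)
    if diff < -1e-6:
        raise FloatingPointError(
            f"full model log-likelihood below the null's ({diff:.3g})"
        )
    return float(1.0 - np.exp(-2.0 * max(diff, 0.0) / n))


def ladder_deltas(r2_values) -> tuple[list, float]:
    """Step improvements of an R^2 ladder and the total gain over the base."""
    r2 = [float(v) for v in r2_values]
    deltas = [r2[k + 1] - r2[k] for k in range(len(r2) - 1)]
    return deltas, r2[-1] - r2[0]


def stepwise_kl(sites: pd.DataFrame, trait, X, A, kind="continuous",
                families=None) -> ModelComparison:
    """Forward-stepwise ladder: base, base+site1, base+site1+site2, ...

    Each model's K-L R^2 is taken against the intercept-only polygenic null
    on the same samples; step p-values are chi2(1) LRTs between consecutive
    models.  A site collinear with the current design adds no information
    (delta R^2 = 0, p = 1, recorded in ``failures``); a failing fit truncates
    the ladder with the failure annotated.
    """
    if sites.shape[1] < 1:
        raise ValueError("stepwise_kl needs at least one site")
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(A, families)
    y = np.asarray(trait, dtype=float)
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    n = y.shape[0]
    yt = eig.rotate(y)

    def loglik(Mat):
        Mt = eig.rotate(Mat)
        h2, _ = _maximise_h2(yt, Mt, eig.d)
        return _profile(h2, yt, Mt, eig.d)[0]

    logL_null = loglik(np.ones((n, 1)))
    labels, r2s, deltas, ps = ["base"], [], [], []
    failures: dict = {}
    cur = Xv
    cur_logL = loglik(cur)
    r2s.append(kl_r2(cur_logL, logL_null, n))
    for name in sites.columns:
        col = sites[name].to_numpy(dtype=float)
        cand = np.column_stack([cur, col])
        labels.append(f"{labels[-1]} + {name}")
        if np.linalg.matrix_rank(cand) <= np.linalg.matrix_rank(cur):
            failures[name] = "collinear with current design; no information added"
            r2s.append(r2s[-1])
            deltas.append(0.0)
            ps.append(1.0)
            continue
        try:
            new_logL = loglik(cand)
        except Exception as exc:  # pragma: no cover - defensive
            failures[name] = f"fit failed: {exc}"
            labels.pop()
            break
        lam = max(2.0 * (new_logL - cur_logL), 0.0)
        r2s.append(kl_r2(new_logL, logL_null, n))
        deltas.append(r2s[-1] - r2s[-2])
        ps.append(float(stats.chi2.sf(lam, 1)))
        cur, cur_logL = cand, new_logL
    return ModelComparison(labels, r2s, deltas, [None] + ps, n, failures)
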