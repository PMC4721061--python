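"""Cross-platform agreement statistics for paired methylation measurements.

Used to compare two ways of measuring the same quantity on the same samples
(e.g. array beta values against pyrosequencing): Spearman rank correlation
for monotone concordance, Bland-Altman limits of agreement for the size and
spread of the systematic difference, and Pitman's test of whether the two
methods have unequal variances (correlation of the paired differences with
the paired sums).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementResult", "bland_altman", "pitman_test", "spearman_corr"]


@dataclass
class AgreementResult:
    mean_diff: float            # mean of (method2 - method1)
    sd_diff: float
    limits: tuple               # mean_diff -/+ 1.96 * sd_diff
    n: int
    n_outside: int
    means: np.ndarray           # per-pair (x + y)/2, for plotting
    diffs: np.ndarray           # per-pair (y - x)


def _paired(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return x, y


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement of method 2 (y) against method 1 (x).

    Differences are oriented y - x; limits of agreement are the mean
    difference -/+ 1.96 standard deviations of the differences.
    """
    x, y = _paired(x, y, 3)
    d = y - x
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    lo, hi = mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d
    outside = int(((d < lo) | (d > hi)).sum())
    return AgreementResult(mean_d, sd_d, (lo, hi), x.size, outside, (x + y) / 2.0, d)


def pitman_test(x, y) -> float:
    """Pitman-Morgan test of unequal variances for paired samples.

    Var(x) = Var(y) iff corr(y - x, y + x) = 0; the correlation is referred
    to a t distribution on n - 2 degrees of freedom, two-sided.
    """
    x, y = _paired(x, y, 4)
    d, s = y - x, y + x
    if d.std() == 0.0 or s.std() == 0.0:
        raise ValueError("degenerate input: differences or sums have zero variance")
    r = float(np.corrcoef(d, s)[0, 1])
    n = x.size
    t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) with t-approximation p."""
    x, y = _paired(x, y, 3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
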