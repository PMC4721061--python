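"""Marker-level association engine for family-based EWAS/GWAS.

Covers construction of the hypertriglyceridemic-waist (HTGW) phenotype,
rank-based inverse-normal transformation, probe/SNP quality-control filters,
per-marker polygenic association with likelihood-ratio tests, genomic-control
inflation, Benjamini–Hochberg FDR, the liability-coefficient-to-odds-ratio
transformation, and ancestry principal components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .polygenic import (
    EigenRelationship,
    _liability_factors,
    _maximise_h2,
    _profile,
    decompose_relationship,
)

__all__ = [
    "MethylationMatrix",
    "ScanResult",
    "make_htgw",
    "component_indicators",
    "inverse_normal",
    "filter_probes",
    "filter_snps",
    "hwe_exact",
    "association_scan",
    "genomic_inflation",
    "correct_inflation",
    "bh_fdr",
    "liability_or",
    "median_beta_difference",
    "ancestry_pcs",
]

log = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

# sex-specific HTGW cut-offs: waist circumference (cm) and triglycerides
# (mmol/L), inclusive; {sex code: (wc_cut, tg_cut)} with 1=male, 2=female
HTGW_THRESHOLDS = {1: (90.0, 2.0), 2: (85.0, 1.5)}


@dataclass
class MethylationMatrix:
    """Methylation beta scores plus probe annotation and detection quality.

    ``beta`` (probes x samples) and ``detection_p`` are optional so that the
    probe-filter arithmetic can run on a bare manifest; ``annotation`` must
    cover every probe, with columns ``chrom``, ``pos``, ``gene``, ``context``,
    ``island``, ``is_cpg``, ``is_snp_probe``.  ``detection_fail_frac`` is the
    per-probe fraction of samples with detection p > 0.01 and is derived from
    ``detection_p`` when absent.
    """

    annotation: pd.DataFrame
    beta: pd.DataFrame | None = None
    detection_p: pd.DataFrame | None = None
    detection_fail_frac: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.beta is not None:
            if not self.beta.index.equals(self.annotation.index):
                raise ValueError("beta rows and annotation rows must match")
            vals = self.beta.to_numpy()
            if np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0:
                raise ValueError("beta values must lie in [0, 1]")
        if self.detection_fail_frac is None and self.detection_p is not None:
            self.detection_fail_frac = (self.detection_p > 0.01).mean(axis=1)

    @property
    def probe_ids(self) -> pd.Index:
        return self.annotation.index

    @property
    def sample_ids(self) -> pd.Index | None:
        return None if self.beta is None else self.beta.columns

    def subset(self, probes) -> "MethylationMatrix":
        return MethylationMatrix(
            annotation=self.annotation.loc[probes],
            beta=None if self.beta is None else self.beta.loc[probes],
            detection_p=None if self.detection_p is None else self.detection_p.loc[probes],
            detection_fail_frac=None
            if self.detection_fail_frac is None
            else self.detection_fail_frac.loc[probes],
        )


@dataclass
class ScanResult:
    """Per-marker association results plus scan-level bookkeeping."""

    table: pd.DataFrame
    lambda_median: float
    counts: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def make_htgw(waist_cm, tg_mmol, sex, thresholds=None) -> np.ndarray:
    """HTGW indicator: both sex-specific waist and triglyceride cut-offs met.

    Comparisons are inclusive (a male at exactly 90 cm and 2.0 mmol/L counts).
    A missing waist or triglyceride value yields NaN; missing indicators are
    counted and logged.
    """
    thresholds = HTGW_THRESHOLDS if thresholds is None else thresholds
    wc = np.asarray(waist_cm, dtype=float)
    tg = np.asarray(tg_mmol, dtype=float)
    sx = np.asarray(sex, dtype=int)
    wc_cut = np.array([thresholds[s][0] for s in sx])
    tg_cut = np.array([thresholds[s][1] for s in sx])
    out = ((wc >= wc_cut) & (tg >= tg_cut)).astype(float)
    miss = np.isnan(wc) | np.isnan(tg)
    out[miss] = np.nan
    if miss.any():
        log.info("make_htgw: %d individuals with missing components", int(miss.sum()))
    return out


def component_indicators(waist_cm, tg_mmol, sex, thresholds=None) -> pd.DataFrame:
    """Mutually exclusive indicators (both high, waist only, TG only).

    The reference category (neither high) is the all-zero row; the four
    categories partition the non-missing samples.
    """
    thresholds = HTGW_THRESHOLDS if thresholds is None else thresholds
    wc = np.asarray(waist_cm, dtype=float)
    tg = np.asarray(tg_mmol, dtype=float)
    sx = np.asarray(sex, dtype=int)
    wc_cut = np.array([thresholds[s][0] for s in sx])
    tg_cut = np.array([thresholds[s][1] for s in sx])
    hi_wc = wc >= wc_cut
    hi_tg = tg >= tg_cut
    out = pd.DataFrame(
        {
            "high_tg_and_wc": (hi_wc & hi_tg).astype(float),
            "high_wc_only": (hi_wc & ~hi_tg).astype(float),
            "high_tg_only": (~hi_wc & hi_tg).astype(float),
        }
    )
    out[np.isnan(wc) | np.isnan(tg)] = np.nan
    return out


def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform, z = Phi^-1((rank - 0.5) / n).

    Ties receive average ranks; missing values stay missing and do not enter
    the ranking.  Undefined when all non-missing values are identical.
    """
    v = np.asarray(values, dtype=float)
    mask = ~np.isnan(v)
    obs = v[mask]
    if obs.size < 3:
        raise ValueError("inverse_normal requires at least 3 non-missing values")
    if np.all(obs == obs[0]):
        raise ValueError("inverse_normal undefined for a constant vector")
    ranks = stats.rankdata(obs, method="average")
    z = stats.norm.ppf((ranks - 0.5) / obs.size)
    out = np.full(v.shape, np.nan)
    out[mask] = z
    return out


def filter_probes(m: MethylationMatrix, convergence_failures=()):
    """Apply the probe exclusions in their fixed order, reporting stage counts.

    Order: sex-chromosome probes, non-CpG probes, SNP-assay probes,
    model-convergence failures, then probes with detection p > 0.01 in > 5 %
    of samples (both inequalities strict).  Returns the filtered matrix and a
    Series of probes *remaining* after each stage.
    """
    ann = m.annotation
    counts = {"input": len(ann)}
    keep = ~ann["chrom"].astype(str).isin(["X", "Y", "23", "24", "chrX", "chrY"])
    counts["autosomal"] = int(keep.sum())
    keep &= ann["is_cpg"].astype(bool)
    counts["cpg"] = int(keep.sum())
    keep &= ~ann["is_snp_probe"].astype(bool)
    counts["non_snp_assay"] = int(keep.sum())
    keep &= ~ann.index.isin(set(convergence_failures))
    counts["converged"] = int(keep.sum())
    if m.detection_fail_frac is not None:
        keep &= ~((m.detection_fail_frac > 0.05) & keep)
    counts["detection_pass"] = int(keep.sum())
    return m.subset(ann.index[keep]), pd.Series(counts)


def filter_snps(g: pd.DataFrame, founders=None, min_call_rate=0.97,
                min_maf=0.05, min_hwe_p=0.001):
    """SNP QC: call rate >= 0.97, MAF >= 0.05, HWE exact p >= 0.001.

    ``g`` holds dosages 0/1/2 (samples x SNPs) with NaN for missing calls;
    the HWE exact test runs on founders only (``founders`` boolean mask,
    default all samples) to avoid relatedness distortion.  All thresholds are
    inclusive.  Returns the filtered matrix and per-stage remaining counts.
    """
    counts = {"input": g.shape[1]}
    call = g.notna().mean(axis=0)
    keep = call >= min_call_rate
    counts["call_rate"] = int(keep.sum())
    freq = g.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep &= maf >= min_maf
    counts["maf"] = int(keep.sum())
    gf = g if founders is None else g.loc[np.asarray(founders, dtype=bool)]
    hwe_p = pd.Series(
        {
            snp: hwe_exact(
                int((gf[snp] == 0).sum()),
                int((gf[snp] == 1).sum()),
                int((gf[snp] == 2).sum()),
            )
            for snp in g.columns[keep]
        }
    )
    keep &= hwe_p.reindex(g.columns, fill_value=0.0) >= min_hwe_p
    counts["hwe"] = int(keep.sum())
    return g.loc[:, keep], pd.Series(counts)


def hwe_exact(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy–Weinberg test by enumeration of heterozygote
    counts conditional on the allele counts (sum of probabilities no larger
    than the observed configuration's)."""
    n = n_aa_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("hwe_exact requires at least one genotype")
    n_a = 2 * n_aa_hom1 + n_het  # count of one allele
    rare = min(n_a, 2 * n - n_a)
    lg = math.lgamma
    lognorm = lg(n + 1) + lg(rare + 1) + lg(2 * n - rare + 1) - lg(2 * n + 1)

    def logp(h: int) -> float:
        return (
            lognorm
            + h * math.log(2.0)
            - lg(h + 1)
            - lg((rare - h) // 2 + 1)
            - lg((2 * n - rare - h) // 2 + 1)
        )

    hs = np.arange(rare % 2, rare + 1, 2)
    logps = np.array([logp(int(h)) for h in hs])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[hs == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def association_scan(markers: pd.DataFrame, trait, covariates, A,
                     kind: str = "continuous", lambda_correct: str = "auto",
                     fdr_level: float = 0.05, families=None) -> ScanResult:
    """Per-marker polygenic fixed-effect LRT scan with genomic control + FDR.

    ``markers`` is samples x markers, already inverse-normalised (methylation)
    or additive dosage (SNPs); ``covariates`` must include the intercept.  A
    single relationship eigendecomposition and one reduced (no-marker) fit are
    shared across all markers.  Per-marker convergence failures are recorded
    in ``failures`` and excluded from the corrected set, never dropped
    silently.  Genomic control divides the chi-square statistics by
    lambda_median only when it exceeds 1 (mode ``"auto"``).
    """
    y = np.asarray(trait, dtype=float)
    Xc = np.asarray(covariates, dtype=float)
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(A, families)
    yt = eig.rotate(y)
    Xct = eig.rotate(Xc)
    if kind == "liability":
        _, z_fac, _ = _liability_factors(float(np.mean(y)))
    cols = list(markers.columns)
    if not cols:
        empty = pd.DataFrame(
            columns=["marker", "b", "se", "p", "chi2", "p_corrected", "q", "n"]
        )
        return ScanResult(empty, float("nan"), {"markers": 0, "tested": 0}, [])
    h2_0, _ = _maximise_h2(yt, Xct, eig.d)
    logL0, _, _, _ = _profile(h2_0, yt, Xct, eig.d)
    rows, failures = [], []
    for name in cols:
        mt = eig.rotate(markers[name].to_numpy(dtype=float))
        Xt = np.column_stack([Xct, mt])
        try:
            h2_1, _ = _maximise_h2(yt, Xt, eig.d)
            logL1, beta, cov, _ = _profile(h2_1, yt, Xt, eig.d)
            lam = max(2.0 * (logL1 - logL0), 0.0)
            b, se = float(beta[-1]), float(np.sqrt(cov[-1, -1]))
            if kind == "liability":
                b, se = b / z_fac, se / z_fac
            rows.append((name, b, se, float(stats.chi2.sf(lam, 1)), lam))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            failures.append(name)
            log.warning("association_scan: marker %s failed to converge (%s)", name, exc)
    table = pd.DataFrame(rows, columns=["marker", "b", "se", "p", "chi2"])
    if len(table):
        lam_med = genomic_inflation(table["chi2"].to_numpy())
        apply_gc = lambda_correct == "auto"
        table["p_corrected"] = (
            correct_inflation(table["p"].to_numpy(), lam_med)
            if apply_gc
            else table["p"].to_numpy()
        )
        table["q"] = bh_fdr(table["p_corrected"].to_numpy())
    else:
        lam_med = float("nan")
        table["p_corrected"] = table["q"] = np.nan
    table["n"] = y.shape[0]
    counts = {"markers": len(cols), "tested": len(table), "failed": len(failures)}
    return ScanResult(table, lam_med, counts, failures)


def genomic_inflation(chi2_stats) -> float:
    """lambda_median: median association chi-square over the chi2(1) median."""
    s = np.asarray(chi2_stats, dtype=float)
    if s.size == 0:
        raise ValueError("genomic_inflation requires at least one statistic")
    if (s < 0).any():
        raise ValueError("chi-square statistics must be non-negative")
    return float(np.median(s) / CHI2_1_MEDIAN)


def correct_inflation(p, lam: float) -> np.ndarray:
    """Genomic-control correction of nominal p-values.

    Each p is mapped to its chi2(1) statistic, divided by max(lam, 1), and
    mapped back; lambda below 1 therefore leaves p untouched (deflating
    significance values would be anti-conservative bookkeeping).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    p = np.asarray(p, dtype=float)
    if lam <= 1.0:
        return p.copy()
    return stats.chi2.sf(stats.chi2.isf(p, 1) / lam, 1)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def liability_or(b: float, ci: tuple[float, float] | None = None):
    """Odds ratio for a liability-scale coefficient, OR = exp(sqrt(pi) * b).

    sqrt(pi) ~ 1.772 is the probit-to-logit scaling, so a liability (probit)
    coefficient maps onto an approximate log odds ratio; b is oriented so
    that positive values increase risk.  CI bounds transform identically.
    """
    out = float(np.exp(np.sqrt(np.pi) * b))
    if ci is None:
        return out
    lo, hi = (float(np.exp(np.sqrt(np.pi) * c)) for c in ci)
    return out, lo, hi


def median_beta_difference(beta, group) -> float:
    """Difference of within-group median beta values (group 1 minus group 0).

    The reporting convention for effect sizes on the raw methylation scale:
    a value of 0.016 means the affected group's median beta is 1.6
    percentage points higher.
    """
    b = np.asarray(beta, dtype=float)
    g = np.asarray(group, dtype=float)
    mask = ~(np.isnan(b) | np.isnan(g))
    b, g = b[mask], g[mask]
    return float(np.median(b[g == 1]) - np.median(b[g == 0]))


def ancestry_pcs(g: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal components of column-standardised dosages.

    Missing calls are mean-imputed per SNP; monomorphic SNPs are dropped.
    Sign convention: each component's largest-magnitude SNP loading is made
    positive, so scores are deterministic.
    """
    X = g.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if k == 0:
        return pd.DataFrame(index=g.index)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if k > rank:
        raise ValueError(f"requested {k} components but rank is {rank}")
    signs = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt[:k]), axis=1)])
    scores = U[:, :k] * S[:k] * signs
    return pd.DataFrame(
        scores, index=g.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
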