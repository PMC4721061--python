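from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from famews.scan import (
    CHI2_1_MEDIAN,
    MethylationMatrix,
    ancestry_pcs,
    association_scan,
    bh_fdr,
    component_indicators,
    correct_inflation,
    filter_probes,
    filter_snps,
    genomic_inflation,
    hwe_exact,
    inverse_normal,
    liability_or,
    make_htgw,
    median_beta_difference,
)


# ---------------------------------------------------------------------- HTGW
def test_htgw_inclusive_boundaries():
    wc = [90.0, 89.9, 85.0, 84.9, 120.0, 80.0]
    tg = [2.0, 2.0, 1.5, 1.5, 1.0, 1.0]
    sex = [1, 1, 2, 2, 1, 2]
    out = make_htgw(wc, tg, sex)
    np.testing.assert_array_equal(out, [1, 0, 1, 0, 0, 0])


def test_htgw_missing_values_propagate():
    out = make_htgw([np.nan, 95.0], [2.5, np.nan], [1, 1])
    assert np.isnan(out).all()


def test_component_indicators_partition():
    rng = np.random.default_rng(0)
    n = 200
    wc = rng.normal(88, 10, n)
    tg = rng.normal(1.8, 0.5, n)
    sex = rng.integers(1, 3, n)
    comp = component_indicators(wc, tg, sex)
    total = comp.sum(axis=1)
    assert set(total.unique()) <= {0.0, 1.0}
    both = make_htgw(wc, tg, sex)
    np.testing.assert_array_equal(comp["high_tg_and_wc"].to_numpy(), both)


# ------------------------------------------------------- inverse normal
def test_inverse_normal_three_values():
    z = inverse_normal([10.0, 20.0, 30.0])
    expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
    np.testing.assert_allclose(z, expected, atol=1e-12)
    assert z[0] == pytest.approx(-0.9674, abs=1e-4)


def test_inverse_normal_moments():
    rng = np.random.default_rng(1)
    z = inverse_normal(rng.exponential(size=850))
    assert abs(z.mean()) < 1e-10
    assert z.std() == pytest.approx(1.0, abs=0.05)


@settings(derandomize=True, max_examples=25)
@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50, unique=True))
def test_inverse_normal_rank_invariance(vals):
    v = np.asarray(vals)
    z1 = inverse_normal(v)
    z2 = inverse_normal(4.0 * v)  # strictly monotone (and float-exact) map
    np.testing.assert_allclose(z1, z2, atol=1e-10)


def test_inverse_normal_errors():
    with pytest.raises(ValueError):
        inverse_normal([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        inverse_normal([1.0, 2.0])


# ------------------------------------------------------------- probe filter
def _manifest(n_sex=5, n_non_cpg=3, n_snp=2, n_clean=20):
    n = n_sex + n_non_cpg + n_snp + n_clean
    chrom = ["X"] * n_sex + ["5"] * (n - n_sex)
    is_cpg = [True] * n_sex + [False] * n_non_cpg + [True] * (n_snp + n_clean)
    is_snp = [False] * (n_sex + n_non_cpg) + [True] * n_snp + [False] * n_clean
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n) + 1,
            "gene": "G",
            "context": "Body",
            "island": "Open sea",
            "is_cpg": is_cpg,
            "is_snp_probe": is_snp,
        },
        index=pd.Index([f"cg{i:04d}" for i in range(n)], name="probe"),
    )
    return ann


def test_filter_probes_stage_order_and_counts():
    ann = _manifest()
    fail_frac = pd.Series(0.0, index=ann.index)
    fail_frac.iloc[-1] = 0.10  # fails detection
    fail_frac.iloc[-2] = 0.05  # exactly 5 %: retained (strict >)
    m = MethylationMatrix(annotation=ann, detection_fail_frac=fail_frac)
    out, counts = filter_probes(m, convergence_failures=[ann.index[-3]])
    assert counts["input"] == 30
    assert counts["autosomal"] == 25
    assert counts["cpg"] == 22
    assert counts["non_snp_assay"] == 20
    assert counts["converged"] == 19
    assert counts["detection_pass"] == 18
    assert (np.diff(counts.to_numpy()) <= 0).all()
    assert ann.index[-2] in out.probe_ids


def test_filter_probes_noop_when_clean():
    ann = _manifest(n_sex=0, n_non_cpg=0, n_snp=0, n_clean=8)
    m = MethylationMatrix(annotation=ann)
    out, counts = filter_probes(m)
    assert list(out.probe_ids) == list(ann.index)
    assert counts["detection_pass"] == 8


# --------------------------------------------------------------- SNP filter
def _geno(cols: dict, n=100) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


def test_filter_snps_maf_boundary():
    n = 100
    maf05 = np.r_[np.ones(10), np.zeros(n - 10)]  # MAF exactly 0.05
    maf04 = np.r_[np.ones(8), np.zeros(n - 8)]    # MAF 0.04
    mono = np.zeros(n)
    g = _geno({"maf05": maf05, "maf04": maf04, "mono": mono})
    kept, counts = filter_snps(g)
    assert "maf05" in kept.columns
    assert "maf04" not in kept.columns and "mono" not in kept.columns


def test_filter_snps_call_rate_and_hwe():
    n = 100
    low_call = np.r_[np.full(4, np.nan), np.ones(n - 4)]   # call rate 0.96
    # call rate exactly 0.97 (inclusive) with HWE-consistent genotype counts
    ok_call = np.r_[np.full(3, np.nan), np.zeros(24), np.ones(49), np.full(24, 2.0)]
    het_excess = np.r_[np.zeros(5), np.ones(90), np.full(5, 2.0)]
    g = _geno({"low": low_call, "ok": ok_call, "hwe_bad": het_excess})
    kept, counts = filter_snps(g)
    assert "low" not in kept.columns
    assert "ok" in kept.columns
    assert "hwe_bad" not in kept.columns  # (5, 90, 5) -> p << 0.001


# ---------------------------------------------------------------- HWE exact
def _hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional het distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    rare = min(na, 2 * n - na)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        a_hom = (rare - h) // 2
        b_hom = (2 * n - rare - h) // 2
        probs[h] = (
            Fraction(2, 1) ** h
            * Fraction(comb(n, a_hom) * comb(n - a_hom, h), 1)
            * Fraction(1, comb(2 * n, rare))
        )
    tot = sum(probs.values())
    probs = {h: p / tot for h, p in probs.items()}
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (0, 100, 0), (5, 90, 5), (30, 40, 30), (1, 0, 99), (0, 2, 3)],
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert hwe_exact(*counts) == pytest.approx(_hwe_oracle(*counts), rel=1e-9)


def test_hwe_exact_properties():
    assert hwe_exact(25, 50, 25) == pytest.approx(1.0, abs=1e-9)
    assert hwe_exact(0, 100, 0) < 1e-6
    assert hwe_exact(7, 41, 52) == hwe_exact(52, 41, 7)  # allele-label symmetry


# -------------------------------------------------------- inflation and FDR
def test_genomic_inflation_basics():
    assert genomic_inflation([CHI2_1_MEDIAN] * 7) == pytest.approx(1.0)
    s = np.array([0.1, 0.5, 2.0])
    assert genomic_inflation(2 * s) == pytest.approx(2 * genomic_inflation(s))
    rng = np.random.default_rng(0)
    draws = rng.chisquare(1, size=100_000)
    assert 0.99 <= genomic_inflation(draws) <= 1.01
    with pytest.raises(ValueError):
        genomic_inflation([])


def test_correct_inflation():
    p = np.array([0.5, 0.05, 0.001])
    np.testing.assert_array_equal(correct_inflation(p, 1.0), p)
    np.testing.assert_array_equal(correct_inflation(p, 0.6152), p)  # no deflation
    corrected = correct_inflation(np.array([0.05]), 2.0)
    assert corrected[0] == pytest.approx(
        stats.chi2.sf(stats.chi2.isf(0.05, 1) / 2.0, 1), abs=1e-12
    )
    assert corrected[0] == pytest.approx(0.1659, abs=2e-4)


def test_bh_fdr_step_up():
    np.testing.assert_allclose(bh_fdr([0.02]), [0.02])
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


@settings(derandomize=True, max_examples=25)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40))
def test_bh_fdr_order_preserving(ps):
    p = np.asarray(ps)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q <= 1.0 + 1e-12).all() and (q >= p - 1e-12).all()


# ------------------------------------------------------------- OR transform
def test_liability_or_values():
    assert round(liability_or(0.65), 2) == 3.16
    assert liability_or(0.0) == 1.0
    or_, lo, hi = liability_or(0.65, (0.39, 0.90))
    assert round(lo, 2) == 2.00 and round(hi, 2) == 4.93


# ------------------------------------------------------------------- scans
def test_association_scan_null_and_power(small_study):
    ped, _, eig = small_study
    n = len(ped)
    rng = np.random.default_rng(7)
    from famews.simulate import simulate_polygenic_trait

    y = simulate_polygenic_trait(ped, eig, 0.4, seed=1)
    markers = pd.DataFrame(
        rng.standard_normal((n, 60)), columns=[f"m{j}" for j in range(60)]
    )
    markers["m0"] = markers["m0"] + 0.6 * (y - y.mean())  # planted marker
    X = np.ones((n, 1))
    res = association_scan(markers, y, X, eig)
    tab = res.table.set_index("marker")
    assert tab.loc["m0", "q"] < 0.05
    assert tab["p"].idxmin() == "m0"
    assert (tab["q"] >= tab["p_corrected"] - 1e-12).all()
    assert res.counts["tested"] == 60


def test_association_scan_identity_matches_plain_regression():
    rng = np.random.default_rng(8)
    n = 150
    y = rng.standard_normal(n)
    markers = pd.DataFrame(rng.standard_normal((n, 10)),
                           columns=[f"m{j}" for j in range(10)])
    X = np.ones((n, 1))
    res = association_scan(markers, y, X, np.eye(n))
    import statsmodels.api as sm

    for j, row in res.table.iterrows():
        full = sm.OLS(y, np.column_stack([X, markers[row["marker"]]])).fit()
        red = sm.OLS(y, X).fit()
        p_ols = stats.chi2.sf(2 * (full.llf - red.llf), 1)
        assert row["p"] == pytest.approx(p_ols, abs=1e-4)


def test_association_scan_empty():
    n = 20
    res = association_scan(
        pd.DataFrame(index=range(n)), np.random.default_rng(0).standard_normal(n),
        np.ones((n, 1)), np.eye(n)
    )
    assert len(res.table) == 0 and np.isnan(res.lambda_median)


# ------------------------------------------------------------ median diff
def test_median_beta_difference():
    group = np.r_[np.ones(5), np.zeros(5)]
    beta = np.r_[np.full(5, 0.5831), np.full(5, 0.5667)]
    assert median_beta_difference(beta, group) == pytest.approx(0.0164)


# ------------------------------------------------------------ ancestry PCs
def test_ancestry_pcs_separate_subpopulations():
    rng = np.random.default_rng(9)
    n, m = 120, 300
    maf_a = rng.uniform(0.1, 0.5, m)
    maf_b = np.clip(maf_a + rng.choice([-0.3, 0.3], m), 0.05, 0.95)
    ga = rng.binomial(2, maf_a, size=(n // 2, m))
    gb = rng.binomial(2, maf_b, size=(n // 2, m))
    g = pd.DataFrame(np.vstack([ga, gb]))
    pcs = ancestry_pcs(g, 4)
    pc1 = pcs["PC1"].to_numpy()
    assert abs(np.mean(pc1[: n // 2]) - np.mean(pc1[n // 2:])) > 3 * pc1.std() / 2
    # orthogonality and determinism
    S = pcs.to_numpy()
    off = S.T @ S - np.diag(np.diag(S.T @ S))
    assert np.abs(off).max() < 1e-8
    pd.testing.assert_frame_equal(pcs, ancestry_pcs(g, 4))
    assert ancestry_pcs(g, 0).shape == (n, 0)
    with pytest.raises(ValueError):
        ancestry_pcs(g.iloc[:, :3], 10)
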