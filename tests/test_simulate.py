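import numpy as np
import pandas as pd
import pytest

from famews.pedigree import relationship_matrix
from famews.polygenic import decompose_relationship
from famews.simulate import (
    SimConfig,
    read_cohort,
    simulate_binary_trait,
    simulate_bivariate,
    simulate_cohort,
    simulate_genotypes,
    simulate_methylome,
    simulate_pedigrees,
    simulate_polygenic_trait,
    write_cohort,
)


def test_pedigree_target_size_and_structure():
    ped = simulate_pedigrees(SimConfig(seed=0))
    assert len(set(ped.family_ids)) == 39
    assert 765 <= len(ped) <= 935  # within 10 % of 850
    # three generations: someone has a grandparent
    parents = ped.parent_indices()
    has_gp = any(
        parents[i, 0] >= 0 and parents[parents[i, 0], 0] >= 0 for i in range(len(ped))
    )
    assert has_gp


def test_pedigree_trio_and_determinism():
    trio = simulate_pedigrees(SimConfig(n_families=1, n_individuals=3, seed=1))
    assert len(trio) == 3 and trio.is_founder().sum() == 2
    a = simulate_pedigrees(SimConfig(seed=7)).table
    b = simulate_pedigrees(SimConfig(seed=7)).table
    pd.testing.assert_frame_equal(a, b)


def test_pedigree_infeasible_config():
    with pytest.raises(ValueError):
        simulate_pedigrees(SimConfig(n_families=10, n_individuals=5))


def test_polygenic_trait_variance_structure(small_study):
    ped, _, eig = small_study
    y0 = simulate_polygenic_trait(ped, eig, 0.0, seed=0)
    y1 = simulate_polygenic_trait(ped, eig, 1.0, seed=0)
    assert np.var(y0) == pytest.approx(1.0, rel=0.2)
    # full heritability: trait equals the genetic component; founder values iid
    founders = ped.is_founder()
    assert np.var(y1[founders]) == pytest.approx(1.0, rel=0.3)
    same = simulate_polygenic_trait(ped, eig, 0.5, seed=3)
    again = simulate_polygenic_trait(ped, eig, 0.5, seed=3)
    np.testing.assert_array_equal(same, again)


def test_binary_trait_prevalence_control():
    rng = np.random.default_rng(2)
    liab = rng.standard_normal(850)
    y = simulate_binary_trait(liab, 0.26)
    assert abs(y.sum() - 0.26 * 850) <= 1
    y50 = simulate_binary_trait(liab, 0.5)
    thr_implied = liab[y50 == 0].max()
    assert thr_implied == pytest.approx(np.median(liab), abs=0.05)


def test_bivariate_matches_closed_form(study):
    ped, _, eig = study
    h2i, h2j, rg, re_ = 0.3, 0.2, 0.07, 0.32
    rho_expected = rg * np.sqrt(h2i * h2j) + re_ * np.sqrt((1 - h2i) * (1 - h2j))
    cors = []
    for s in range(10):
        y1, y2 = simulate_bivariate(ped, eig, h2i, h2j, rg, re_, seed=s)
        cors.append(np.corrcoef(y1, y2)[0, 1])
    assert np.mean(cors) == pytest.approx(rho_expected, abs=0.04)
    # independence and the pure-genetic limit
    y1, y2 = simulate_bivariate(ped, eig, 0.5, 0.5, 0.0, 0.0, seed=99)
    assert abs(np.corrcoef(y1, y2)[0, 1]) < 0.15
    y1, y2 = simulate_bivariate(ped, eig, 1.0, 1.0, 0.6, 0.0, seed=100)
    assert np.corrcoef(y1, y2)[0, 1] == pytest.approx(0.6, abs=0.1)


def test_bivariate_rejects_non_psd(small_study):
    ped, _, eig = small_study
    with pytest.raises(ValueError, match="PSD"):
        simulate_bivariate(ped, eig, 0.3, 0.3, 1.4, 0.0)


def test_methylome_bounds_and_planted_differences(small_study):
    ped, _, eig = small_study
    n = len(ped)
    cfg = SimConfig(n_probes=150, seed=5)
    rng = np.random.default_rng(8)
    trait = (rng.random(n) < 0.26).astype(float)
    m = simulate_methylome(cfg, trait, ped, A=eig, seed=11)
    b = m.beta.to_numpy()
    assert b.min() >= 0.0 and b.max() <= 1.0
    assert m.annotation.shape[0] == 150
    assert set(cfg.effect_sites) <= set(m.probe_ids)
    # annotation exercises every filter category
    ann = m.annotation
    assert ann["chrom"].astype(str).isin(["X", "Y"]).any()
    assert (~ann["is_cpg"]).any()


def test_methylome_median_shift_sign(study):
    ped, _, eig = study
    cfg = SimConfig(n_probes=60, seed=5)
    rng = np.random.default_rng(9)
    trait = (rng.random(len(ped)) < 0.3).astype(float)
    diffs = {k: [] for k in cfg.effect_sites}
    for s in range(6):
        m = simulate_methylome(cfg, trait, ped, A=eig, seed=50 + s)
        for k in diffs:
            v = m.beta.loc[k].to_numpy()
            diffs[k].append(np.median(v[trait == 1]) - np.median(v[trait == 0]))
    for k, target in cfg.effect_sites.items():
        assert np.mean(diffs[k]) == pytest.approx(target, abs=0.004)


def test_genotypes_hwe_and_mendelian(write_ped):
    founders = "".join(f"F1 i{k} 0 0 {1 + k % 2}\n" for k in range(400))
    from famews.pedigree import read_pedigree

    ped = read_pedigree(write_ped(founders, "founders.fam"))
    g = simulate_genotypes(ped, 300, (0.5, 0.5), seed=0)
    freqs = np.array(
        [(g == 0).mean().mean(), (g == 1).mean().mean(), (g == 2).mean().mean()]
    )
    np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)


def test_genotypes_no_opposite_homozygotes(small_study):
    ped, _, _ = small_study
    g = simulate_genotypes(ped, 100, (0.1, 0.5), seed=1).to_numpy()
    parents = ped.parent_indices()
    for i in range(len(ped)):
        for par in parents[i]:
            if par >= 0:
                assert not np.any(np.abs(g[i] - g[par]) == 2)


def test_sib_dosage_correlation(study):
    ped, A, _ = study
    g = simulate_genotypes(ped, 400, (0.2, 0.5), seed=2).to_numpy()
    Av = A.to_numpy()
    parents = ped.parent_indices()
    # collect full-sib pairs
    sibs = []
    key = {i: tuple(parents[i]) for i in range(len(ped)) if parents[i].min() >= 0}
    from collections import defaultdict

    groups = defaultdict(list)
    for i, k in key.items():
        groups[k].append(i)
    for members in groups.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                sibs.append((members[a], members[b]))
    cors = []
    for i, j in sibs[:200]:
        c = np.corrcoef(g[i], g[j])[0, 1]
        if np.isfinite(c):
            cors.append(c)
    assert np.mean(cors) == pytest.approx(0.5, abs=0.05)


def test_cohort_roundtrip(tmp_path):
    cfg = SimConfig(n_families=4, n_individuals=60, n_probes=30, n_snps=20, seed=3)
    c = simulate_cohort(cfg)
    write_cohort(c, tmp_path / "cohort")
    back = read_cohort(tmp_path / "cohort")
    assert back.pedigree.sample_ids == c.pedigree.sample_ids
    pd.testing.assert_frame_equal(
        back.phenotypes, c.phenotypes, check_exact=False, rtol=1e-9
    )
    np.testing.assert_allclose(
        back.methylation.beta.to_numpy(), c.methylation.beta.to_numpy(), rtol=1e-9
    )
    np.testing.assert_allclose(back.genotypes.to_numpy(), c.genotypes.to_numpy())


def test_cohort_determinism():
    cfg = SimConfig(n_families=3, n_individuals=50, n_probes=20, n_snps=10, seed=9)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    np.testing.assert_array_equal(
        a.methylation.beta.to_numpy(), b.methylation.beta.to_numpy()
    )
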