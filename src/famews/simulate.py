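"""Synthetic family cohorts with the statistical structure the analyses assume.

The generator emulates the study conditions the pipeline is designed for:
39 three-generation extended families totalling ~850 individuals, a binary
hypertriglyceridemic-waist (HTGW) phenotype built from sex-thresholded waist
circumference and triglycerides, waist/triglyceride pairs with a specified
genetic/environmental correlation split, a methylome with a handful of
planted probes showing 1.0-1.6 percentage-point median beta differences
between phenotype groups, and SNP dosages produced by Mendelian gene
dropping through the pedigree.  Every generator is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .pedigree import Pedigree, relationship_matrix
from .polygenic import EigenRelationship, decompose_relationship
from .scan import MethylationMatrix, make_htgw

__all__ = [
    "SimConfig",
    "Cohort",
    "simulate_pedigrees",
    "simulate_polygenic_trait",
    "simulate_binary_trait",
    "simulate_bivariate",
    "simulate_methylome",
    "simulate_genotypes",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

CELL_TYPES = ("cd4t", "cd8t", "bcell", "nk", "gran")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the target design: 39 extended families, ~850
    individuals, HTGW heritability 0.52 at 26 % prevalence, a waist/TG pair
    with (h2_i, h2_j, rho_G, rho_E) = (0.30, 0.20, 0.07, 0.32), and three
    planted methylation probes with median beta differences of 1.0, 1.1 and
    1.6 percentage points between HTGW groups.
    """

    n_families: int = 39
    n_individuals: int = 850
    mean_children: float = 4.2
    mean_grandchildren: float = 3.2
    marry_prob: float = 0.85
    h2: float = 0.52
    prevalence: float = 0.26
    bivariate: tuple = (0.30, 0.20, 0.07, 0.32)  # (h2_i, h2_j, rho_G, rho_E)
    n_probes: int = 2000
    effect_sites: dict = field(
        default_factory=lambda: {
            "cg_eff_cpt1a_1": -0.010,
            "cg_eff_cpt1a_2": -0.011,
            "cg_eff_abcg1": 0.016,
        }
    )
    probe_noise_sd: float = 0.15  # logit scale
    probe_h2: float = 0.30
    frac_sex_chr: float = 0.024
    frac_non_cpg: float = 0.006
    frac_snp_probe: float = 0.001
    detection_fail_frac: float = 0.003
    chip_size: int = 12
    batch_sd: float = 0.05
    cell_dirichlet: tuple = (12.0, 5.0, 3.0, 2.0, 58.0)
    cell_loading_sd: float = 0.2
    n_snps: int = 1000
    maf_range: tuple = (0.05, 0.5)
    snp_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("h2", self.h2), ("prevalence", self.prevalence)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        h2i, h2j, rg, re_ = self.bivariate
        if not (0 <= h2i <= 1 and 0 <= h2j <= 1 and abs(rg) <= 1 and abs(re_) <= 1):
            raise ValueError("bivariate parameters out of bounds")
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")


@dataclass
class Cohort:
    """A fully simulated study: pedigree, phenotypes, methylome, genotypes."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    methylation: MethylationMatrix
    genotypes: pd.DataFrame
    cell_fractions: pd.DataFrame
    relationship: pd.DataFrame
    config: SimConfig


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_pedigrees(cfg: SimConfig) -> Pedigree:
    """Three-generation extended families within 10 % of the target size.

    Each family starts from a founder couple whose children may marry
    unrelated founders and have children of their own; after generation the
    total size is nudged to within 5 % of the target by adding or removing
    grandchildren (always leaves, so structure stays valid).
    """
    if cfg.n_families < 1:
        raise ValueError("n_families must be at least 1")
    if cfg.n_individuals < 3 * cfg.n_families - 1:
        raise ValueError(
            "n_individuals too small for the requested number of families"
        )
    rng = np.random.default_rng(cfg.seed)
    rows: list[tuple] = []  # (fid, iid, pat, mat, sex)
    couples: list[tuple] = []  # (fid, father iid, mother iid) able to add kids
    per_family = cfg.n_individuals / cfg.n_families

    for f in range(cfg.n_families):
        fid = f"FAM{f + 1:03d}"
        k = 0

        def new_iid():
            nonlocal k
            k += 1
            return f"{fid}_I{k:03d}"

        pa, ma = new_iid(), new_iid()
        rows.append((fid, pa, "", "", 1))
        rows.append((fid, ma, "", "", 2))
        n_children = max(1, int(rng.poisson(cfg.mean_children))) if per_family > 3 else 1
        for _ in range(n_children):
            child = new_iid()
            child_sex = int(rng.integers(1, 3))
            rows.append((fid, child, pa, ma, child_sex))
            if per_family > 6 and rng.random() < cfg.marry_prob:
                spouse = new_iid()
                spouse_sex = 3 - child_sex
                rows.append((fid, spouse, "", "", spouse_sex))
                father, mother = (child, spouse) if child_sex == 1 else (spouse, child)
                couples.append((fid, father, mother))
                for _ in range(int(rng.poisson(cfg.mean_grandchildren))):
                    rows.append((fid, new_iid(), father, mother, int(rng.integers(1, 3))))

    lo, hi = 0.95 * cfg.n_individuals, 1.05 * cfg.n_individuals
    grandchild_rows = [
        i for i, r in enumerate(rows) if r[2] and any(c[1] == r[2] and c[0] == r[0] for c in couples)
    ]
    while len(rows) > hi and grandchild_rows:
        rows.pop(grandchild_rows.pop(int(rng.integers(len(grandchild_rows)))))
        grandchild_rows = [
            i for i, r in enumerate(rows) if r[2] and any(c[1] == r[2] and c[0] == r[0] for c in couples)
        ]
    counter = {c[0]: 1000 for c in couples}
    while len(rows) < lo and couples:
        fid, father, mother = couples[int(rng.integers(len(couples)))]
        counter[fid] += 1
        rows.append((fid, f"{fid}_I{counter[fid]}", father, mother, int(rng.integers(1, 3))))

    table = pd.DataFrame(rows, columns=["fid", "iid", "pat", "mat", "sex"])
    return Pedigree(table)


def _eig(ped_or_A, A=None) -> EigenRelationship:
    if isinstance(ped_or_A, EigenRelationship):
        return ped_or_A
    return decompose_relationship(np.asarray(ped_or_A, dtype=float), A)


def simulate_polygenic_trait(ped: Pedigree, A, h2: float, seed=0,
                             X=None, beta=None) -> np.ndarray:
    """y = Xb + g + e with cov(g) = h2 * A and var(e) = 1 - h2."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    rng = _rng(seed)
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(
        np.asarray(A, dtype=float), ped.family_ids if ped is not None else None
    )
    n = eig.n
    if (eig.d < -1e-8).any():
        raise np.linalg.LinAlgError("relationship matrix is not PSD")
    g = eig.U @ (np.sqrt(h2 * eig.d) * rng.standard_normal(n))
    e = np.sqrt(1.0 - h2) * rng.standard_normal(n)
    y = g + e
    if X is not None and beta is not None:
        y = y + np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    return y


def simulate_binary_trait(liability, prevalence: float) -> np.ndarray:
    """Indicator of liability above its empirical (1 - prevalence) quantile."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    l = np.asarray(liability, dtype=float)
    thr = np.quantile(l, 1.0 - prevalence)
    return (l > thr).astype(float)


def simulate_bivariate(ped: Pedigree, A, h2_i: float, h2_j: float,
                       rho_g: float, rho_e: float, seed=0):
    """Two traits with genetic correlation rho_G and environmental rho_E.

    Genetic effects follow the Kronecker structure Sigma_G (x) A with
    Sigma_G = [[h2_i, rho_G*sqrt(h2_i h2_j)], [., h2_j]], and environmental
    residuals are i.i.d. with the complementary 2x2 covariance, so the
    implied phenotypic correlation is
    rho_G*sqrt(h2_i h2_j) + rho_E*sqrt((1-h2_i)(1-h2_j)).
    """
    for r, nm in ((rho_g, "rho_g"), (rho_e, "rho_e")):
        if abs(r) > 1.0:
            raise ValueError(f"{nm} correlation matrix is not PSD (|rho| > 1)")
    rng = _rng(seed)
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(
        np.asarray(A, dtype=float), ped.family_ids if ped is not None else None
    )
    n = eig.n
    sg = np.array(
        [
            [h2_i, rho_g * np.sqrt(h2_i * h2_j)],
            [rho_g * np.sqrt(h2_i * h2_j), h2_j],
        ]
    )
    se = np.array(
        [
            [1 - h2_i, rho_e * np.sqrt((1 - h2_i) * (1 - h2_j))],
            [rho_e * np.sqrt((1 - h2_i) * (1 - h2_j)), 1 - h2_j],
        ]
    )
    Lg = np.linalg.cholesky(sg + 1e-12 * np.eye(2))
    Le = np.linalg.cholesky(se + 1e-12 * np.eye(2))
    zg = rng.standard_normal((n, 2)) @ Lg.T * np.sqrt(eig.d)[:, None]
    G = eig.U @ zg
    E = rng.standard_normal((n, 2)) @ Le.T
    Y = G + E
    return Y[:, 0], Y[:, 1]


def _probe_annotation(cfg: SimConfig, rng) -> pd.DataFrame:
    ids = [f"cg{j:06d}" for j in range(cfg.n_probes - len(cfg.effect_sites))]
    ids += list(cfg.effect_sites)
    n = len(ids)
    chrom = rng.integers(1, 23, size=n).astype(object)
    is_cpg = np.ones(n, dtype=bool)
    is_snp = np.zeros(n, dtype=bool)
    n_bg = n - len(cfg.effect_sites)  # flags only on background probes
    n_sex = int(round(cfg.frac_sex_chr * n))
    n_ncpg = int(round(cfg.frac_non_cpg * n))
    n_snpp = int(round(cfg.frac_snp_probe * n))
    flagged = rng.choice(n_bg, size=min(n_sex + n_ncpg + n_snpp, n_bg), replace=False)
    chrom[flagged[:n_sex]] = rng.choice(["X", "Y"], size=len(flagged[:n_sex]), p=[0.8, 0.2])
    is_cpg[flagged[n_sex:n_sex + n_ncpg]] = False
    is_snp[flagged[n_sex + n_ncpg:]] = True
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": rng.integers(10_000, 200_000_000, size=n),
            "gene": [f"GENE{int(g)}" for g in rng.integers(1, 5000, size=n)],
            "context": rng.choice(["5'UTR", "Body", "TSS1500", "3'UTR"], size=n),
            "island": rng.choice(
                ["Island", "North shore", "South shore", "Open sea"], size=n
            ),
            "is_cpg": is_cpg,
            "is_snp_probe": is_snp,
        },
        index=pd.Index(ids, name="probe"),
    )


def simulate_methylome(cfg: SimConfig, trait, ped: Pedigree, A=None,
                       batch: pd.DataFrame | None = None,
                       cell_fractions: pd.DataFrame | None = None,
                       seed=None) -> MethylationMatrix:
    """Beta matrix on (0, 1) with planted group differences at effect sites.

    Values are generated on the logit scale as probe baseline + polygenic
    component + trait effect + chip/position batch effect + cell-fraction
    loading + noise, then mapped through the logistic function.  The planted
    shift for an effect site with baseline m and target median beta
    difference delta is logit(m + delta) - logit(m), applied to the affected
    group, so the realised median differences match the configured ones.
    """
    rng = _rng(cfg.seed + 1 if seed is None else seed)
    t = np.asarray(trait, dtype=float)
    n = t.shape[0]
    ann = _probe_annotation(cfg, rng)
    P = len(ann)
    baseline = rng.uniform(0.08, 0.92, size=P)
    # keep room for the planted shift at effect sites
    for j, (pid, delta) in enumerate(cfg.effect_sites.items()):
        i = ann.index.get_loc(pid)
        baseline[i] = float(np.clip(baseline[i], 0.08 + abs(delta), 0.92 - abs(delta)))
    M = np.tile(logit(baseline)[:, None], (1, n))
    # planted trait effects
    for pid, delta in cfg.effect_sites.items():
        i = ann.index.get_loc(pid)
        m0 = baseline[i]
        shift = logit(m0 + delta) - logit(m0)
        M[i] += shift * t
    # probe-level polygenic + residual noise
    if A is None:
        A = relationship_matrix(ped)
    eig = A if isinstance(A, EigenRelationship) else decompose_relationship(
        np.asarray(A, dtype=float), ped.family_ids
    )
    sd = cfg.probe_noise_sd
    Zg = rng.standard_normal((n, P))
    G = eig.U @ (np.sqrt(cfg.probe_h2 * sd * sd * eig.d)[:, None] * Zg)
    M += G.T
    M += np.sqrt((1 - cfg.probe_h2)) * sd * rng.standard_normal((P, n))
    # batch structure: chips of chip_size samples, 12 positions per chip
    if batch is None:
        chips = np.arange(n) // cfg.chip_size
        pos = np.arange(n) % cfg.chip_size
        batch = pd.DataFrame({"chip": chips, "position": pos})
    chip_eff = rng.normal(0.0, cfg.batch_sd, size=(P, int(batch["chip"].max()) + 1))
    pos_eff = rng.normal(0.0, cfg.batch_sd / 2, size=(P, int(batch["position"].max()) + 1))
    M += chip_eff[:, batch["chip"].to_numpy()]
    M += pos_eff[:, batch["position"].to_numpy()]
    # cell-type composition loadings
    if cell_fractions is None:
        cell_fractions = pd.DataFrame(
            rng.dirichlet(cfg.cell_dirichlet, size=n), columns=list(CELL_TYPES)
        )
    cf = cell_fractions.to_numpy()
    load = rng.normal(0.0, cfg.cell_loading_sd, size=(P, cf.shape[1]))
    M += load @ (cf - cf.mean(axis=0)).T
    beta = expit(M)
    samples = pd.Index(ped.sample_ids, name="sample")
    beta_df = pd.DataFrame(beta, index=ann.index, columns=samples)
    # detection p-values: clean probes well below 0.01, a configurable
    # fraction of probes failing in >5 % of samples
    det = rng.uniform(0.0, 0.005, size=(P, n))
    n_fail = int(round(cfg.detection_fail_frac * P))
    ok = np.ones(P, dtype=bool)
    for pid in cfg.effect_sites:
        ok[ann.index.get_loc(pid)] = False
    fail_probes = rng.choice(np.flatnonzero(ok), size=n_fail, replace=False)
    for i in fail_probes:
        frac = rng.uniform(0.06, 0.25)
        bad = rng.choice(n, size=max(int(np.ceil(frac * n)), int(0.05 * n) + 1), replace=False)
        det[i, bad] = rng.uniform(0.011, 0.5, size=bad.size)
    det_df = pd.DataFrame(det, index=ann.index, columns=samples)
    return MethylationMatrix(annotation=ann, beta=beta_df, detection_p=det_df)


def simulate_genotypes(ped: Pedigree, n_snps: int, maf_range=(0.05, 0.5),
                       seed=0, missing_rate: float = 0.0) -> pd.DataFrame:
    """Dosage matrix (samples x SNPs) by Mendelian gene dropping.

    Founder alleles are Bernoulli draws at a per-SNP MAF uniform on
    ``maf_range``; each non-founder inherits one uniformly chosen allele from
    each known parent (an unknown parent contributes a population draw).
    """
    lo, hi = maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed)
    n = len(ped)
    maf = rng.uniform(lo, hi, size=n_snps)
    alleles = np.zeros((n, 2, n_snps), dtype=np.int8)
    parents = ped.parent_indices()
    for i in ped.topological_order():
        f, m = parents[i]
        for slot, par in ((0, f), (1, m)):
            if par < 0:
                alleles[i, slot] = rng.random(n_snps) < maf
            else:
                pick = rng.integers(0, 2, size=n_snps)
                alleles[i, slot] = alleles[par, pick, np.arange(n_snps)]
    dose = alleles.sum(axis=1).astype(float)
    if missing_rate > 0:
        dose[rng.random(dose.shape) < missing_rate] = np.nan
    return pd.DataFrame(
        dose,
        index=pd.Index(ped.sample_ids, name="sample"),
        columns=[f"snp{j:05d}" for j in range(n_snps)],
    )


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a complete synthetic study under the configured conditions.

    Waist circumference and triglycerides are a bivariate polygenic pair with
    the configured (h2_i, h2_j, rho_G, rho_E); their sex-specific threshold
    crossings define HTGW with ~26 % joint prevalence.  T2D is a second
    threshold trait loading on the same waist/TG liabilities, glucose tracks
    T2D, and the methylome plants its effect sites on the HTGW indicator.
    """
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigrees(cfg)
    n = len(ped)
    A = relationship_matrix(ped)
    eig = decompose_relationship(A.to_numpy(), ped.family_ids)
    sex = ped.table["sex"].to_numpy()
    h2i, h2j, rg, re_ = cfg.bivariate
    z_wc, z_tg = simulate_bivariate(
        ped, eig, h2i, h2j, rg, re_, seed=rng.integers(2**31)
    )
    age = np.clip(rng.normal(45.0, 15.0, size=n), 18.0, 90.0)
    # scale liabilities so that ~55 % cross the waist cut and ~40 % the TG cut
    waist = np.where(sex == 1, 91.5, 86.5) + 12.0 * z_wc
    tg = np.clip(np.where(sex == 1, 1.85, 1.35) + 0.6 * z_tg, 0.1, None)
    htgw = make_htgw(waist, tg, sex)
    # T2D loads on the shared waist/TG axis plus its own polygenic liability
    own = simulate_polygenic_trait(ped, eig, 0.4, seed=rng.integers(2**31))
    t2d_liab = 0.45 * (z_wc + z_tg) / np.sqrt(2.0) + 0.9 * own
    t2d = simulate_binary_trait(t2d_liab, 0.20)
    glucose = np.clip(rng.normal(5.4, 0.7, size=n) + 1.8 * t2d, 3.0, None)
    bmi = np.clip(24.0 + 0.35 * (waist - waist.mean()) + rng.normal(0, 2.5, n), 15, None)
    sbp = np.clip(rng.normal(122, 14, n) + 4.0 * t2d, 80, None)
    dbp = np.clip(rng.normal(76, 9, n) + 2.0 * t2d, 40, None)
    med_lipid = (rng.random(n) < np.where(tg > np.median(tg), 0.25, 0.08)).astype(int)
    med_htn = (rng.random(n) < np.where(sbp > 130, 0.35, 0.10)).astype(int)
    med_diab = (rng.random(n) < np.where(t2d > 0, 0.6, 0.02)).astype(int)
    chips = np.arange(n) // cfg.chip_size
    pos = np.arange(n) % cfg.chip_size
    cells = pd.DataFrame(
        rng.dirichlet(cfg.cell_dirichlet, size=n),
        columns=list(CELL_TYPES),
        index=pd.Index(ped.sample_ids, name="sample"),
    )
    batch = pd.DataFrame({"chip": chips, "position": pos})
    meth = simulate_methylome(
        cfg, htgw, ped, A=eig, batch=batch,
        cell_fractions=cells.reset_index(drop=True),
        seed=rng.integers(2**31),
    )
    geno = simulate_genotypes(
        ped, cfg.n_snps, cfg.maf_range, seed=rng.integers(2**31),
        missing_rate=cfg.snp_missing_rate,
    )
    pheno = pd.DataFrame(
        {
            "fid": ped.family_ids,
            "age": age,
            "sex": sex,
            "waist_cm": waist,
            "tg_mmol": tg,
            "glucose_mmol": glucose,
            "t2d": t2d.astype(int),
            "htgw": htgw,
            "bmi": bmi,
            "sbp": sbp,
            "dbp": dbp,
            "med_lipid": med_lipid,
            "med_htn": med_htn,
            "med_diab": med_diab,
            "chip": chips,
            "chip_position": pos,
        },
        index=pd.Index(ped.sample_ids, name="sample"),
    )
    return Cohort(ped, pheno, meth, geno, cells, A, cfg)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort as plain TSV files plus a flat key=value config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.pedigree.table.assign(
        pat=lambda t: t["pat"].replace("", "0"),
        mat=lambda t: t["mat"].replace("", "0"),
    ).to_csv(out / "pedigree.tsv", sep="\t", header=False, index=False)
    cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
    cohort.methylation.beta.to_csv(out / "methylation_beta.tsv", sep="\t")
    cohort.methylation.annotation.to_csv(out / "probe_annotation.tsv", sep="\t")
    cohort.methylation.detection_p.to_csv(out / "detection_p.tsv", sep="\t")
    cohort.genotypes.to_csv(out / "genotypes.tsv", sep="\t")
    cohort.cell_fractions.to_csv(out / "cell_fractions.tsv", sep="\t")
    with open(out / "sim_config.txt", "w") as fh:
        for k, v in asdict(cohort.config).items():
            fh.write(f"{k}={v}\n")


def read_cohort(indir) -> Cohort:
    """Read back a cohort written by :func:`write_cohort` (lossless round trip
    up to floating-point text precision)."""
    from .pedigree import read_pedigree

    d = Path(indir)
    ped = read_pedigree(d / "pedigree.tsv")
    pheno = pd.read_csv(d / "phenotypes.tsv", sep="\t", index_col=0)
    ann = pd.read_csv(d / "probe_annotation.tsv", sep="\t", index_col=0)
    beta = pd.read_csv(d / "methylation_beta.tsv", sep="\t", index_col=0)
    det = pd.read_csv(d / "detection_p.tsv", sep="\t", index_col=0)
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col=0)
    cells = pd.read_csv(d / "cell_fractions.tsv", sep="\t", index_col=0)
    cfg_kv = {}
    with open(d / "sim_config.txt") as fh:
        for line in fh:
            k, v = line.rstrip("\n").split("=", 1)
            cfg_kv[k] = v
    meth = MethylationMatrix(annotation=ann, beta=beta, detection_p=det)
    A = relationship_matrix(ped)
    cfg = SimConfig(seed=int(cfg_kv.get("seed", 0)))
    return Cohort(ped, pheno, meth, geno, cells, A, cfg)
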