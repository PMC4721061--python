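"""End-to-end orchestration of the family-based HTGW study flow.

``run_pipeline`` sequences the stages on simulated (or previously written)
cohort data: phenotype construction, probe/SNP QC with stage counts, HTGW
heritability, waist-triglyceride bivariate decomposition, the EWAS scan
(optionally a GWAS scan with ancestry PCs), and — for FDR-significant sites —
the specificity model, the interactive-component model, mediation to T2D,
and the forward-stepwise K-L R^2 ladder.  Every number written to a report
comes from one module operation; the pipeline adds no arithmetic of its own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bivariate import correlation_test, fit_bivariate, residual_phenotypic_corr
from .covariates import build_covariates
from .pedigree import relationship_matrix
from .polygenic import decompose_relationship, fit_polygenic, fixed_effect_test, heritability_test
from .posthoc import sobel_mediation, stepwise_kl
from .scan import (
    ancestry_pcs,
    association_scan,
    component_indicators,
    filter_probes,
    filter_snps,
    inverse_normal,
    liability_or,
    make_htgw,
)
from .simulate import Cohort, SimConfig, read_cohort, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None          # load a written cohort instead of simulating
    covariate_set: str = "ewas"
    fdr_level: float = 0.05
    lambda_correct: str = "auto"
    medication_mode: str = "adjust"       # adjust | ignore | exclude
    run_gwas: bool = False
    n_pcs: int = 4
    outdir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.medication_mode not in ("adjust", "ignore", "exclude"):
            raise ValueError("medication_mode must be adjust, ignore or exclude")


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full study flow; returns the run report (also written to
    ``outdir`` as TSV tables plus a JSON report)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "version": __version__}

    # ---- data ------------------------------------------------------------
    if cfg.input_dir is not None:
        cohort = read_cohort(cfg.input_dir)
    else:
        sim = SimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
        cohort = _stage("simulate")(simulate_cohort)(sim)
    ped = cohort.pedigree
    founders = ped.is_founder()
    if cfg.medication_mode == "exclude":
        keep = (
            cohort.phenotypes[["med_lipid", "med_htn", "med_diab"]].sum(axis=1) == 0
        ).to_numpy()
        cohort = _subset(cohort, keep)
        founders = founders[keep]
    pheno = cohort.phenotypes.copy()
    A = cohort.relationship
    fams = pheno["fid"].to_numpy()
    eig = decompose_relationship(A.to_numpy(), fams)

    # ---- phenotype construction -----------------------------------------
    htgw = make_htgw(pheno["waist_cm"], pheno["tg_mmol"], pheno["sex"])
    pheno["htgw"] = htgw
    report["n"] = int(len(pheno))
    report["htgw_prevalence"] = float(np.nanmean(htgw))

    # ---- QC filters ------------------------------------------------------
    meth, probe_counts = _stage("probe_filter")(filter_probes)(cohort.methylation)
    geno, snp_counts = _stage("snp_filter")(filter_snps)(cohort.genotypes, founders)
    probe_counts.to_csv(out / "probe_filter_counts.tsv", sep="\t", header=["n_probes"])
    snp_counts.to_csv(out / "snp_filter_counts.tsv", sep="\t", header=["n_snps"])
    report["probe_counts"] = probe_counts.to_dict()
    report["snp_counts"] = snp_counts.to_dict()

    # ---- heritability of HTGW -------------------------------------------
    Xh = build_covariates(pheno, "heritability", medication_mode=cfg.medication_mode)
    fit_h = _stage("heritability")(fit_polygenic)(htgw, Xh, eig, kind="liability")
    p_h = heritability_test(fit_h, htgw, Xh, eig)
    report["heritability"] = {"h2": fit_h.h2, "p": p_h, "converged": fit_h.converged}

    # ---- Table-1-style association of HTGW with T2D traits ---------------
    t1_rows = []
    for cset in ("A", "B"):
        Xa = build_covariates(pheno, cset, medication_mode=cfg.medication_mode)
        Xa["htgw"] = htgw
        b, se, p = _stage("table1")(fixed_effect_test)(
            pheno["t2d"].to_numpy(float), Xa, eig, "htgw", kind="liability"
        )
        or_, or_lo, or_hi = liability_or(b, (b - 1.96 * se, b + 1.96 * se))
        t1_rows.append(("t2d", cset, b, se, p, or_, or_lo, or_hi))
        zg = inverse_normal(pheno["glucose_mmol"])
        b, se, p = fixed_effect_test(zg, Xa, eig, "htgw", kind="continuous")
        t1_rows.append(("glucose", cset, b, se, p, np.nan, np.nan, np.nan))
    table1 = pd.DataFrame(
        t1_rows, columns=["trait", "covariate_set", "b", "se", "p", "OR", "OR_lo", "OR_hi"]
    )
    table1.to_csv(out / "table1_htgw_t2d.tsv", sep="\t", index=False)
    report["table1"] = table1.to_dict("records")

    # ---- bivariate waist-TG decomposition --------------------------------
    Xa = build_covariates(pheno, "A", medication_mode=cfg.medication_mode)
    Xa = Xa.drop(columns=["bmi"])  # BMI is a near-alias of waist itself
    zw = inverse_normal(pheno["waist_cm"])
    zt = inverse_normal(pheno["tg_mmol"])
    bfit = _stage("bivariate")(fit_bivariate)(zw, zt, Xa, eig)
    bfit.p_rho_g = correlation_test(bfit, zw, zt, Xa, eig, "genetic")
    bfit.p_rho_e = correlation_test(bfit, zw, zt, Xa, eig, "environmental")
    rho_raw, p_raw = residual_phenotypic_corr(zw, zt, Xa)
    pd.DataFrame(
        [
            {
                "trait_i": "waist_cm", "trait_j": "tg_mmol",
                "rhoP_model": bfit.rho_p, "rhoP_residual": rho_raw,
                "p_rhoP_residual": p_raw, "rhoG": bfit.rho_g, "rhoE": bfit.rho_e,
                "p_G": bfit.p_rho_g, "p_E": bfit.p_rho_e,
                "h2_i": bfit.h2_i, "h2_j": bfit.h2_j,
            }
        ]
    ).to_csv(out / "bivariate_waist_tg.tsv", sep="\t", index=False)
    report["bivariate"] = {
        "rho_g": bfit.rho_g, "rho_e": bfit.rho_e, "rho_p": bfit.rho_p,
        "rho_p_residual": rho_raw, "p_g": bfit.p_rho_g, "p_e": bfit.p_rho_e,
    }

    # ---- EWAS scan -------------------------------------------------------
    Xe = build_covariates(
        pheno, cfg.covariate_set, cells=cohort.cell_fractions,
        medication_mode=cfg.medication_mode,
    )
    markers = pd.DataFrame(
        {p_: inverse_normal(meth.beta.loc[p_]) for p_ in meth.probe_ids},
        index=meth.beta.columns,
    )
    scan_res = _stage("ewas")(association_scan)(
        markers, htgw, Xe, eig, kind="liability",
        lambda_correct=cfg.lambda_correct, fdr_level=cfg.fdr_level,
    )
    ann = meth.annotation
    tab = scan_res.table.merge(
        ann[["chrom", "pos", "gene"]], left_on="marker", right_index=True, how="left"
    )
    tab.to_csv(out / "ewas_scan.tsv", sep="\t", index=False)
    tab[["marker", "chrom", "pos", "p_corrected"]].to_csv(
        out / "ewas_manhattan.tsv", sep="\t", index=False
    )
    report["ewas"] = {
        "lambda_median": scan_res.lambda_median,
        "counts": scan_res.counts,
        "n_significant": int((scan_res.table["q"] < cfg.fdr_level).sum()),
    }

    # ---- optional GWAS scan ---------------------------------------------
    if cfg.run_gwas and geno.shape[1] > 0:
        pcs = ancestry_pcs(geno, min(cfg.n_pcs, len(pheno) - 1))
        Xg = build_covariates(pheno, "gwas", pcs=pcs, medication_mode=cfg.medication_mode)
        gscan = _stage("gwas")(association_scan)(
            geno.fillna(geno.mean()), htgw, Xg, eig, kind="liability",
            lambda_correct=cfg.lambda_correct, fdr_level=cfg.fdr_level,
        )
        gscan.table.to_csv(out / "gwas_scan.tsv", sep="\t", index=False)
        report["gwas"] = {
            "lambda_median": gscan.lambda_median,
            "n_significant": int((gscan.table["q"] < cfg.fdr_level).sum()),
        }

    # ---- follow-ups on FDR-significant sites ------------------------------
    sig = scan_res.table.loc[scan_res.table["q"] < cfg.fdr_level].sort_values("p")
    report["significant_sites"] = list(sig["marker"])
    if len(sig):
        Xs = build_covariates(
            pheno, "specificity", cells=cohort.cell_fractions,
            medication_mode=cfg.medication_mode,
        )
        comp = component_indicators(pheno["waist_cm"], pheno["tg_mmol"], pheno["sex"])
        rows = []
        for site in sig["marker"]:
            z = markers[site].to_numpy()
            Xspec = Xs.copy()
            Xspec[site] = z
            b, se, p = _stage("specificity")(fixed_effect_test)(
                htgw, Xspec, eig, site, kind="liability"
            )
            rows.append({"site": site, "model": "specificity", "b": b, "se": se, "p": p})
            # interactive-component model: methylation regressed on the three
            # mutually exclusive phenotype-category indicators jointly
            Xi = pd.concat([Xe, comp.set_axis(Xe.index)], axis=1)
            for cat in comp.columns:
                b, se, p = fixed_effect_test(z, Xi, eig, cat, kind="continuous")
                rows.append({"site": site, "model": f"interactive:{cat}",
                             "b": b, "se": se, "p": p})
            med = _stage("mediation")(sobel_mediation)(
                z, htgw, pheno["t2d"].to_numpy(float), Xe, eig
            )
            rows.append({"site": site, "model": "mediation_t2d",
                         "b": med.product, "se": med.se, "p": med.p})
        table2 = pd.DataFrame(rows)
        table2.to_csv(out / "table2_followups.tsv", sep="\t", index=False)
        report["table2"] = table2.to_dict("records")
        ladder = _stage("kl_ladder")(stepwise_kl)(markers[list(sig["marker"])], htgw, Xe, eig)
        pd.DataFrame(
            {
                "model": ladder.labels,
                "kl_r2": ladder.r2,
                "delta_r2": [np.nan] + ladder.delta_r2,
                "p": ladder.p_step,
            }
        ).to_csv(out / "table3_kl_ladder.tsv", sep="\t", index=False)
        report["kl_ladder"] = {"r2": ladder.r2, "delta_r2": ladder.delta_r2}
    else:
        report["table2"] = []
        report["kl_ladder"] = None
        log.info("no FDR-significant sites; follow-up analyses skipped")

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _subset(cohort: Cohort, keep: np.ndarray) -> Cohort:
    """Restrict a cohort to a boolean sample mask (pedigree left intact for
    relationship bookkeeping; matrices are aligned to the kept samples)."""
    ids = cohort.phenotypes.index[keep]
    return Cohort(
        pedigree=cohort.pedigree,
        phenotypes=cohort.phenotypes.loc[ids],
        methylation=_meth_cols(cohort.methylation, ids),
        genotypes=cohort.genotypes.loc[ids],
        cell_fractions=cohort.cell_fractions.loc[ids],
        relationship=cohort.relationship.loc[ids, ids],
        config=cohort.config,
    )


def _meth_cols(m, ids):
    from .scan import MethylationMatrix

    return MethylationMatrix(
        annotation=m.annotation,
        beta=None if m.beta is None else m.beta[ids],
        detection_p=None if m.detection_p is None else m.detection_p[ids],
    )
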