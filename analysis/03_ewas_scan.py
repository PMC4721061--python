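#!/usr/bin/env python
"""Probe/SNP QC and the epigenome-wide association scan for HTGW.

Applies the probe exclusions (sex chromosomes, non-CpG, SNP-assay probes,
detection failures) and SNP filters (call rate, MAF, founder HWE), then runs
the per-probe liability-scale polygenic scan of inverse-normalised
methylation against HTGW with the full EWAS covariate set (age terms, chip
and position batch dummies, cell fractions, medications), applies genomic
control and BH-FDR, and also runs the SNP scan with four ancestry PCs.
Writes filter stage counts, the full scan table, Manhattan-plot data, and
the significant-site list under results/.
"""

import sys
import time
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))

from famews.covariates import build_covariates
from famews.polygenic import decompose_relationship
from famews.scan import (
    ancestry_pcs,
    association_scan,
    filter_probes,
    filter_snps,
    inverse_normal,
)
from famews.simulate import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort")
    ph = cohort.phenotypes
    eig = decompose_relationship(
        cohort.relationship.to_numpy(), cohort.pedigree.family_ids
    )
    htgw = ph["htgw"].to_numpy(float)

    meth, probe_counts = filter_probes(cohort.methylation)
    geno, snp_counts = filter_snps(cohort.genotypes, cohort.pedigree.is_founder())
    probe_counts.to_csv(ROOT / "results" / "probe_filter_counts.tsv", sep="\t",
                        header=["n_probes"], index_label="stage")
    snp_counts.to_csv(ROOT / "results" / "snp_filter_counts.tsv", sep="\t",
                      header=["n_snps"], index_label="stage")
    print("probe filter stages:", dict(probe_counts))
    print("SNP filter stages:  ", dict(snp_counts))

    X = build_covariates(ph, "ewas", cells=cohort.cell_fractions)
    markers = pd.DataFrame(
        {p: inverse_normal(meth.beta.loc[p]) for p in meth.probe_ids},
        index=meth.beta.columns,
    )
    t0 = time.time()
    res = association_scan(markers, htgw, X, eig, kind="liability")
    print(f"EWAS: {res.counts['tested']} probes in {time.time() - t0:.0f} s, "
          f"lambda_median = {res.lambda_median:.4f}")
    tab = res.table.merge(meth.annotation[["chrom", "pos", "gene"]],
                          left_on="marker", right_index=True, how="left")
    # full per-marker tables are bulky; they stay under scratch/
    tab.to_csv(ROOT / "scratch" / "ewas_scan.tsv", sep="\t", index=False)
    tab[["marker", "chrom", "pos", "p_corrected"]].to_csv(
        ROOT / "scratch" / "ewas_manhattan.tsv", sep="\t", index=False
    )
    sig = tab.loc[tab["q"] < 0.05].sort_values("p")
    sig.to_csv(ROOT / "results" / "ewas_significant.tsv", sep="\t", index=False)
    print(f"{len(sig)} FDR-significant sites:")
    if len(sig):
        print(sig[["marker", "b", "se", "p", "q"]].to_string(index=False))

    # GWAS with ancestry PCs
    pcs = ancestry_pcs(geno, 4)
    Xg = build_covariates(ph, "gwas", pcs=pcs)
    gres = association_scan(geno.fillna(geno.mean()), htgw, Xg, eig,
                            kind="liability")
    gres.table.to_csv(ROOT / "scratch" / "gwas_scan.tsv", sep="\t", index=False)
    pd.Series(
        {"n_snps": gres.counts["tested"], "lambda_median": gres.lambda_median,
         "min_q": gres.table["q"].min()}, name="value",
    ).to_csv(ROOT / "results" / "gwas_summary.tsv", sep="\t", header=True,
             index_label="quantity")
    print(f"GWAS: {gres.counts['tested']} SNPs, "
          f"lambda_median = {gres.lambda_median:.4f}, "
          f"min q = {gres.table['q'].min():.3f}")


if __name__ == "__main__":
    main()
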