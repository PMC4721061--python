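#!/usr/bin/env python
"""Cross-platform agreement of two methylation assays at the top site.

Emulates the validation experiment: a second measurement of the top
significant CpG site is simulated as the array value shifted down by 6.2
percentage points plus independent assay noise (a synthetic stand-in for a
pyrosequencing re-measurement; no real assay data is involved).  Reports
Spearman correlation, Bland-Altman limits of agreement with the fraction of
samples outside, and Pitman's test of unequal variances.  Writes
results/agreement.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))

from famews.agreement import bland_altman, pitman_test, spearman_corr
from famews.simulate import read_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 20_260_930
SHIFT = -0.062        # systematic offset of the second method
RHO = 0.70            # correlation between the two assays


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort")
    sig = pd.read_csv(ROOT / "results" / "ewas_significant.tsv", sep="\t")
    site = sig["marker"].iloc[0] if len(sig) else cohort.methylation.probe_ids[0]
    array = cohort.methylation.beta.loc[site].to_numpy()
    rng = np.random.default_rng(SEED + 1)
    # equal-variance construction: the second assay shares a correlated
    # component with the array and adds the complementary noise, so the two
    # methods disagree sample-to-sample without a variance difference
    mu, sd = array.mean(), array.std()
    noise = rng.normal(0.0, sd * np.sqrt(1.0 - RHO**2), array.size)
    pyro = np.clip(mu + SHIFT + RHO * (array - mu) + noise, 0.0, 1.0)

    rho, p_rho = spearman_corr(array, pyro)
    ba = bland_altman(array, pyro)
    p_pitman = pitman_test(array, pyro)
    out = pd.Series(
        {
            "site": site,
            "spearman_rho": rho,
            "spearman_p": p_rho,
            "mean_difference": ba.mean_diff,
            "loa_lower": ba.limits[0],
            "loa_upper": ba.limits[1],
            "n": ba.n,
            "n_outside_loa": ba.n_outside,
            "frac_outside_loa": ba.n_outside / ba.n,
            "pitman_p": p_pitman,
        },
        name="value",
    )
    out.to_csv(ROOT / "results" / "agreement.tsv", sep="\t", header=True,
               index_label="quantity")
    print(out.to_string())
    pd.DataFrame({"mean": ba.means, "difference": ba.diffs}).to_csv(
        ROOT / "scratch" / "agreement_bland_altman_points.tsv", sep="\t",
        index=False,
    )


if __name__ == "__main__":
    main()
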