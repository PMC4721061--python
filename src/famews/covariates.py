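"""Covariate-set construction for the polygenic models.

The analyses share a small vocabulary of covariate sets:

* ``age_terms`` — age, age^2, sex, age x sex, age^2 x sex (age is centred
  and scaled for conditioning; the span of the design is unchanged);
* ``A`` — age terms + BMI + systolic/diastolic BP + anti-lipid and
  anti-hypertensive medication flags;
* ``B`` — set A + anti-diabetic medication;
* ``heritability`` — age terms + the three medication flags + BP + presence
  of T2D and obesity (BMI >= 30);
* ``ewas`` — age terms + chip and chip-position dummies + estimated cell
  fractions + the three medication flags;
* ``specificity`` — ewas + T2D, obesity, and both blood pressures;
* ``gwas`` — age terms + the three medication flags (ancestry PCs are
  appended by the caller).

Every returned design carries an explicit leading intercept column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["age_terms", "build_covariates", "COVARIATE_SETS"]

MEDS = ["med_lipid", "med_htn", "med_diab"]


def age_terms(pheno: pd.DataFrame) -> pd.DataFrame:
    a = (pheno["age"].to_numpy(dtype=float) - 50.0) / 10.0
    s = (pheno["sex"].to_numpy(dtype=float) == 2).astype(float)  # female indicator
    return pd.DataFrame(
        {
            "age": a,
            "age2": a * a,
            "sex": s,
            "age_sex": a * s,
            "age2_sex": a * a * s,
        },
        index=pheno.index,
    )


def _dummies(values, prefix) -> pd.DataFrame:
    d = pd.get_dummies(pd.Categorical(values), prefix=prefix, drop_first=True)
    return d.astype(float)


def build_covariates(pheno: pd.DataFrame, which, cells: pd.DataFrame | None = None,
                     pcs: pd.DataFrame | None = None,
                     medication_mode: str = "adjust") -> pd.DataFrame:
    """Assemble the named covariate set (or an explicit column list).

    ``medication_mode="ignore"`` drops the medication flags from any set;
    sample exclusion for the "exclude-medicated" strategy is handled by the
    caller, which subsets the cohort before building covariates.
    """
    parts = [pd.DataFrame({"intercept": np.ones(len(pheno))}, index=pheno.index)]
    if isinstance(which, (list, tuple)):
        parts.append(pheno[list(which)].astype(float))
        return pd.concat(parts, axis=1)
    if which not in COVARIATE_SETS:
        raise KeyError(f"unknown covariate set {which!r}")
    at = age_terms(pheno)
    parts.append(at)
    meds = [] if medication_mode == "ignore" else MEDS
    if which in ("A", "B"):
        parts.append(pheno[["bmi", "sbp", "dbp"]].astype(float))
        if meds:
            use = ["med_lipid", "med_htn"] + (["med_diab"] if which == "B" else [])
            parts.append(pheno[use].astype(float))
    elif which == "heritability":
        if meds:
            parts.append(pheno[meds].astype(float))
        obesity = (pheno["bmi"] >= 30.0).astype(float).rename("obesity")
        parts.append(pheno[["sbp", "dbp"]].astype(float))
        parts.append(pd.concat([pheno["t2d"].astype(float), obesity], axis=1))
    elif which in ("ewas", "specificity"):
        bat = pd.concat(
            [
                _dummies(pheno["chip"].to_numpy(), "chip"),
                _dummies(pheno["chip_position"].to_numpy(), "pos"),
            ],
            axis=1,
        )
        bat.index = pheno.index
        parts.append(bat)
        if cells is not None:
            # drop one cell fraction: they sum to 1 with the intercept
            parts.append(cells.iloc[:, :-1].astype(float).set_axis(pheno.index))
        if meds:
            parts.append(pheno[meds].astype(float))
        if which == "specificity":
            obesity = (pheno["bmi"] >= 30.0).astype(float).rename("obesity")
            parts.append(pd.concat(
                [pheno["t2d"].astype(float), obesity,
                 pheno[["sbp", "dbp"]].astype(float)], axis=1))
    elif which == "gwas":
        if meds:
            parts.append(pheno[meds].astype(float))
        if pcs is not None:
            parts.append(pcs.set_axis(pheno.index))
    out = pd.concat(parts, axis=1)
    return out.loc[:, out.std() > 0].assign(intercept=1.0)[
        ["intercept"] + [c for c in out.columns if c != "intercept" and out[c].std() > 0]
    ]


COVARIATE_SETS = {"A", "B", "heritability", "ewas", "specificity", "gwas"}
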