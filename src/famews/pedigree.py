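"""Pedigree parsing and the additive genetic relationship matrix.

A pedigree is a forest of family graphs in the PLINK ``.fam`` column dialect
(FID IID PAT MAT SEX).  The additive relationship matrix A (twice the kinship
coefficient) is built by the recursive tabular method: founders are assumed
unrelated and non-inbred, and each non-founder row is the average of its
parents' rows, so entries between families are exactly zero and A is positive
semi-definite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "relationship_matrix",
    "write_relationship_matrix",
]

MALE, FEMALE = 1, 2


class PedigreeError(ValueError):
    """Structural or validation failure in a pedigree file."""


@dataclass
class Pedigree:
    """Validated pedigree; row order of ``table`` is the canonical sample order.

    ``table`` columns: fid, iid, pat, mat, sex — all ids as strings, missing
    parents as the empty string, sex coded 1=male / 2=female.
    """

    table: pd.DataFrame
    missing_marker: str = "0"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {
            (f, i): k
            for k, (f, i) in enumerate(zip(self.table["fid"], self.table["iid"]))
        }
        _validate(self)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["iid"])

    @property
    def family_ids(self) -> list[str]:
        return list(self.table["fid"])

    def is_founder(self) -> np.ndarray:
        """Boolean vector: True where both parents are unknown."""
        return ((self.table["pat"] == "") & (self.table["mat"] == "")).to_numpy()

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of row indices of (father, mother); -1 when unknown."""
        out = np.full((len(self), 2), -1, dtype=int)
        for k, (f, pat, mat) in enumerate(
            zip(self.table["fid"], self.table["pat"], self.table["mat"])
        ):
            if pat:
                out[k, 0] = self._index[(f, pat)]
            if mat:
                out[k, 1] = self._index[(f, mat)]
        return out

    def topological_order(self) -> np.ndarray:
        """Row indices ordered so every parent precedes its offspring."""
        parents = self.parent_indices()
        n = len(self)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for k in range(n):
            for p in parents[k]:
                if p >= 0:
                    children[p].append(k)
                    indeg[k] += 1
        order, stack = [], [k for k in range(n) if indeg[k] == 0]
        while stack:
            k = stack.pop()
            order.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != n:
            cyc = sorted(self.table["iid"][indeg > 0])
            raise PedigreeError(f"cyclic ancestry involving individuals {cyc}")
        return np.asarray(order)


def _validate(ped: Pedigree) -> None:
    t = ped.table
    dup = t.duplicated(subset=["fid", "iid"])
    if dup.any():
        bad = t.loc[dup, ["fid", "iid"]].to_records(index=False).tolist()
        raise PedigreeError(f"duplicate individual ids within family: {bad}")
    for role, col, want in (("father", "pat", MALE), ("mother", "mat", FEMALE)):
        for fid, pid in zip(t["fid"], t[col]):
            if not pid:
                continue
            key = (fid, pid)
            if key not in ped._index:
                raise PedigreeError(
                    f"{role} {pid!r} of family {fid!r} not present in that family"
                )
            if int(t["sex"].iloc[ped._index[key]]) != want:
                raise PedigreeError(
                    f"{role} {pid!r} in family {fid!r} has inconsistent sex"
                )
    ped.topological_order()  # raises on cycles


def read_pedigree(path, missing_marker: str = "0") -> Pedigree:
    """Read a whitespace-delimited FID IID PAT MAT SEX file.

    Missing parents are encoded by ``missing_marker`` (default ``"0"``); one
    known and one missing parent is allowed (unknown founder).  Row order is
    preserved as the canonical sample order.
    """
    t = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex"],
        dtype=str,
        comment="#",
        keep_default_na=False,
    )
    if t.isna().any().any():
        raise PedigreeError(f"{path}: expected 5 columns FID IID PAT MAT SEX")
    for col in ("pat", "mat"):
        t[col] = t[col].where(t[col] != missing_marker, "")
    sex = pd.to_numeric(t["sex"], errors="coerce")
    if not sex.isin([MALE, FEMALE]).all():
        raise PedigreeError("sex column must be coded 1 (male) / 2 (female)")
    t["sex"] = sex.astype(int)
    return Pedigree(t.reset_index(drop=True), missing_marker=missing_marker)


def relationship_matrix(ped: Pedigree) -> pd.DataFrame:
    """Additive relationship matrix A = 2*kinship, in canonical sample order.

    Tabular recursion with parents processed first:

        A[i, j] = (A[father(i), j] + A[mother(i), j]) / 2   (j already done)
        A[i, i] = 1 + A[father(i), mother(i)] / 2

    Unknown parents contribute 0 (unrelated founder); inbred loops raise the
    diagonal above 1 through the recursion.  Returned as a DataFrame indexed
    by individual id, block-diagonal by family.
    """
    n = len(ped)
    parents = ped.parent_indices()
    order = ped.topological_order()
    A = np.zeros((n, n))
    done: list[int] = []
    for i in order:
        f, m = parents[i]
        if f < 0 and m < 0:
            A[i, i] = 1.0
        else:
            row = np.zeros(len(done))
            if f >= 0:
                row += A[f, done]
            if m >= 0:
                row += A[m, done]
            row /= 2.0
            A[i, done] = row
            A[np.asarray(done, dtype=int), i] = row
            A[i, i] = 1.0 + (A[f, m] / 2.0 if (f >= 0 and m >= 0) else 0.0)
        done.append(i)
    return pd.DataFrame(A, index=ped.sample_ids, columns=ped.sample_ids)


def write_relationship_matrix(A: pd.DataFrame, path) -> None:
    A.to_csv(path, sep="\t", index_label="id")
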