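import numpy as np
import pytest

from famews.pedigree import Pedigree, relationship_matrix
from famews.polygenic import decompose_relationship
from famews.simulate import SimConfig, simulate_pedigrees


@pytest.fixture(scope="session")
def study():
    """Full-scale design: 39 extended families, ~850 individuals."""
    ped = simulate_pedigrees(SimConfig(seed=42))
    A = relationship_matrix(ped)
    eig = decompose_relationship(A.to_numpy(), ped.family_ids)
    return ped, A, eig


@pytest.fixture(scope="session")
def small_study():
    """Reduced design for repeated-simulation tests: 10 families, ~230."""
    ped = simulate_pedigrees(SimConfig(n_families=10, n_individuals=220, seed=42))
    A = relationship_matrix(ped)
    eig = decompose_relationship(A.to_numpy(), ped.family_ids)
    return ped, A, eig


@pytest.fixture
def write_ped(tmp_path):
    def _write(text, name="ped.fam"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


# ---------------------------------------------------------------------------
# independent oracles


def kinship_recursive(ped: Pedigree):
    """Kinship coefficients by the classical pairwise recursion (independent
    of the tabular construction): phi(i,i) = 1/2 + phi(f_i, m_i)/2 and, for
    i not an ancestor of j, phi(i,j) = (phi(f_i, j) + phi(m_i, j))/2."""
    parents = ped.parent_indices()
    order = {k: r for r, k in enumerate(ped.topological_order())}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def phi(i, j):
        if i == j:
            f, m = parents[i]
            both = f >= 0 and m >= 0
            return 0.5 * (1.0 + (phi(f, m) if both else 0.0))
        # recurse on the individual appearing later in topological order
        a, b = (i, j) if order[i] >= order[j] else (j, i)
        f, m = parents[a]
        if f < 0 and m < 0:
            return 0.0
        pf = phi(f, b) if f >= 0 else 0.0
        pm = phi(m, b) if m >= 0 else 0.0
        return 0.5 * (pf + pm)

    n = len(ped)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = phi(i, j)
    return K


def kinship_gene_drop(ped: Pedigree, n_rep=100_000, seed=0):
    """Monte-Carlo additive relationship by gene dropping: founders carry
    unique allele labels, alleles descend mendelianly, and A[i, j] is twice
    the probability that random alleles drawn from i and j are identical by
    descent."""
    rng = np.random.default_rng(seed)
    n = len(ped)
    parents = ped.parent_indices()
    order = ped.topological_order()
    alleles = np.zeros((n_rep, n, 2), dtype=np.int32)
    label = 0
    for i in order:
        f, m = parents[i]
        for slot, par in ((0, f), (1, m)):
            if par < 0:
                label += 1
                alleles[:, i, slot] = label * (n + 1) + i  # unique per founder slot
            else:
                pick = rng.integers(0, 2, size=n_rep)
                alleles[:, i, slot] = alleles[np.arange(n_rep), par, pick]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = (
                alleles[:, i, :, None] == alleles[:, j, None, :]
            ).mean(axis=(1, 2))
            A[i, j] = A[j, i] = 2.0 * ibd.mean()
    return A
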