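import numpy as np
import pytest

from sisdta.featurize import SubstructureSet, enumerate_substructures


@pytest.fixture(scope="session")
def benzene_set() -> SubstructureSet:
    return enumerate_substructures("c1ccccc1", mol_id="benzene")


@pytest.fixture(scope="session")
def phenol_set() -> SubstructureSet:
    return enumerate_substructures("Oc1ccccc1", mol_id="phenol")


def make_set(mol_id: str, idents) -> SubstructureSet:
    return SubstructureSet(molecule_id=mol_id, identifiers=frozenset(idents))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def gotoh_local(a: str, b: str, matrix, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Quadratic-space affine-gap local alignment (independent reference DP).

    A gap of length L costs gap_open + (L-1) * gap_extend, matching the
    convention where the first gapped position scores -gap_open and each
    extension -gap_extend.
    """
    n, m = len(a), len(b)
    neg = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
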