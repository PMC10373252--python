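import numpy as np
import pandas as pd
import pytest

from sspig import simdata


def make_pedigree(rows):
    """rows: (animal, sire, dam, generation, litter) tuples."""
    arr = np.array(rows, dtype=np.int64)
    n = len(arr)
    return simdata.Pedigree(
        animal=arr[:, 0],
        sire=arr[:, 1],
        dam=arr[:, 2],
        generation=arr[:, 3],
        litter=arr[:, 4],
        cohort=np.array([simdata.PUREBRED] * n),
        sex=np.array(["M", "F"] * ((n + 1) // 2))[:n],
    )


def kinship_oracle(pedigree):
    """Independent additive-relationship oracle: memoized recursive kinship,
    A_ij = 2 * phi(i, j)."""
    sire, dam = pedigree.parent_indices()
    memo = {}

    def phi(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        if (i, j) in memo:
            return memo[(i, j)]
        if i == j:
            val = 0.5 * (1.0 + phi(sire[i], dam[i]))
        else:
            # j is the younger (later) animal
            val = 0.5 * (phi(i, sire[j]) + phi(i, dam[j]))
        memo[(i, j)] = val
        return val

    n = pedigree.n
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = 2.0 * phi(i, j)
    return A


@pytest.fixture(scope="session")
def trio():
    return make_pedigree([(1, 0, 0, 0, 0), (2, 0, 0, 0, 0), (3, 1, 2, 1, 1)])


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimulationConfig(
        n_founders=60,
        n_generations=3,
        n_matings_per_gen=15,
        litter_size=6,
        n_seq_markers=600,
        n_chip_markers=60,
        n_qtl=15,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simdata.simulate_population(small_config)


def records_frame(animals, values, cg=None, litter=None, trait="T", covariate=None):
    n = len(animals)
    return pd.DataFrame(
        {
            "animal": animals,
            "trait": [trait] * n,
            "value": values,
            "cg": cg if cg is not None else [0] * n,
            "covariate": covariate if covariate is not None else [0.0] * n,
            "litter": litter if litter is not None else [0] * n,
        }
    )


def vc_frame(traits, values):
    idx = pd.Index(traits)
    return pd.DataFrame(np.atleast_2d(values), index=idx, columns=idx)
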