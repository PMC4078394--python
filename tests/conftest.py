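import numpy as np
import pytest

import csgwas as cg


@pytest.fixture(scope="session")
def small_genotypes() -> cg.GenotypeMatrix:
    """Independent-column matrix, 400 subjects x 200 markers."""
    return cg.simulate_genotypes(400, 200, maf_spec=(0.05, 0.5), seed=101)


@pytest.fixture(scope="session")
def medium_genotypes() -> cg.GenotypeMatrix:
    """Independent-column matrix, 1000 subjects x 500 markers."""
    return cg.simulate_genotypes(1000, 500, maf_spec=(0.05, 0.5), seed=202)


@pytest.fixture(scope="session")
def noisy_instance(medium_genotypes):
    """A fixed h2=0.5 selection problem with its simulated phenotype."""
    gm = medium_genotypes
    model = cg.make_true_model(cg.EnsembleSpec.signs(15), gm.markers, h2=0.5, seed=7)
    real = cg.simulate_phenotype(gm, model, seed=8)
    return gm, model, real


def brute_force_lambda_max(A: np.ndarray, y: np.ndarray) -> float:
    """Independent per-column oracle for the smallest all-zero penalty."""
    n = A.shape[0]
    best = 0.0
    for j in range(A.shape[1]):
        best = max(best, abs(float(A[:, j] @ y)) / n)
    return best
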