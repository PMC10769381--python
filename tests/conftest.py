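import numpy as np
import pytest

from elonglm.features import FeatureMatrix
from elonglm.glm import GeneData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_poisson_genes(kappa, n_genes, length, rng, chi_range=(0.5, 2.0)):
    """Generate genes directly from the count model X ~ Pois(chi * e^{-kappa.Y})
    with standard-normal dense features; returns (genes, matrix, chi)."""
    p = len(kappa) - 1
    Y = rng.standard_normal((n_genes * length, p))
    chi = rng.uniform(*chi_range, size=n_genes)
    z = Y @ np.asarray(kappa[1:]) + kappa[0]
    mean = np.repeat(chi, length) * np.exp(-z)
    counts = rng.poisson(mean).astype(float)
    genes = [GeneData(f"g{j}", counts[j * length:(j + 1) * length])
             for j in range(n_genes)]
    matrix = FeatureMatrix([f"f{i}" for i in range(p)], Y, mu=np.zeros(p),
                           sigma=np.ones(p), mode="dense")
    return genes, matrix, chi


@pytest.fixture
def poisson_gene_factory(rng):
    def factory(kappa, n_genes=3, length=40):
        return make_poisson_genes(np.asarray(kappa, float), n_genes, length, rng)
    return factory
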