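import numpy as np
import pytest

from drugnmf.expression import ExpressionStudy
from drugnmf.synthetic import make_nmf_study, make_two_class_study


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """3 genes x 4 samples, 2 normal + 2 tumor."""
    return ExpressionStudy(
        values=np.array(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [0.5, 0.25, 0.125, 0.0625]]
        ),
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["n1", "n2", "t1", "t2"],
        sample_class=["normal", "normal", "tumor", "tumor"],
        sample_drug=[None, None, "aspirin", "ibuprofen"],
    )


@pytest.fixture(scope="session")
def planted_nmf_study():
    """200 genes x 44 samples with 2 planted clusters at noise 0.1."""
    return make_nmf_study(n_genes=200, n_samples=44, k=2, noise_sd=0.1, seed=11)


@pytest.fixture(scope="session")
def planted_two_class_study():
    """300 genes, 30 planted DE genes at effect 3, 12 normal vs 44 tumor."""
    return make_two_class_study(
        n_genes=300, n_de=30, effect=3.0, n_norm=12, n_tumor=44, seed=11
    )


def random_consensus(m: int, n_runs: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """A valid consensus matrix from random run labelings."""
    C = np.zeros((m, m))
    for _ in range(n_runs):
        lab = rng.integers(0, k, size=m)
        C += lab[:, None] == lab[None, :]
    return C / n_runs
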