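import numpy as np
import pytest
from hypothesis import settings

# derandomized so the suite is reproducible in any environment
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere_problem():
    from bisma.core import Problem

    return Problem(
        dimension=2,
        lower=-10.0,
        upper=10.0,
        objective=lambda x: float(np.sum(np.asarray(x) ** 2)),
        name="sphere-2d",
    )


@pytest.fixture
def toy_dataset():
    """Small separable two-class expression matrix (6 samples x 4 genes)."""
    from bisma.gene_selection import ExpressionDataset

    matrix = np.array(
        [
            [0.1, 5.0, 0.3, -0.2],
            [-0.2, 5.2, 0.1, 0.4],
            [0.0, 4.8, -0.3, 0.0],
            [0.2, -5.1, 0.2, 0.1],
            [-0.1, -4.9, -0.1, -0.3],
            [0.3, -5.0, 0.0, 0.2],
        ]
    )
    labels = np.array([0, 0, 0, 1, 1, 1])
    return ExpressionDataset(matrix, labels, [f"g{i}" for i in range(4)], name="toy")
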