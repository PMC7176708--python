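import numpy as np
import pytest

from mandifem.meshing import generate_mesh
from mandifem.synth import ShapeParams, outline_from_params, simulate_phylogeny


@pytest.fixture(scope="session")
def default_outline():
    outline, landmarks, fractions = outline_from_params(ShapeParams())
    return outline, landmarks, fractions


@pytest.fixture(scope="session")
def mandible_mesh(default_outline):
    outline, _, _ = default_outline
    return generate_mesh(outline, 2.0, seed=0)


@pytest.fixture(scope="session")
def tree30():
    return simulate_phylogeny(30, seed=42)


@pytest.fixture(scope="session")
def bm_factory(tree30):
    """Draw BM-evolved trait matrices on the 30-tip session tree."""
    c, labels = tree30.vcv()
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(len(labels)))

    def draw(rng, p=10, scale=1.0):
        return scale * (chol @ rng.standard_normal((len(labels), p)))

    return draw, labels
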