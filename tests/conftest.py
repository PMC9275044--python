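import numpy as np
import pytest

from mtvc.genotypes import RelationshipMatrix
from mtvc.simulate import TraitArchitecture, default_architecture


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_kinship() -> RelationshipMatrix:
    """A fixed, well-conditioned 3x3 kinship used by the Kronecker
    covariance oracles."""
    A = np.array(
        [
            [1.00, 0.50, 0.20],
            [0.50, 1.00, 0.30],
            [0.20, 0.30, 1.00],
        ]
    )
    return RelationshipMatrix(A=A)


@pytest.fixture
def study_architecture() -> TraitArchitecture:
    """The two-trait simulation truth (h2 = 0.1/0.5, r_a ~ 0.3, r_e ~ 0.1)."""
    return default_architecture()
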