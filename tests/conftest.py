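import numpy as np
import pytest

from contiguity import (
    PlasticityRule,
    TransitionMatrix,
    random_transition_matrix,
    sample_sequence,
)


@pytest.fixture(scope="session")
def two_state_chain() -> TransitionMatrix:
    """P(A->B) = 0.8, P(B->A) = 0.4; stationary f = (1/3, 2/3)."""
    return TransitionMatrix(np.array([[0.2, 0.4], [0.8, 0.6]]))


@pytest.fixture(scope="session")
def chain12() -> TransitionMatrix:
    return random_transition_matrix(12, seed=12345)


@pytest.fixture(scope="session")
def long_sequence(chain12):
    return sample_sequence(chain12, 200_000, seed=999)


@pytest.fixture(scope="session")
def pre_rule() -> PlasticityRule:
    return PlasticityRule(0.06, 0.03, depression="pre")
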