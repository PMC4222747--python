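import numpy as np
import pytest

from rephmm import HMMParams, ObservedSequence, random_hmm


def random_instance(seed, n_max=5, m_max=4, t_max=400, t_min=2):
    """Random (model, i.i.d. sequence) pair for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    t = int(rng.integers(t_min, t_max + 1))
    hmm = random_hmm(n, m, seed=seed + 10_000)
    tokens = rng.integers(0, m, size=t)
    return hmm, ObservedSequence(tokens=tokens, alphabet_size=m)


@pytest.fixture
def identity_model():
    """2-state model with identity transitions and emissions: one surviving path."""
    return HMMParams(pi=[0.5, 0.5], trans=np.eye(2), emit=np.eye(2))


@pytest.fixture
def figure_sequence():
    """The 14-symbol binary worked example 10100010011001."""
    return ObservedSequence(tokens=[int(c) for c in "10100010011001"], alphabet_size=2)
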