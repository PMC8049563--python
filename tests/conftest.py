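import numpy as np
import pytest
from hypothesis import strategies as st

from twotwo import TTParams, tt_forward_probs


@pytest.fixture
def const_params():
    """A representative constant-ancestor parameter set (asymmetric drift)."""
    return TTParams(alpha1=0.8, alpha2=0.5, T1=1.25e-4, T2=2.0e-4,
                    V1=2.5e-5, V2=5.0e-5, theta=1e-3)


@pytest.fixture
def expected_counts(const_params):
    """Exact expected counts at 1e8 sites under ``const_params``."""
    return tt_forward_probs(const_params).expected_counts(1e8)


@st.composite
def tt_params(draw):
    """Valid constant-model parameters with V <= T (so that all seven
    polymorphic probabilities are nonnegative)."""
    alpha1 = draw(st.floats(0.05, 0.99))
    alpha2 = draw(st.floats(0.05, 0.99))
    theta = draw(st.floats(1e-5, 5e-3))
    T1 = draw(st.floats(0.0, 1e-3))
    T2 = draw(st.floats(0.0, 1e-3))
    V1 = T1 * draw(st.floats(0.0, 1.0))
    V2 = T2 * draw(st.floats(0.0, 1.0))
    return TTParams(alpha1=alpha1, alpha2=alpha2, T1=T1, T2=T2,
                    V1=V1, V2=V2, theta=theta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
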