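import numpy as np
import pytest

from predecode import GenerativeParams
from predecode.synthetic import FixtureSpec, make_pf_set


@pytest.fixture
def small_params():
    """Three receptors, two features with disjoint support."""
    Q = np.array([[2.0, 0.0], [0.0, 1.5], [0.0, 0.0]])
    return GenerativeParams(Q=Q, q0=np.array([0.1, 0.1, 0.2]))


@pytest.fixture
def disjoint_fixture():
    """Canonical disjoint-support fixture: 5 features on 30 channels."""
    spec = FixtureSpec(n_features=5, overlap=0.0, duration_s=50.0, seed=7)
    return spec, make_pf_set(spec)


@pytest.fixture
def overlapping_fixture():
    spec = FixtureSpec(n_features=5, overlap=0.7, duration_s=50.0, seed=7)
    return spec, make_pf_set(spec)
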