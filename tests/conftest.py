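import pytest

from dyadkit import DyadDesign, load_couples_moments


@pytest.fixture(scope="session")
def moments():
    """Packaged summary moments for the 141-couple example."""
    return load_couples_moments()


@pytest.fixture(scope="session")
def design():
    return DyadDesign(roles=("man", "woman"), predictor="anxiety", outcome="satisfaction")


@pytest.fixture(scope="session")
def sample_cov(moments, design):
    """4x4 sample covariance in design order (anxiety first, then satisfaction)."""
    return design.covariance(moments)
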