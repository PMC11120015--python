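import pytest

from npulud import SyntheticConfig, generate_gaussian_pu, toy_fixture


@pytest.fixture
def toy_pu():
    return toy_fixture("pu")


@pytest.fixture
def toy_supervised():
    return toy_fixture("supervised")


@pytest.fixture
def gaussian_separated():
    """Well-separated two-cluster dataset, 5% masked, fixed seed."""
    return generate_gaussian_pu(
        SyntheticConfig(n=200, separation=6.0, mask_ratio=0.05, seed=11)
    )
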