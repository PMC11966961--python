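import numpy as np
import pytest

from morphogrn import GradientSpec, Tissue1D


@pytest.fixture(scope="session")
def tissue100() -> Tissue1D:
    return Tissue1D(100)


@pytest.fixture(scope="session")
def falling_gradient() -> GradientSpec:
    """Static sigmoid with its high end at x = 0 (slope k < 0)."""
    return GradientSpec(form="static_sigmoid", k=-0.1, x0=50.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
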