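import numpy as np
import pytest

from dcmodel import MultilocusModel, PenetranceModel


@pytest.fixture
def default_levels() -> PenetranceModel:
    return PenetranceModel()


@pytest.fixture
def single_locus_model() -> MultilocusModel:
    """The canonical single-locus model: c = 0.2, 10% left-handedness."""
    return MultilocusModel.equal(1, 0.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
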