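import numpy as np
import pytest

import tissuevisco as tv


@pytest.fixture(scope="session")
def ligament_model() -> tv.TissueModel:
    """Bundled literature ligament parameters (a1 = 0) with spectrum."""
    return tv.reference_model("ligament")


@pytest.fixture(scope="session")
def cartilage_model() -> tv.TissueModel:
    """Bundled literature cartilage parameters with spectrum."""
    return tv.reference_model("cartilage")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
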