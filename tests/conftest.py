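import numpy as np
import pytest

from medicrypt import EncryptionKey, synth_xray


@pytest.fixture(scope="session")
def key() -> EncryptionKey:
    return EncryptionKey.from_hex("0123456789ABCDEF")


@pytest.fixture(scope="session")
def small_img() -> np.ndarray:
    """A 64x64 synthetic X-ray-like image shared across fast tests."""
    return synth_xray(64, 64, seed=7)
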