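import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
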