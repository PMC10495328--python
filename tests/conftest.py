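import numpy as np
import pytest

from rootsetup import geometry as geo


@pytest.fixture
def canonical_frame():
    """Occlusal plane z = 0, superior +z."""
    return geo.build_occlusal_frame(
        (10.0, 0.0, 0.0), (-10.0, 0.0, 0.0), (0.0, 30.0, 0.0), (0.0, 15.0, 8.0)
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform(rng: np.random.Generator, scale: float = 20.0) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = random_rotation(rng)
    T[:3, 3] = rng.uniform(-scale, scale, 3)
    return T


@pytest.fixture
def rng():
    return np.random.default_rng(20230911)
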