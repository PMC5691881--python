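import numpy as np
import pytest

from vertmorph import VertebraSpec, generate_vertebra_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def symmetric_model():
    """Mirror-symmetric vertebral body: parallel endplates, no wedging."""
    return generate_vertebra_mesh(VertebraSpec(tilt_deg=0.0))


@pytest.fixture
def wedged_spec():
    """Circular-endplate wedged body with a convenient closed form."""
    return VertebraSpec(r_x=20.0, r_y=20.0, height=25.0, tilt_deg=3.0)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
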