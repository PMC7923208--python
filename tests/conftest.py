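import numpy as np
import pytest

from uclstrain import GeneratorParams, generate_specimen


@pytest.fixture(params=["I", "II", "III"])
def group(request):
    return request.param


@pytest.fixture
def specimen(group):
    """Default synthetic specimen of each morphology group."""
    return generate_specimen(GeneratorParams(seed=3, group=group))


@pytest.fixture
def group1_specimen():
    return generate_specimen(GeneratorParams(seed=3, group="I"))


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
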