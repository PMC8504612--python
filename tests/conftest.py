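import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_gradient(tensor, scalar_fn, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar_fn w.r.t. tensor.data."""
    g = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        tensor.data[i] += eps
        fp = scalar_fn()
        tensor.data[i] -= 2 * eps
        fm = scalar_fn()
        tensor.data[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture
def smooth_field():
    """A smooth random displacement field factory (voxel units)."""

    def make(shape, amplitude=0.8, seed=0):
        r = np.random.default_rng(seed)
        axes = [np.linspace(0, 2 * np.pi, d) for d in shape]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        field = np.zeros(tuple(shape) + (3,))
        for a in range(3):
            p = r.uniform(0, 2 * np.pi, 3)
            field[..., a] = amplitude * (
                np.sin(gx + p[0]) * np.cos(gy + p[1]) * np.sin(gz + p[2])
            )
        return field

    return make
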