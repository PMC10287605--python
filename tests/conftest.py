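import numpy as np
import pytest

from lemap import (
    EntropyMap,
    KernelConfig,
    Mask,
    PhantomSpec,
    Volume,
    generate_phantom,
    kernel_entropy,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def random_volume(rng):
    """A 16^3 volume of random integer HU-like values."""
    return Volume(data=rng.integers(-50, 200, size=(16, 16, 16)).astype(float))


@pytest.fixture
def ball_mask():
    def _make(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return Mask(data=d2 <= radius**2, spacing=spacing)

    return _make


@pytest.fixture(scope="session")
def rim_phantom():
    return generate_phantom(PhantomSpec(pattern="peripheral_rim_complete", seed=11))


def brute_force_entropy_map(data: np.ndarray, k: int, bin_width: float = 1.0) -> np.ndarray:
    """Independent per-voxel oracle: extract every k^3 neighborhood from a
    reflect-padded copy and evaluate the entropy formula on it."""
    half = k // 2
    padded = np.pad(np.asarray(data, dtype=float), half, mode="reflect")
    out = np.empty(data.shape)
    for x in range(data.shape[0]):
        for y in range(data.shape[1]):
            for z in range(data.shape[2]):
                win = padded[x : x + k, y : y + k, z : z + k]
                out[x, y, z] = kernel_entropy(win, bin_width)
    return out


def as_entropy_map(data, **kw) -> EntropyMap:
    """Wrap a plain array as an EntropyMap for stats/classifier tests."""
    return EntropyMap(data=np.asarray(data, dtype=float), kernel=KernelConfig(), **kw)
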