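import numpy as np
import pytest

from spherosim import LabelVolume, SpheroidSpec, generate_spheroid


@pytest.fixture(scope="session")
def small_spheroid() -> LabelVolume:
    """~20 cells in a radius-10 ball; shared by tests that only read it."""
    return generate_spheroid(SpheroidSpec(n_cells=20, radius=10, seed=11))


@pytest.fixture(scope="session")
def medium_spheroid() -> LabelVolume:
    """~40 cells in a radius-14 ball (33^3 lattice)."""
    return generate_spheroid(SpheroidSpec(n_cells=40, radius=14, seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_label_volume(rng: np.random.Generator, shape=(6, 5, 4), n_labels=4) -> LabelVolume:
    """Arbitrary (not necessarily connected) random label lattice."""
    lattice = rng.integers(0, n_labels + 1, size=shape).astype(np.int32)
    return LabelVolume(lattice, (1.0, 1.0, 1.0))
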