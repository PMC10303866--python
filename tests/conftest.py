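import numpy as np
import pytest

from vermicelli.hic import ContactMatrix
from vermicelli.io import GenomeBins, NucleusImage, make_bins


@pytest.fixture
def bins10() -> GenomeBins:
    return make_bins({"chrS": 10 * 40_000}, 40_000)


@pytest.fixture
def random_symmetric():
    """Factory for random positive symmetric count matrices."""

    def _make(n: int, seed: int = 0, lam: float = 20.0) -> ContactMatrix:
        rng = np.random.default_rng(seed)
        a = rng.poisson(lam, (n, n)).astype(float) + 1.0
        a = 0.5 * (a + a.T)
        return ContactMatrix(a, make_bins({"chrS": n * 40_000}, 40_000))

    return _make


@pytest.fixture
def constant_image():
    """Factory for constant-intensity nucleus images (full-frame mask)."""

    def _make(value: float = 50.0, shape=(60, 60),
              pixel_size: float = 0.05) -> NucleusImage:
        return NucleusImage(intensity=np.full(shape, value),
                            pixel_size=pixel_size)

    return _make
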