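"""Shared fixtures: small rasters and geometries generated at test time."""

import numpy as np
import pytest

from spikedecay import Geometry, SpikeRaster, pairwise_distances


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_geometry() -> Geometry:
    rng = np.random.default_rng(42)
    return pairwise_distances(rng.random((6, 2)))


@pytest.fixture()
def small_raster() -> SpikeRaster:
    rng = np.random.default_rng(43)
    return SpikeRaster((rng.random((6, 40)) < 0.2).astype(np.uint8))


@pytest.fixture()
def bernoulli_raster() -> SpikeRaster:
    """Independent homogeneous Bernoulli(0.01) raster, 200 x 20000 bins."""
    rng = np.random.default_rng(44)
    return SpikeRaster((rng.random((200, 20000)) < 0.01).astype(np.uint8))
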