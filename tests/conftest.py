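"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fragmatrix.grids import (HIGH, MATRIX, MEDIUM, NODATA, SUITABLE,
                              UNSUITABLE, BinaryHabitatMap, FootprintRaster,
                              SuitabilityRaster)


def brute_force_mean_distance(source_mask: np.ndarray, target_mask: np.ndarray,
                              pixel_size: float = 1.0) -> float:
    """All-pairs oracle: mean over source pixels of min distance to a target pixel."""
    src = np.argwhere(source_mask).astype(float)
    tgt = np.argwhere(target_mask).astype(float)
    return float(cdist(src, tgt).min(axis=1).mean() * pixel_size)


def random_binary_map(rng: np.random.Generator, size: int,
                      p_suitable: float = 0.5) -> BinaryHabitatMap:
    """Random habitat map guaranteed to contain both classes."""
    while True:
        grid = np.where(rng.random((size, size)) < p_suitable,
                        SUITABLE, MATRIX).astype(np.uint8)
        if (grid == SUITABLE).any() and (grid == MATRIX).any():
            return BinaryHabitatMap(grid)


@pytest.fixture
def center_block_map() -> BinaryHabitatMap:
    """5x5 map, central 3x3 suitable, rest matrix."""
    grid = np.full((5, 5), MATRIX, dtype=np.uint8)
    grid[1:4, 1:4] = SUITABLE
    return BinaryHabitatMap(grid)


@pytest.fixture
def uniform_footprint():
    def make(value: int, shape=(5, 5), epoch: int = 2000) -> FootprintRaster:
        return FootprintRaster(np.full(shape, value, dtype=np.int16), epoch=epoch)
    return make


def suitability_from_string(text: str) -> SuitabilityRaster:
    """Build a raster from an ASCII sketch: H/M/U classes, '.' = NODATA."""
    code = {"H": HIGH, "M": MEDIUM, "U": UNSUITABLE, ".": NODATA}
    rows = [[code[ch] for ch in line] for line in text.split()]
    return SuitabilityRaster(np.array(rows, dtype=np.uint8))
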