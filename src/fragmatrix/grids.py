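"""Raster containers and single-band TIFF I/O.

All grids in the package live on one shared rectangular pixel grid.  Suitability
rasters are categorical (high / medium / unsuitable), habitat maps are binary
(suitable / matrix), and human-footprint rasters are integer pressure indices
in 0-50.  NODATA marks pixels outside the species' geographic range and is
carried unchanged through every operation.

Code table used on disk (uint8, single band):

=============  =====
class          code
=============  =====
UNSUITABLE     0
MEDIUM         1
HIGH           2
NODATA         255
SUITABLE       1  (binary maps)
MATRIX         0  (binary maps)
footprint      0-50, NODATA 255
=============  =====
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

# categorical suitability codes
UNSUITABLE = 0
MEDIUM = 1
HIGH = 2
NODATA = 255

# binary habitat-map codes
MATRIX = 0
SUITABLE = 1

#: suitability classes that may appear inside a species range
SUITABILITY_CLASSES = (UNSUITABLE, MEDIUM, HIGH)

MAIN = "main"
SENSITIVITY = "sensitivity"
SCENARIOS = (MAIN, SENSITIVITY)


@dataclass
class SuitabilityRaster:
    """Categorical habitat-suitability grid for one species.

    ``grid`` holds codes from :data:`SUITABILITY_CLASSES` plus :data:`NODATA`
    outside the range.  ``degenerate`` flags all-suitable / all-unsuitable
    landscapes produced by extreme habitat proportions.
    """

    grid: np.ndarray
    pixel_size: float = 1.0
    species_id: str = "sp0000"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("suitability grid must be 2-D")
        valid = set(SUITABILITY_CLASSES) | {NODATA}
        if not set(np.unique(self.grid)).issubset(valid):
            raise ValueError("suitability grid contains unknown codes")
        if np.all(self.grid == NODATA):
            raise ValueError("suitability grid has no in-range pixels")

    @property
    def in_range(self) -> np.ndarray:
        return self.grid != NODATA


@dataclass
class BinaryHabitatMap:
    """Binary habitat / matrix map derived from a suitability raster."""

    grid: np.ndarray
    scenario: str = MAIN
    pixel_size: float = 1.0
    species_id: str = "sp0000"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def suitable(self) -> np.ndarray:
        return self.grid == SUITABLE

    @property
    def matrix(self) -> np.ndarray:
        return self.grid == MATRIX

    @property
    def in_range(self) -> np.ndarray:
        return self.grid != NODATA


@dataclass
class FootprintRaster:
    """Human-footprint pressure index (0-50) for one epoch."""

    grid: np.ndarray
    epoch: int = 2000
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        data = self.grid[self.grid != NODATA]
        if data.size and (data.min() < 0 or data.max() > 50):
            raise ValueError("footprint values must lie in [0, 50]")

    @property
    def valid(self) -> np.ndarray:
        return self.grid != NODATA


def write_raster(path: str | Path, grid: np.ndarray) -> None:
    """Write a single-band uint8 TIFF using the module code table."""
    tifffile.imwrite(str(path), np.asarray(grid, dtype=np.uint8))


def read_raster(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    return arr.astype(np.uint8)
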