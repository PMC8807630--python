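"""Per-species landscape and pressure predictors.

From a binary habitat map and two human-footprint epochs this module derives
the environmental / pressure predictor set used by the extinction-risk model:

* degree of fragmentation — mean Euclidean distance of suitable-habitat
  pixels to the nearest habitat edge.  Large values mean large, compact
  patches, i.e. LOW fragmentation; the raw mean is returned and any inverse
  coding is left to presentation.
* degree of patch isolation — mean Euclidean distance of matrix pixels to
  the nearest suitable pixel.  Large values mean isolated patches.
* extent of high human footprint — proportion of a region's pixels at or
  above the footprint threshold (default 3 of 50), for the matrix and for
  the suitable patches, per epoch.
* change in that extent between epochs, after discarding cells whose
  footprint decreased (treated as unchanged), so the change is never
  negative.
* proportion of suitable habitat within the range.

All metrics are means or proportions, never totals, so they do not encode
range size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BinaryHabitatMap, FootprintRaster

logger = logging.getLogger(__name__)

CENTER_TO_CENTER = "center_to_center"
CENTER_TO_BOUNDARY = "center_to_boundary"

#: names of the trait columns joined onto the landscape metrics
TRAIT_COLUMNS = ("body_mass", "diet", "weaning_age", "gestation_length",
                 "order", "realm")


class UndefinedMetricError(ValueError):
    """A metric has no defined value on this map (e.g. an empty region)."""


@dataclass
class MetricsConfig:
    """Conventions for the landscape metrics.

    ``hfp_threshold`` is inclusive ("3 or above").  ``distance_convention``
    selects pixel-centre-to-pixel-centre distances (GIS default) or
    centre-to-boundary (half a pixel shorter, floored at zero).  When
    ``treat_range_boundary_as_edge`` is set, NODATA pixels count as edge in
    both distance metrics (for ranges whose habitat reaches the range limit).
    """

    hfp_threshold: int = 3
    distance_convention: str = CENTER_TO_CENTER
    treat_range_boundary_as_edge: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.hfp_threshold <= 50:
            raise ValueError("hfp_threshold must lie in [0, 50]")
        if self.distance_convention not in (CENTER_TO_CENTER, CENTER_TO_BOUNDARY):
            raise ValueError(f"unknown distance convention {self.distance_convention!r}")


def _mean_distance_to(targets: np.ndarray, sources: np.ndarray,
                      pixel_size: float, convention: str) -> float:
    """Mean distance from each source pixel to the nearest target pixel."""
    if not targets.any():
        raise UndefinedMetricError("no edge pixels anywhere on the map")
    dist = ndimage.distance_transform_edt(~targets) * pixel_size
    vals = dist[sources]
    if convention == CENTER_TO_BOUNDARY:
        vals = np.maximum(vals - 0.5 * pixel_size, 0.0)
    return float(vals.mean())


def fragmentation_degree(map_: BinaryHabitatMap,
                         cfg: MetricsConfig | None = None) -> float:
    """Mean distance of suitable pixels to the nearest habitat edge.

    The edge is the set of matrix pixels (plus NODATA when the range
    boundary counts as edge).  Raises :class:`UndefinedMetricError` when the
    map has no suitable pixel, or no edge at all.
    """
    cfg = cfg or MetricsConfig()
    if not map_.suitable.any():
        raise UndefinedMetricError("no suitable pixels")
    edge = map_.matrix
    if cfg.treat_range_boundary_as_edge:
        edge = edge | ~map_.in_range
    return _mean_distance_to(edge, map_.suitable, map_.pixel_size,
                             cfg.distance_convention)


def isolation_degree(map_: BinaryHabitatMap,
                     cfg: MetricsConfig | None = None) -> float:
    """Mean distance of matrix pixels to the nearest suitable pixel."""
    cfg = cfg or MetricsConfig()
    if not map_.matrix.any():
        raise UndefinedMetricError("no matrix pixels")
    edge = map_.suitable
    if cfg.treat_range_boundary_as_edge:
        edge = edge | ~map_.in_range
    return _mean_distance_to(edge, map_.matrix, map_.pixel_size,
                             cfg.distance_convention)


def _region_mask(map_: BinaryHabitatMap, region: str) -> np.ndarray:
    if region == "MATRIX":
        return map_.matrix
    if region == "SUITABLE":
        return map_.suitable
    raise ValueError(f"unknown region {region!r}")


def hfp_extent(map_: BinaryHabitatMap, hfp: FootprintRaster, region: str,
               cfg: MetricsConfig | None = None) -> float:
    """Proportion of region pixels at or above the footprint threshold."""
    cfg = cfg or MetricsConfig()
    mask = _region_mask(map_, region) & hfp.valid
    if not mask.any():
        raise UndefinedMetricError(f"empty region {region}")
    return float((hfp.grid[mask] >= cfg.hfp_threshold).mean())


def hfp_change(map_: BinaryHabitatMap, hfp_2000: FootprintRaster,
               hfp_2013: FootprintRaster, region: str,
               cfg: MetricsConfig | None = None) -> float:
    """Increase in high-footprint extent between epochs, decreases discarded.

    Cells whose footprint fell between 2000 and 2013 are treated as
    unchanged (their 2000 value is kept), so the result is non-negative.
    """
    cfg = cfg or MetricsConfig()
    mask = _region_mask(map_, region) & hfp_2000.valid & hfp_2013.valid
    if not mask.any():
        raise UndefinedMetricError(f"empty region {region}")
    g2000 = hfp_2000.grid[mask]
    g2013 = np.maximum(hfp_2013.grid[mask], g2000)
    extent_2000 = (g2000 >= cfg.hfp_threshold).mean()
    extent_2013 = (g2013 >= cfg.hfp_threshold).mean()
    return float(extent_2013 - extent_2000)


def proportion_suitable(map_: BinaryHabitatMap) -> float:
    """Share of the in-range area that is suitable habitat."""
    n_in = int(map_.in_range.sum())
    if n_in == 0:
        raise UndefinedMetricError("no in-range pixels")
    return float(map_.suitable.sum() / n_in)


def compute_species_features(map_: BinaryHabitatMap, hfp_2000: FootprintRaster,
                             hfp_2013: FootprintRaster,
                             cfg: MetricsConfig | None = None) -> dict[str, float]:
    """All landscape/pressure metrics for one species as a dict.

    Raises :class:`UndefinedMetricError` if any metric is undefined; callers
    exclude such species rather than imputing.
    """
    cfg = cfg or MetricsConfig()
    return {
        "species_id": map_.species_id,
        "frag_mean_edge_distance": fragmentation_degree(map_, cfg),
        "isolation_mean_distance": isolation_degree(map_, cfg),
        "hfp_extent_matrix": hfp_extent(map_, hfp_2000, "MATRIX", cfg),
        "hfp_extent_patches": hfp_extent(map_, hfp_2000, "SUITABLE", cfg),
        "hfp_change_matrix": hfp_change(map_, hfp_2000, hfp_2013, "MATRIX", cfg),
        "hfp_change_patches": hfp_change(map_, hfp_2000, hfp_2013, "SUITABLE", cfg),
        "prop_suitable": proportion_suitable(map_),
    }


def assemble_features(metrics: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Join per-species metrics with traits, keeping complete cases only.

    Species missing any metric or trait are dropped with a logged reason
    (mirroring exclusion of species without defined habitat suitability).
    """
    merged = metrics.merge(traits, on="species_id", how="inner", validate="1:1")
    unmatched = set(metrics["species_id"]) - set(merged["species_id"])
    for sid in sorted(unmatched):
        logger.info("%s dropped: no trait record", sid)
    complete = merged.dropna()
    for sid in sorted(set(merged["species_id"]) - set(complete["species_id"])):
        logger.info("%s dropped: missing values", sid)
    return complete.reset_index(drop=True)
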