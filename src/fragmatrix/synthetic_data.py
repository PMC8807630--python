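"""Synthetic landscapes, footprint epochs, traits and Red List histories.

Every downstream stage of the pipeline is exercised on data from this module,
so its defaults define the study conditions.  The generators emulate the
statistical structure of the real inputs:

* **suitability rasters** — a thresholded smoothed Gaussian random field
  (a neutral-landscape model).  One parameter (the smoothing length) controls
  patch grain: short lengths give many small habitat blobs, long lengths give
  few large ones.  The threshold is set by quantile so the realised suitable
  fraction tracks the requested habitat proportion.  Medium suitability is
  carved as an erosion band just inside the suitable blobs, with high
  suitability in the blob cores.
* **human-footprint rasters** — a spatially autocorrelated 0-50 integer
  pressure index for epoch 2000, and a 2013 epoch in which a configurable
  fraction of cells increases and a (disjoint) fraction decreases, to
  exercise the downstream rule that discards decreases.
* **Red List histories** — each species receives a high-risk transition with
  probability given by a logistic model on its standardised features; the
  history is then a (first, last) category pair consistent with that label,
  plus optional cosmetic intermediate assessments.

A global seed drives per-species substreams, so adding species does not
reshuffle earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .grids import (HIGH, MEDIUM, UNSUITABLE, FootprintRaster,
                    SuitabilityRaster, write_raster)
from .risk_transitions import CATEGORY_ORDER, RedListHistory

logger = logging.getLogger(__name__)

REALMS = ("Afrotropical", "Australasian", "Indomalayan", "Nearctic",
          "Neotropical", "Palearctic")
DIETS = ("vertebrate carnivore", "invertebrate carnivore", "omnivore", "herbivore")
ORDERS = ("Rodentia", "Chiroptera", "Soricomorpha", "Primates",
          "Carnivora", "Artiodactyla", "Diprotodontia", "Lagomorpha")

#: numeric landscape/pressure predictors (traits added separately)
LANDSCAPE_COLUMNS = (
    "frag_mean_edge_distance", "isolation_mean_distance",
    "hfp_extent_matrix", "hfp_extent_patches",
    "hfp_change_matrix", "hfp_change_patches", "prop_suitable",
)


def default_risk_link() -> dict[str, float]:
    """Logistic coefficients on standardised features.

    The magnitudes encode the effect hierarchy fragmentation > matrix
    condition > isolation; the fragmentation coefficient is negative because
    the feature is the mean distance to habitat edge, which is inversely
    coded (large distance = little fragmentation = low risk).  The intercept
    puts the marginal high-risk rate near one third.
    """
    return {
        "intercept": -0.9,
        "frag_mean_edge_distance": -1.0,
        "hfp_extent_matrix": 0.6,
        "isolation_mean_distance": 0.3,
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``fragmentation_level`` is the autocorrelation (smoothing) length of the
    landscape field in pixels; smaller values produce finer-grained, more
    fragmented habitat.  ``footprint_increase_rate`` / ``decrease_rate`` are
    the disjoint fractions of cells whose pressure index rises / falls
    between epochs.  ``matrix_extent_beta`` shapes the Beta distribution of
    the matrix-condition feature when features are sampled directly (without
    rasters).  ``risk_link_fn``, when given, overrides the coefficient-based
    logistic link and must map a feature table to a logit array.
    """

    grid_size: int = 96
    pixel_size: float = 1.0
    n_species: int = 400
    habitat_proportion: float = 0.4
    fragmentation_level: float = 4.0
    medium_band: float = 1.5
    footprint_base_intensity: float = 8.0
    footprint_increase_rate: float = 0.25
    footprint_decrease_rate: float = 0.05
    footprint_autocorr: float = 6.0
    risk_link_coefficients: dict[str, float] = field(default_factory=default_risk_link)
    risk_link_fn: Callable[[pd.DataFrame], np.ndarray] | None = None
    matrix_extent_beta: tuple[float, float] = (2.0, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.habitat_proportion <= 1.0:
            raise ValueError("habitat_proportion must lie in [0, 1]")
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if self.footprint_increase_rate + self.footprint_decrease_rate > 1.0:
            raise ValueError("increase and decrease fractions must sum to <= 1")


def _rng(config: SimulationConfig, stream: int, index: int = 0) -> np.random.Generator:
    """Substream generator: independent of n_species, stable per species."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream, index)))


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    return noise


def generate_suitability_raster(config: SimulationConfig,
                                species_index: int) -> SuitabilityRaster:
    """Neutral-landscape suitability raster for one species.

    The smoothed field is thresholded at the (1 - habitat_proportion)
    quantile, so the realised suitable fraction matches the target up to
    pixel rounding.  Suitable pixels within ``medium_band`` (pixels,
    Euclidean) of the matrix become MEDIUM; deeper pixels are HIGH.
    """
    rng = _rng(config, stream=0, index=species_index)
    size, p = config.grid_size, config.habitat_proportion
    field_ = _smooth_field(rng, size, config.fragmentation_level)

    degenerate = p in (0.0, 1.0)
    if p == 0.0:
        grid = np.full((size, size), UNSUITABLE, dtype=np.uint8)
    elif p == 1.0:
        grid = np.full((size, size), HIGH, dtype=np.uint8)
    else:
        thresh = np.quantile(field_, 1.0 - p)
        suitable = field_ >= thresh
        grid = np.where(suitable, HIGH, UNSUITABLE).astype(np.uint8)
        # erosion band: suitable pixels near the matrix are secondary habitat
        depth = ndimage.distance_transform_edt(suitable)
        grid[suitable & (depth <= config.medium_band)] = MEDIUM
    if degenerate:
        logger.warning("species %d: degenerate landscape (habitat_proportion=%g)",
                       species_index, p)
    return SuitabilityRaster(grid, pixel_size=config.pixel_size,
                             species_id=f"sp{species_index:04d}",
                             degenerate=degenerate)


def generate_footprint_rasters(config: SimulationConfig,
                               species_index: int = 0,
                               ) -> tuple[FootprintRaster, FootprintRaster]:
    """Autocorrelated footprint grids for epochs 2000 and 2013.

    The 2000 epoch is a smoothed field centred on the base intensity with
    spread proportional to it (a zero base intensity therefore yields a
    pressure-free landscape).  Between epochs a fraction
    ``footprint_increase_rate`` of cells gains pressure and a disjoint
    fraction ``footprint_decrease_rate`` loses pressure; both epochs are
    clamped to the 0-50 index range.
    """
    rng = _rng(config, stream=1, index=species_index)
    size = config.grid_size
    base = config.footprint_base_intensity
    field_ = _smooth_field(rng, size, config.footprint_autocorr)
    sd = field_.std()
    scale = (base / 2.0) / sd if sd > 0 else 0.0
    hfp2000 = np.clip(np.rint(base + scale * field_), 0, 50).astype(np.int16)

    u = rng.random((size, size))
    inc = u < config.footprint_increase_rate
    dec = (~inc) & (u < config.footprint_increase_rate + config.footprint_decrease_rate)
    delta = np.zeros((size, size), dtype=np.int16)
    delta[inc] = rng.poisson(3.0, inc.sum()) + 1
    delta[dec] = -(rng.poisson(2.0, dec.sum()) + 1)
    hfp2013 = np.clip(hfp2000 + delta, 0, 50).astype(np.int16)

    return (FootprintRaster(hfp2000, epoch=2000, pixel_size=config.pixel_size),
            FootprintRaster(hfp2013, epoch=2013, pixel_size=config.pixel_size))


def generate_traits(config: SimulationConfig) -> pd.DataFrame:
    """Life-history trait table: body mass, diet, weaning age, gestation, order, realm."""
    rows = []
    for i in range(config.n_species):
        rng = _rng(config, stream=3, index=i)
        rows.append({
            "species_id": f"sp{i:04d}",
            "body_mass": float(np.exp(rng.normal(5.5, 2.0))),       # grams
            "diet": DIETS[rng.integers(len(DIETS))],
            "weaning_age": float(np.exp(rng.normal(4.0, 0.8))),     # days
            "gestation_length": float(np.exp(rng.normal(4.6, 0.6))),  # days
            "order": ORDERS[rng.integers(len(ORDERS))],
            "realm": REALMS[rng.integers(len(REALMS))],
        })
    return pd.DataFrame(rows)


def sample_feature_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample the per-species predictor set directly (no rasters).

    Used for model-scale experiments where thousands of species are needed:
    landscape metrics are drawn from distributions matching what the raster
    pipeline produces (right-skewed distances, Beta-distributed proportions)
    rather than being measured on generated grids.
    """
    traits = generate_traits(config)
    a, b = config.matrix_extent_beta
    rows = []
    for i in range(config.n_species):
        rng = _rng(config, stream=4, index=i)
        rows.append({
            "species_id": f"sp{i:04d}",
            "frag_mean_edge_distance": float(np.exp(rng.normal(0.8, 0.7))),
            "isolation_mean_distance": float(np.exp(rng.normal(1.0, 0.7))),
            "hfp_extent_matrix": float(rng.beta(a, b)),
            "hfp_extent_patches": float(rng.beta(1.5, 1.5)),
            "hfp_change_matrix": float(0.3 * rng.beta(1.2, 6.0)),
            "hfp_change_patches": float(0.3 * rng.beta(1.2, 6.0)),
            "prop_suitable": float(rng.beta(2.0, 2.0)),
        })
    return pd.DataFrame(rows).merge(traits, on="species_id")


def high_risk_probabilities(config: SimulationConfig,
                            features: pd.DataFrame) -> np.ndarray:
    """Per-species probability of a high-risk transition under the link.

    Coefficient keys name feature columns; each column is z-scored across
    the provided table before entering the linear predictor.  A custom
    ``risk_link_fn`` overrides the coefficients entirely.
    """
    if config.risk_link_fn is not None:
        logit = np.asarray(config.risk_link_fn(features), dtype=float)
    else:
        coefs = config.risk_link_coefficients
        logit = np.full(len(features), float(coefs.get("intercept", 0.0)))
        for name, beta in coefs.items():
            if name == "intercept":
                continue
            col = features[name].to_numpy(dtype=float)
            sd = col.std()
            z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
            logit += beta * z
    return expit(logit)


def _history_for_label(rng: np.random.Generator, species_id: str,
                       high_risk: bool) -> RedListHistory:
    """Draw a (first, last) category pair consistent with the label."""
    threatened = CATEGORY_ORDER[1:]  # NT..CR
    if high_risk:
        if rng.random() < 0.7:   # retained NT or worse
            first = last = threatened[rng.integers(len(threatened))]
        else:                    # upward move
            fi = rng.integers(0, len(CATEGORY_ORDER) - 1)
            li = rng.integers(fi + 1, len(CATEGORY_ORDER))
            first, last = CATEGORY_ORDER[fi], CATEGORY_ORDER[li]
    else:
        if rng.random() < 0.6:   # retained Least Concern
            first = last = "LC"
        else:                    # downward move
            fi = rng.integers(1, len(CATEGORY_ORDER))
            li = rng.integers(0, fi)
            first, last = CATEGORY_ORDER[fi], CATEGORY_ORDER[li]
    first_year = int(1996 + rng.integers(0, 4))
    last_year = int(2020 - rng.integers(0, 4))
    assessments = [(first_year, first)]
    if rng.random() < 0.3 and last_year - first_year > 2:
        mid_year = int(rng.integers(first_year + 1, last_year))
        assessments.append((mid_year, first))  # cosmetic; classification uses first/last
    assessments.append((last_year, last))
    return RedListHistory(species_id, assessments)


def generate_redlist_histories(config: SimulationConfig,
                               features: pd.DataFrame) -> list[RedListHistory]:
    """Category histories whose high-risk rate follows the logistic link."""
    probs = high_risk_probabilities(config, features)
    histories = []
    for i, (sid, p) in enumerate(zip(features["species_id"], probs)):
        rng = _rng(config, stream=2, index=i)
        histories.append(_history_for_label(rng, str(sid), rng.random() < p))
    return histories


def histories_to_frame(histories: Sequence[RedListHistory]) -> pd.DataFrame:
    rows = [{"species_id": h.species_id, "year": y, "category": c}
            for h in histories for y, c in h.assessments]
    return pd.DataFrame(rows)


def write_dataset(config: SimulationConfig, outdir: str | Path) -> None:
    """Materialise a full dataset: rasters as TIFF, tables as CSV.

    Histories are drawn from the directly sampled feature table; for
    histories consistent with metrics measured on the written rasters use
    the pipeline module's raster study.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traits = generate_traits(config)
    features = sample_feature_table(config)
    for i in range(config.n_species):
        sid = f"sp{i:04d}"
        rast = generate_suitability_raster(config, i)
        write_raster(outdir / f"{sid}_suitability.tif", rast.grid)
        h2000, h2013 = generate_footprint_rasters(config, i)
        write_raster(outdir / f"{sid}_hfp2000.tif", h2000.grid)
        write_raster(outdir / f"{sid}_hfp2013.tif", h2013.grid)
    traits.to_csv(outdir / "traits.csv", index=False)
    histories_to_frame(generate_redlist_histories(config, features)).to_csv(
        outdir / "histories.csv", index=False)
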