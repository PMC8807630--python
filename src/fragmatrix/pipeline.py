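"""End-to-end synthetic studies: landscapes -> features -> labels -> model.

Two entry points:

* :func:`run_raster_study` exercises the full raster path — generate
  suitability and footprint grids per species, clean and binarize, measure
  the landscape metrics, draw Red List histories from the logistic link on
  the measured features, classify transitions, and fit the forest.
* :func:`run_feature_study` skips the rasters and samples the feature table
  directly, for experiments that need thousands of species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .extinction_model import (ModelFit, PerformanceMetrics,
                               build_feature_table, evaluate, importance,
                               tune_and_fit)
from .landscape_metrics import (MetricsConfig, UndefinedMetricError,
                                assemble_features, compute_species_features)
from .raster_prep import binarize, clean_small_groups
from .risk_transitions import classify_histories
from .synthetic_data import (SimulationConfig, generate_footprint_rasters,
                             generate_redlist_histories,
                             generate_suitability_raster, generate_traits,
                             sample_feature_table)

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    features: pd.DataFrame
    transitions: pd.DataFrame
    table: pd.DataFrame
    fit: ModelFit
    importance: pd.DataFrame
    performance: PerformanceMetrics

    @property
    def high_risk_rate(self) -> float:
        return float((self.table["label"] == "HIGH_RISK").mean())


def compute_feature_table(config: SimulationConfig,
                          scenario: str = "main",
                          metrics_cfg: MetricsConfig | None = None,
                          clean: bool = True) -> pd.DataFrame:
    """Measure the per-species predictor set on generated rasters."""
    metrics_cfg = metrics_cfg or MetricsConfig()
    rows = []
    for i in range(config.n_species):
        rast = generate_suitability_raster(config, i)
        if clean:
            rast = clean_small_groups(rast)
        bmap = binarize(rast, scenario)
        h2000, h2013 = generate_footprint_rasters(config, i)
        try:
            rows.append(compute_species_features(bmap, h2000, h2013, metrics_cfg))
        except UndefinedMetricError as err:
            logger.info("%s excluded: %s", rast.species_id, err)
    metrics = pd.DataFrame(rows)
    return assemble_features(metrics, generate_traits(config))


def _fit_study(config: SimulationConfig, features: pd.DataFrame, seed: int,
               **fit_kwargs) -> StudyResult:
    histories = generate_redlist_histories(config, features)
    transitions = classify_histories(histories)
    table = build_feature_table(features, transitions)
    fit = tune_and_fit(table, seed=seed, **fit_kwargs)
    return StudyResult(features=features, transitions=transitions, table=table,
                       fit=fit, importance=importance(fit),
                       performance=evaluate(fit))


def run_raster_study(config: SimulationConfig, seed: int | None = None,
                     scenario: str = "main",
                     metrics_cfg: MetricsConfig | None = None,
                     **fit_kwargs) -> StudyResult:
    """Full raster-based study under one configuration."""
    features = compute_feature_table(config, scenario, metrics_cfg)
    return _fit_study(config, features,
                      seed=config.seed if seed is None else seed, **fit_kwargs)


def run_feature_study(config: SimulationConfig, seed: int | None = None,
                      **fit_kwargs) -> StudyResult:
    """Study on a directly sampled feature table (no rasters)."""
    features = sample_feature_table(config)
    return _fit_study(config, features,
                      seed=config.seed if seed is None else seed, **fit_kwargs)
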