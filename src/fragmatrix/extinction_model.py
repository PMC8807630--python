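"""Random-Forest classification of extinction-risk transitions.

The model predicts the binary low-risk / high-risk transition label from the
landscape, pressure and life-history predictors.  The number of trees and
the number of predictors sampled at each split are tuned by three repeats of
stratified 10-fold cross-validation on a 75% training partition; the 25%
holdout is touched only for final evaluation.  Predictor importance is the
mean decrease in classification accuracy (MDA) under random permutation of
one predictor, rescaled to the model improvement ratio MIR = I_n / I_max so
the most important predictor scores exactly 1.  Partial-dependence curves
sweep one predictor over its observed range while all other predictors keep
their observed values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score
from sklearn.model_selection import (GridSearchCV, RepeatedStratifiedKFold,
                                     train_test_split)
from statsmodels.nonparametric.smoothers_lowess import lowess

from .risk_transitions import EXCLUDED, HIGH_RISK

logger = logging.getLogger(__name__)

NUMERIC_PREDICTORS = (
    "frag_mean_edge_distance", "isolation_mean_distance",
    "hfp_extent_matrix", "hfp_extent_patches",
    "hfp_change_matrix", "hfp_change_patches", "prop_suitable",
    "body_mass", "weaning_age", "gestation_length",
)
CATEGORICAL_PREDICTORS = ("realm", "diet", "order")
PREDICTORS = NUMERIC_PREDICTORS + CATEGORICAL_PREDICTORS


class UndefinedMetricSignal(ValueError):
    """A performance metric is undefined (e.g. a class absent from the holdout)."""


def build_feature_table(features: pd.DataFrame,
                        transitions: pd.DataFrame) -> pd.DataFrame:
    """Join predictors with transition labels into a model-ready table.

    Excluded species and incomplete rows are dropped; categorical predictors
    become pandas categories.  The result carries a binary ``label`` column
    (HIGH_RISK / LOW_RISK).
    """
    lab = transitions.loc[transitions["label"] != EXCLUDED, ["species_id", "label"]]
    table = features.merge(lab, on="species_id", how="inner", validate="1:1")
    table = table.dropna(subset=list(PREDICTORS) + ["label"]).reset_index(drop=True)
    for col in CATEGORICAL_PREDICTORS:
        table[col] = table[col].astype("category")
    if table["label"].nunique() < 2:
        raise ValueError("feature table must contain both transition classes")
    return table


def _encode(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Predictor matrix (categoricals as integer codes) and 0/1 label vector."""
    X = table[list(PREDICTORS)].copy()
    for col in CATEGORICAL_PREDICTORS:
        X[col] = table[col].cat.codes
    y = (table["label"] == HIGH_RISK).astype(int).to_numpy()
    return X, y


def default_mtry_grid(n_predictors: int) -> tuple[int, ...]:
    """Candidate numbers of predictors per split: 2..ceil(p/2) plus ceil(sqrt(p))."""
    grid = set(range(2, math.ceil(n_predictors / 2) + 1))
    grid.add(math.ceil(math.sqrt(n_predictors)))
    return tuple(sorted(grid))


@dataclass
class ModelFit:
    """A tuned forest with its data partitions and tuning record."""

    model: RandomForestClassifier
    feature_names: list[str]
    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray
    best_params: dict
    cv_accuracy: float
    seed: int


@dataclass
class PerformanceMetrics:
    """Holdout (or CV) classification performance; tss = sens + spec - 1."""

    accuracy: float
    sensitivity: float
    specificity: float
    tss: float = field(init=False)

    def __post_init__(self) -> None:
        self.tss = self.sensitivity + self.specificity - 1.0


@dataclass
class PartialDependenceCurve:
    predictor: str
    grid: np.ndarray
    probability: np.ndarray
    smoothed: np.ndarray | None = None


def tune_and_fit(table: pd.DataFrame, seed: int,
                 trees_grid: tuple[int, ...] = (500, 1000, 2000),
                 mtry_grid: tuple[int, ...] | None = None,
                 cv_folds: int = 10, cv_repeats: int = 3,
                 test_size: float = 0.25) -> ModelFit:
    """Tune and fit the forest on a stratified 75/25 split.

    The grid over {number of trees} x {predictors per split} is scored by
    repeated stratified k-fold CV accuracy on the training partition only.
    Identical seed and table give identical hyperparameters and predictions.
    """
    X, y = _encode(table)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y)) * (1 - test_size) < cv_folds:
        # each stratified training fold needs at least one member per class
        raise ValueError("too few minority-class cases for the CV folds")
    if mtry_grid is None:
        mtry_grid = default_mtry_grid(X.shape[1])

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed)
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats,
                                 random_state=seed)
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        param_grid={"n_estimators": list(trees_grid),
                    "max_features": list(mtry_grid)},
        scoring="accuracy", cv=cv, refit=True)
    search.fit(X_tr, y_tr)
    logger.info("tuned forest: %s (CV accuracy %.3f)",
                search.best_params_, search.best_score_)
    return ModelFit(model=search.best_estimator_,
                    feature_names=list(X.columns),
                    X_train=X_tr, y_train=y_tr, X_test=X_te, y_test=y_te,
                    best_params=dict(search.best_params_),
                    cv_accuracy=float(search.best_score_), seed=seed)


def mir_scores(mda: np.ndarray) -> np.ndarray:
    """Model improvement ratio: I_n / I_max on clamped MDA values.

    Negative MDA (permutation noise) is clamped to zero first, so the result
    lies in [0, 1] with the top predictor at exactly 1.  When every MDA is
    non-positive the ratio is undefined and all scores are 0.
    """
    clamped = np.clip(np.asarray(mda, dtype=float), 0.0, None)
    top = clamped.max()
    if top <= 0:
        logger.warning("all permutation importances <= 0; MIR undefined, set to 0")
        return np.zeros_like(clamped)
    return clamped / top


def importance(fit: ModelFit, n_repeats: int = 10) -> pd.DataFrame:
    """Permutation importance (MDA) and its MIR rescaling.

    MDA is the drop in holdout accuracy when one predictor is permuted,
    averaged over repetitions; ``mda_se`` is the Monte-Carlo standard error
    of that mean.  Columns: predictor, mda_raw, mda_se, mda, mir.
    """
    perm = permutation_importance(fit.model, fit.X_test, fit.y_test,
                                  scoring="accuracy", n_repeats=n_repeats,
                                  random_state=fit.seed)
    raw = perm.importances_mean
    se = perm.importances_std / np.sqrt(n_repeats)
    out = pd.DataFrame({"predictor": fit.feature_names, "mda_raw": raw,
                        "mda_se": se, "mda": np.clip(raw, 0.0, None),
                        "mir": mir_scores(raw)})
    return out.sort_values("mir", ascending=False).reset_index(drop=True)


def evaluate(fit: ModelFit) -> PerformanceMetrics:
    """Holdout confusion-matrix metrics (high-risk is the positive class)."""
    y_pred = fit.model.predict(fit.X_test)
    y_true = fit.y_test
    if (y_true == 1).sum() == 0 or (y_true == 0).sum() == 0:
        raise UndefinedMetricSignal("holdout is missing a class")
    sens = float((y_pred[y_true == 1] == 1).mean())
    spec = float((y_pred[y_true == 0] == 0).mean())
    return PerformanceMetrics(accuracy=float(accuracy_score(y_true, y_pred)),
                              sensitivity=sens, specificity=spec)


def partial_dependence(fit: ModelFit, predictor: str, grid_points: int = 50,
                       loess_span: float = 0.75) -> PartialDependenceCurve:
    """Partial dependence of the high-risk probability on one predictor.

    For each grid value the predictor column is set to that value in every
    training row and the predicted high-risk probabilities are averaged.
    Categorical predictors get per-level dependence instead of a curve.
    The LOESS overlay is presentation-only smoothing of the curve.
    """
    if predictor not in fit.feature_names:
        raise KeyError(predictor)
    col = fit.X_train[predictor]
    if predictor in CATEGORICAL_PREDICTORS:
        grid = np.sort(col.unique()).astype(float)
    else:
        grid = np.linspace(float(col.min()), float(col.max()), grid_points)
    probs = np.empty(grid.size)
    X_mod = fit.X_train.copy()
    for i, v in enumerate(grid):
        X_mod[predictor] = v
        probs[i] = float(fit.model.predict_proba(X_mod)[:, 1].mean())
    smoothed = None
    if predictor not in CATEGORICAL_PREDICTORS and grid.size >= 5:
        smoothed = lowess(probs, grid, frac=loess_span, return_sorted=False)
    return PartialDependenceCurve(predictor=predictor, grid=grid,
                                  probability=probs, smoothed=smoothed)
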