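"""Matrix-quality strata and the stratified importance comparison.

The matrix condition — the share of a species' matrix under high human
footprint — is discretized into a low-quality and a high-quality stratum at
the point where its partial-dependence curve crosses the marginal high-risk
rate: species above the crossing (where the matrix condition pushes risk up)
form the low-quality stratum, species below the complementary cutoff form
the high-quality stratum.  Separate forests are then fitted per stratum and
the relative importance (MIR) of fragmentation and isolation is compared
between them, together with one-sided rank-sum tests and Cohen's d for the
difference in those variables between low-risk and high-risk species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .extinction_model import (ModelFit, PartialDependenceCurve,
                               PerformanceMetrics, evaluate, importance,
                               tune_and_fit)
from .risk_transitions import HIGH_RISK, LOW_RISK

logger = logging.getLogger(__name__)

MIN_STRATUM_N = 40


class NoStrataSignal(ValueError):
    """The partial-dependence curve never crosses the baseline rate."""


@dataclass
class QualityStrata:
    """Cutoffs defining the two matrix-quality strata.

    Low quality: matrix-condition values ABOVE ``low_quality_cutoff``.
    High quality: values BELOW ``high_quality_cutoff`` (= 1 - low cutoff).
    ``crossing_index`` and ``baseline_rate`` record the derivation.
    """

    low_quality_cutoff: float
    high_quality_cutoff: float
    baseline_rate: float = float("nan")
    crossing_index: int = -1

    def __post_init__(self) -> None:
        if not self.high_quality_cutoff < self.low_quality_cutoff:
            raise ValueError("high-quality cutoff must lie below low-quality cutoff")


@dataclass
class GroupComparison:
    p_value: float
    cohens_d: float


@dataclass
class StratumResult:
    name: str
    n_low_risk: int
    n_high_risk: int
    fit: ModelFit
    importance: pd.DataFrame
    performance: PerformanceMetrics
    comparisons: dict[str, GroupComparison]


@dataclass
class StratifiedComparison:
    strata: QualityStrata
    low_quality: StratumResult
    high_quality: StratumResult
    mir_percent_change: dict[str, dict[str, float]] = dc_field(default_factory=dict)


def derive_cutoffs(pd_curve: PartialDependenceCurve,
                   baseline_rate: float) -> QualityStrata:
    """Locate the matrix-condition value where its effect turns positive.

    The low-quality cutoff is the smallest grid value at which the
    partial-dependence probability first exceeds the baseline high-risk rate
    and stays above it through the end of the grid; the high-quality cutoff
    is its complement (the condition is a proportion in [0, 1]).  A curve
    that never crosses, or that sits above baseline everywhere, yields
    :class:`NoStrataSignal`.
    """
    above = pd_curve.probability > baseline_rate
    if not above[-1] or above.all() or not above.any():
        raise NoStrataSignal(
            "partial dependence does not cross the baseline from below")
    last_not_above = int(np.flatnonzero(~above).max())
    idx = last_not_above + 1
    t = float(pd_curve.grid[idx])
    if t <= 0.5:
        # complementary tails would overlap; no meaningful quality split
        raise NoStrataSignal(
            f"crossing at {t:.3f} is not in the upper half of the range")
    return QualityStrata(low_quality_cutoff=t, high_quality_cutoff=1.0 - t,
                         baseline_rate=float(baseline_rate), crossing_index=idx)


def compare_groups(values_low_risk: np.ndarray,
                   values_high_risk: np.ndarray) -> GroupComparison:
    """One-sided rank-sum test and Cohen's d between risk classes.

    The alternative is that high-risk species have larger values.  Cohen's d
    is (mean_high - mean_low) / pooled SD with unbiased variances; all-tied
    samples give p = 1 with a warning.
    """
    lo = np.asarray(values_low_risk, dtype=float)
    hi = np.asarray(values_high_risk, dtype=float)
    if lo.size == 0 or hi.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([lo, hi])) == 0:
        logger.warning("all values tied; rank-sum p-value set to 1")
        return GroupComparison(p_value=1.0, cohens_d=0.0)
    method = "exact" if (lo.size <= 50 and hi.size <= 50) else "asymptotic"
    try:
        res = stats.mannwhitneyu(hi, lo, alternative="greater", method=method)
    except ValueError:  # exact method rejects ties
        res = stats.mannwhitneyu(hi, lo, alternative="greater",
                                 method="asymptotic")
    d = _cohens_d(lo, hi)
    return GroupComparison(p_value=float(res.pvalue), cohens_d=d)


def _cohens_d(lo: np.ndarray, hi: np.ndarray) -> float:
    n1, n2 = lo.size, hi.size
    if n1 < 2 or n2 < 2:
        return float("nan")
    pooled = np.sqrt(((n1 - 1) * lo.var(ddof=1) + (n2 - 1) * hi.var(ddof=1))
                     / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0
    return float((hi.mean() - lo.mean()) / pooled)


def _fit_stratum(name: str, table: pd.DataFrame, seed: int,
                 focal: dict[str, np.ndarray], **fit_kwargs) -> StratumResult:
    counts = table["label"].value_counts()
    n_low = int(counts.get(LOW_RISK, 0))
    n_high = int(counts.get(HIGH_RISK, 0))
    if n_low == 0 or n_high == 0:
        raise ValueError(f"{name} stratum has a single class")
    if n_low + n_high < MIN_STRATUM_N:
        logger.warning("%s stratum has only %d species", name, n_low + n_high)
    fit = tune_and_fit(table, seed=seed, **fit_kwargs)
    comparisons = {}
    is_high = table["label"] == HIGH_RISK
    for var, values in focal.items():
        comparisons[var] = compare_groups(values[~is_high], values[is_high])
    return StratumResult(name=name, n_low_risk=n_low, n_high_risk=n_high,
                         fit=fit, importance=importance(fit),
                         performance=evaluate(fit), comparisons=comparisons)


def stratify_and_refit(table: pd.DataFrame, strata: QualityStrata, seed: int,
                       **fit_kwargs) -> StratifiedComparison:
    """Fit per-stratum forests and compare fragmentation / isolation effects.

    The focal rank-sum comparisons use the DEGREE of fragmentation (the
    negated mean edge distance, so larger = more fragmented) and the degree
    of isolation (mean matrix distance as-is), matching the directional
    alternative that high-risk species are more fragmented / more isolated.
    Percent change in MIR between strata is reported under two conventions:
    relative to the low-quality stratum's MIR, and relative to the mean of
    the two (symmetric), because a drop can exceed the smaller value.
    """
    cond = table["hfp_extent_matrix"]
    low_tbl = table[cond > strata.low_quality_cutoff].reset_index(drop=True)
    high_tbl = table[cond < strata.high_quality_cutoff].reset_index(drop=True)

    def focal(t: pd.DataFrame) -> dict[str, np.ndarray]:
        return {
            "fragmentation": -t["frag_mean_edge_distance"].to_numpy(float),
            "isolation": t["isolation_mean_distance"].to_numpy(float),
        }

    low = _fit_stratum("low_quality", low_tbl, seed, focal(low_tbl), **fit_kwargs)
    high = _fit_stratum("high_quality", high_tbl, seed, focal(high_tbl), **fit_kwargs)

    pct = {}
    for var in ("frag_mean_edge_distance", "isolation_mean_distance",
                "hfp_extent_matrix"):
        m_low = _mir_of(low.importance, var)
        m_high = _mir_of(high.importance, var)
        rel = 100.0 * (m_low - m_high) / m_low if m_low else float("nan")
        mean = (m_low + m_high) / 2.0
        sym = 100.0 * (m_low - m_high) / mean if mean else float("nan")
        pct[var] = {"mir_low": m_low, "mir_high": m_high,
                    "pct_change_rel_low": rel, "pct_change_symmetric": sym}
    return StratifiedComparison(strata=strata, low_quality=low,
                                high_quality=high, mir_percent_change=pct)


def _mir_of(imp: pd.DataFrame, predictor: str) -> float:
    row = imp.loc[imp["predictor"] == predictor, "mir"]
    return float(row.iloc[0]) if len(row) else float("nan")
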