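"""Classify Red List category histories into low-risk / high-risk transitions.

A species' trajectory through IUCN Red List categories between 1996 and 2020 is
collapsed to a binary label.  With the severity order LC < NT < VU < EN < CR:

* **low-risk** — the species retained Least Concern (first = last = LC), or it
  moved from a higher category of threat to a lower one (last < first);
* **high-risk** — the species retained a threatened or Near Threatened
  category (first = last in {NT, VU, EN, CR}), or it moved from a lower
  category to a higher one (last > first).

Species whose final in-window assessment is Data Deficient, Extinct, Extinct
in the Wild, or Not Evaluated are excluded, unless their earlier in-window
assessments already express a defined transition, in which case that
transition stands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: modelled categories in increasing severity
CATEGORY_ORDER = ("LC", "NT", "VU", "EN", "CR")
SEVERITY = {c: i for i, c in enumerate(CATEGORY_ORDER)}
#: categories that trigger exclusion when they close the history
EXCLUSION_CATEGORIES = {"DD": "data deficient", "EX": "extinct",
                        "EW": "extinct in the wild", "NE": "not evaluated"}
ALL_CATEGORIES = set(CATEGORY_ORDER) | set(EXCLUSION_CATEGORIES)

LOW_RISK = "LOW_RISK"
HIGH_RISK = "HIGH_RISK"
EXCLUDED = "EXCLUDED"

FIRST_LAST = "first_last"
LAST_TWO = "last_two"

STUDY_WINDOW = (1996, 2020)


@dataclass
class RedListHistory:
    """Ordered assessment history ``[(year, category), ...]`` for one species."""

    species_id: str
    assessments: list[tuple[int, str]]

    def __post_init__(self) -> None:
        if not self.assessments:
            raise ValueError(f"{self.species_id}: empty assessment history")
        years = [y for y, _ in self.assessments]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"{self.species_id}: years must strictly increase")
        bad = {c for _, c in self.assessments} - ALL_CATEGORIES
        if bad:
            raise ValueError(f"{self.species_id}: unknown categories {bad}")

    @property
    def last_category(self) -> str:
        return self.assessments[-1][1]

    def modelled(self) -> list[tuple[int, str]]:
        """Assessments restricted to the five modelled categories."""
        return [(y, c) for y, c in self.assessments if c in SEVERITY]


@dataclass
class RiskTransition:
    species_id: str
    label: str
    basis: tuple[str, str] | None = None
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if (self.label == EXCLUDED) != bool(self.exclusion_reason):
            raise ValueError("label EXCLUDED iff exclusion_reason non-empty")


def _label_pair(first: str, last: str) -> str:
    """Binary label for a (first, last) pair of modelled categories."""
    f, l = SEVERITY[first], SEVERITY[last]
    if l < f or (f == l == SEVERITY["LC"]):
        return LOW_RISK
    return HIGH_RISK


def _select_pair(modelled: Sequence[tuple[int, str]], mode: str) -> tuple[str, str]:
    cats = [c for _, c in modelled]
    if mode == FIRST_LAST:
        return cats[0], cats[-1]
    if mode == LAST_TWO:
        return cats[-2] if len(cats) >= 2 else cats[-1], cats[-1]
    raise ValueError(f"unknown mode {mode!r}")


def classify_transition(history: RedListHistory, mode: str = FIRST_LAST) -> RiskTransition:
    """Classify a history whose final assessment is a modelled category.

    ``mode`` selects which assessments define the (first, last) pair:
    the first and last in the window, or the last two.
    """
    excluded = apply_exclusions(history)
    if excluded is not None:
        return excluded
    modelled = history.modelled()
    first, last = _select_pair(modelled, mode)
    return RiskTransition(history.species_id, _label_pair(first, last),
                          basis=(first, last))


def apply_exclusions(history: RedListHistory) -> RiskTransition | None:
    """Return an EXCLUDED (or rescued) transition, or None to pass through.

    Exclusion applies when the last in-window category is DD, EX, EW or NE —
    unless the earlier modelled assessments already express a defined
    transition (which requires at least two modelled assessments), in which
    case that transition is returned.
    """
    last = history.last_category
    if last in SEVERITY:
        return None
    reason = EXCLUSION_CATEGORIES[last]
    modelled = history.modelled()
    if len(modelled) >= 2:
        first_c, last_c = modelled[0][1], modelled[-1][1]
        return RiskTransition(history.species_id, _label_pair(first_c, last_c),
                              basis=(first_c, last_c))
    return RiskTransition(history.species_id, EXCLUDED, exclusion_reason=reason)


def classify_histories(histories: Iterable[RedListHistory],
                       mode: str = FIRST_LAST) -> pd.DataFrame:
    """Classify many histories; one row per species.

    Columns: species_id, label, first, last, exclusion_reason.
    """
    rows = []
    for h in histories:
        t = classify_transition(h, mode=mode)
        if t.label == EXCLUDED:
            logger.info("%s excluded: %s", t.species_id, t.exclusion_reason)
        rows.append({
            "species_id": t.species_id,
            "label": t.label,
            "first": t.basis[0] if t.basis else "",
            "last": t.basis[1] if t.basis else "",
            "exclusion_reason": t.exclusion_reason,
        })
    return pd.DataFrame(rows)


def histories_from_frame(df: pd.DataFrame) -> list[RedListHistory]:
    """Build histories from a long table (species_id, year, category)."""
    out = []
    for sid, grp in df.groupby("species_id", sort=True):
        grp = grp.sort_values("year")
        out.append(RedListHistory(str(sid),
                                  list(zip(grp["year"].astype(int), grp["category"]))))
    return out
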