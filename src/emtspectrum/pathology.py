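"""Weighted histopathology scoring of specimen composition tables.

A specimen's H&E section is scored for the relative percentage of six
histological categories — normal (non-neoplastic), PanIN,
well-/moderately-/poorly-differentiated PDAC, and necrosis. A fixed weight
is added whenever a category (or aggregate) exceeds its threshold, all
thresholds strict: normal > 5% adds 1, PanIN > 30% adds 2, well+moderate
PDAC > 30% adds 4, poorly-differentiated PDAC > 5% adds 5, necrosis > 5%
adds 6; the weighted pathology score is the sum (maximum 18 under the
defaults). Whether poorly-differentiated PDAC also counts toward the
PDAC > 30% aggregate is configurable; the default excludes it, since that
category carries its own rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

CATEGORIES = (
    "normal", "panin", "pdac_well", "pdac_moderate", "pdac_poor", "necrosis",
)


@dataclass(frozen=True)
class PathologyRule:
    """Add ``weight`` iff the summed percentage over ``categories`` is
    strictly greater than ``threshold``."""

    categories: tuple[str, ...]
    threshold: float
    weight: int

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 100:
            raise ValueError("threshold must be in (0, 100)")
        if self.weight <= 0:
            raise ValueError("weight must be a positive integer")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")


def default_rules(include_poor_in_pdac: bool = False) -> tuple[PathologyRule, ...]:
    pdac = ("pdac_well", "pdac_moderate") + (
        ("pdac_poor",) if include_poor_in_pdac else ()
    )
    return (
        PathologyRule(("normal",), 5.0, 1),
        PathologyRule(("panin",), 30.0, 2),
        PathologyRule(pdac, 30.0, 4),
        PathologyRule(("pdac_poor",), 5.0, 5),
        PathologyRule(("necrosis",), 5.0, 6),
    )


def max_score(rules: Sequence[PathologyRule] = default_rules()) -> int:
    return sum(r.weight for r in rules)


def _validate_composition(comp: Mapping[str, float]) -> None:
    total = 0.0
    for cat in CATEGORIES:
        v = float(comp.get(cat, 0.0))
        if v < 0:
            raise ValueError(f"negative percentage for {cat!r}")
        if v > 100:
            raise ValueError(f"percentage above 100 for {cat!r}")
        total += v
    if total > 100 + 1e-9:
        raise ValueError(f"composition percentages sum to {total:g} > 100")


def weighted_pathology_score(
    comp: Mapping[str, float],
    rules: Sequence[PathologyRule] = default_rules(),
) -> int:
    """Weighted pathology score of one specimen composition.

    ``comp`` maps category names (see ``CATEGORIES``) to percentages;
    absent categories count as 0.
    """
    _validate_composition(comp)
    score = 0
    for rule in rules:
        pct = sum(float(comp.get(c, 0.0)) for c in rule.categories)
        if pct > rule.threshold:
            score += rule.weight
    return score


def score_table(
    df: pd.DataFrame, rules: Sequence[PathologyRule] = default_rules()
) -> pd.DataFrame:
    """Score every row of a histology composition table.

    Expects a ``specimen_id`` column plus the six category columns; returns
    (specimen_id, score).
    """
    missing = set(CATEGORIES) - set(df.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    scores = [
        weighted_pathology_score(row[list(CATEGORIES)].to_dict(), rules)
        for _, row in df.iterrows()
    ]
    out = pd.DataFrame({"score": scores})
    if "specimen_id" in df.columns:
        out.insert(0, "specimen_id", df["specimen_id"].to_numpy())
    return out
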