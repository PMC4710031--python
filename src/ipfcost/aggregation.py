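"""Course-weighted cost breakdown table and category shares.

Builds the categories x (courses + weighted) matrix with a TOTAL row.
Weighting happens on unrounded component values; display rounding is left
to the writer.  Category shares are reported to one decimal using
largest-remainder allocation so the printed percentages sum to exactly
100.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cost_components import CourseCostVector, course_cost_vector
from .epidemiology import case_counts
from .errors import DomainError, ReferenceResolutionError
from .model_io import ModelInputs

__all__ = [
    "CATEGORIES",
    "WEIGHTED_COLUMN",
    "TOTAL_ROW",
    "CostComponentTable",
    "course_total",
    "weighted_average",
    "category_shares",
    "build_breakdown_table",
    "national_annual_burden",
]

CATEGORIES: tuple[str, ...] = (
    "diagnosis",
    "treatment",
    "monitoring",
    "exacerbations",
    "end_of_life",
)
WEIGHTED_COLUMN = "weighted"
TOTAL_ROW = "TOTAL"

PROPORTION_TOL = 1e-9


@dataclass
class CostComponentTable:
    """Cost breakdown: category rows x course columns, plus weighted column.

    ``frame`` holds unrounded EUR values indexed by category (with a TOTAL
    row) and columned by course label (with a ``weighted`` column).
    """

    frame: pd.DataFrame
    proportions: dict[str, float] = field(default_factory=dict)

    @property
    def weighted_total(self) -> float:
        return float(self.frame.loc[TOTAL_ROW, WEIGHTED_COLUMN])

    def weighted_column(self) -> dict[str, float]:
        """Per-category weighted EUR (TOTAL row excluded)."""
        return {cat: float(self.frame.loc[cat, WEIGHTED_COLUMN]) for cat in CATEGORIES}

    def course_totals(self) -> dict[str, float]:
        return {
            col: float(self.frame.loc[TOTAL_ROW, col])
            for col in self.frame.columns
            if col != WEIGHTED_COLUMN
        }


def course_total(v: CourseCostVector) -> float:
    """Sum of the five annual components for one course."""
    return v.diagnosis + v.treatment + v.monitoring + v.exacerbations + v.end_of_life


def weighted_average(
    values: Mapping[str, float], proportions: Mapping[str, float]
) -> float:
    """Population-weighted mean over courses.

    ``values`` and ``proportions`` must cover the same course set and the
    proportions must sum to 1.
    """
    if set(values) != set(proportions):
        raise ReferenceResolutionError(
            f"course sets differ: values={sorted(values)} proportions={sorted(proportions)}"
        )
    total_weight = sum(proportions.values())
    if abs(total_weight - 1.0) > PROPORTION_TOL:
        raise ValueError(f"proportions must sum to 1, got {total_weight!r}")
    return sum(proportions[label] * values[label] for label in values)


def category_shares(weighted_column: Mapping[str, float]) -> dict[str, float]:
    """Per-category share of the weighted total, in percent at one decimal.

    Uses largest-remainder rounding on tenths of a percent so the reported
    shares sum to exactly 100.0.  Raises :class:`DomainError` on a
    non-positive total.
    """
    total = sum(weighted_column.values())
    if total <= 0 or not math.isfinite(total):
        raise DomainError(f"cannot compute shares of non-positive total {total}")
    # Work in tenths of a percent: floor, then hand out the shortfall to the
    # largest fractional remainders (ties broken by category order).
    tenths = {k: v / total * 1000.0 for k, v in weighted_column.items()}
    floors = {k: math.floor(t) for k, t in tenths.items()}
    shortfall = 1000 - sum(floors.values())
    by_remainder = sorted(tenths, key=lambda k: tenths[k] - floors[k], reverse=True)
    for k in by_remainder[:shortfall]:
        floors[k] += 1
    return {k: floors[k] / 10.0 for k in weighted_column}


def build_breakdown_table(inputs: ModelInputs) -> CostComponentTable:
    """Compute the full breakdown table from validated model inputs."""
    proportions = {c.label: c.proportion for c in inputs.courses}
    vectors = {c.label: course_cost_vector(inputs, c.label) for c in inputs.courses}

    columns: dict[str, list[float]] = {}
    for label, vec in vectors.items():
        cells = vec.as_dict()
        columns[label] = [cells[cat] for cat in CATEGORIES]
    frame = pd.DataFrame(columns, index=list(CATEGORIES))
    frame[WEIGHTED_COLUMN] = [
        weighted_average(
            {label: float(frame.loc[cat, label]) for label in proportions}, proportions
        )
        for cat in CATEGORIES
    ]
    frame.loc[TOTAL_ROW] = frame.sum(axis=0)
    return CostComponentTable(frame=frame, proportions=proportions)


def national_annual_burden(inputs: ModelInputs, table: CostComponentTable) -> float:
    """Convenience: weighted per-patient cost x diagnosed case count (EUR/year)."""
    return table.weighted_total * case_counts(inputs.epidemiology).diagnosed


def breakdown_from_vectors(
    vectors: Sequence[CourseCostVector], proportions: Mapping[str, float]
) -> CostComponentTable:
    """Assemble a table from precomputed vectors (used by sensitivity plots)."""
    columns = {v.course_label: [v.as_dict()[cat] for cat in CATEGORIES] for v in vectors}
    frame = pd.DataFrame(columns, index=list(CATEGORIES))
    frame[WEIGHTED_COLUMN] = [
        weighted_average(
            {label: float(frame.loc[cat, label]) for label in proportions}, proportions
        )
        for cat in CATEGORIES
    ]
    frame.loc[TOTAL_ROW] = frame.sum(axis=0)
    return CostComponentTable(frame=frame, proportions=dict(proportions))
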