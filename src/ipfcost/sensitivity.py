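"""One-at-a-time (univariate) sensitivity analysis.

Each scenario perturbs exactly one parameter block of the model inputs —
never the baseline object itself — re-runs the full breakdown, and records
the weighted total at the block's low and high settings together with the
percent difference from the base case.  Percent differences are stored
unrounded; the tornado CSV displays them as whole percents.

Supported parameter blocks
--------------------------
prevalence, incidence            scalar epidemiology fields
unit_costs                       whole catalogue (column switch or scale)
diagnosis_resource_use           quantities of the diagnostic work-up
monitoring_resource_use          quantities of all monitoring profiles
exacerbation_components          the three per-event cost components
exacerbation_rate                per-course annual exacerbation rates
end_of_life_components           the two lump terminal-cost components
treatment                        drug/therapy unit costs and overrides

Transforms are either ``multiply`` (relative, e.g. 0.75 for -25 %),
``set`` (absolute substitute, scalar parameters only), or ``column``
("min"/"max", unit_costs only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence, Union

import yaml

from .aggregation import build_breakdown_table
from .errors import DomainError, ReferenceResolutionError
from .model_io import ModelInputs

__all__ = [
    "Multiply",
    "SetValue",
    "UnitCostColumn",
    "Transform",
    "SensitivityScenario",
    "SensitivityResult",
    "apply_scenario",
    "run_univariate",
    "tornado_ranking",
    "load_scenarios",
    "default_epidemiology_scenarios",
]


@dataclass(frozen=True)
class Multiply:
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError(f"multiplier must be > 0, got {self.factor}")


@dataclass(frozen=True)
class SetValue:
    value: float


@dataclass(frozen=True)
class UnitCostColumn:
    column: Literal["min", "max"]


Transform = Union[Multiply, SetValue, UnitCostColumn]


@dataclass(frozen=True)
class SensitivityScenario:
    """One tornado row: a parameter block with its low and high transforms."""

    parameter_id: str
    low: Transform
    high: Transform


@dataclass(frozen=True)
class SensitivityResult:
    parameter_id: str
    base_cost: float
    cost_at_min: float
    cost_at_max: float

    @property
    def pct_diff_min(self) -> float:
        return (self.cost_at_min - self.base_cost) / self.base_cost * 100.0

    @property
    def pct_diff_max(self) -> float:
        return (self.cost_at_max - self.base_cost) / self.base_cost * 100.0

    @property
    def max_abs_pct_diff(self) -> float:
        return max(abs(self.pct_diff_min), abs(self.pct_diff_max))


# --------------------------------------------------------------------------
# Transform application


def _scalar(transform: Transform, current: float, what: str) -> float:
    if isinstance(transform, Multiply):
        return current * transform.factor
    if isinstance(transform, SetValue):
        return transform.value
    raise DomainError(f"{what}: transform {transform!r} not applicable to a scalar")


def _scale_only(transform: Transform, what: str) -> float:
    if isinstance(transform, Multiply):
        return transform.factor
    raise DomainError(f"{what}: only 'multiply' transforms are supported")


def _apply_prevalence(inputs: ModelInputs, t: Transform) -> None:
    epi = inputs.epidemiology
    epi.prevalence_per_100k = _scalar(t, epi.prevalence_per_100k, "prevalence")


def _apply_incidence(inputs: ModelInputs, t: Transform) -> None:
    epi = inputs.epidemiology
    epi.incidence_per_100k = _scalar(t, epi.incidence_per_100k, "incidence")


def _apply_unit_costs(inputs: ModelInputs, t: Transform) -> None:
    if isinstance(t, UnitCostColumn):
        for entry in inputs.unit_costs:
            entry.cost_mean = entry.cost_min if t.column == "min" else entry.cost_max
        return
    k = _scale_only(t, "unit_costs")
    # Rebuild entries atomically: scaling the whole range keeps the
    # min<=mean<=max invariant, but field-by-field assignment could violate
    # it transiently under validate_assignment.
    inputs.unit_costs = [
        entry.model_copy(
            update={
                "cost_min": entry.cost_min * k,
                "cost_mean": entry.cost_mean * k,
                "cost_max": entry.cost_max * k,
            }
        )
        for entry in inputs.unit_costs
    ]


def _apply_diagnosis_use(inputs: ModelInputs, t: Transform) -> None:
    k = _scale_only(t, "diagnosis_resource_use")
    for item in inputs.diagnosis_use:
        item.quantity *= k


def _apply_monitoring_use(inputs: ModelInputs, t: Transform) -> None:
    k = _scale_only(t, "monitoring_resource_use")
    for items in inputs.monitoring_use_by_course.values():
        for item in items:
            item.quantity *= k


def _apply_exacerbation_components(inputs: ModelInputs, t: Transform) -> None:
    k = _scale_only(t, "exacerbation_components")
    exc = inputs.exacerbation
    exc.diagnosis_cost *= k
    exc.treatment_cost *= k
    exc.resource_followup_cost *= k


def _apply_exacerbation_rate(inputs: ModelInputs, t: Transform) -> None:
    k = _scale_only(t, "exacerbation_rate")
    for course in inputs.courses:
        course.exacerbations_per_year *= k


def _apply_end_of_life(inputs: ModelInputs, t: Transform) -> None:
    k = _scale_only(t, "end_of_life_components")
    eol = inputs.end_of_life
    eol.treatment_cost *= k
    eol.visit_cost *= k


def _apply_treatment(inputs: ModelInputs, t: Transform) -> None:
    k = _scale_only(t, "treatment")
    for drug in inputs.drugs:
        drug.unit_cost *= k
    for therapy in inputs.nonpharma:
        therapy.unit_cost *= k
    if inputs.treatment_override_by_course is not None:
        inputs.treatment_override_by_course = {
            label: value * k for label, value in inputs.treatment_override_by_course.items()
        }


_APPLIERS: dict[str, Callable[[ModelInputs, Transform], None]] = {
    "prevalence": _apply_prevalence,
    "incidence": _apply_incidence,
    "unit_costs": _apply_unit_costs,
    "diagnosis_resource_use": _apply_diagnosis_use,
    "monitoring_resource_use": _apply_monitoring_use,
    "exacerbation_components": _apply_exacerbation_components,
    "exacerbation_rate": _apply_exacerbation_rate,
    "end_of_life_components": _apply_end_of_life,
    "treatment": _apply_treatment,
}


def apply_scenario(inputs: ModelInputs, parameter_id: str, transform: Transform) -> ModelInputs:
    """Return a deep copy of ``inputs`` with one parameter block transformed.

    The original object is never mutated.
    """
    try:
        applier = _APPLIERS[parameter_id]
    except KeyError:
        raise ReferenceResolutionError(
            f"unknown sensitivity parameter {parameter_id!r}; "
            f"known: {sorted(_APPLIERS)}"
        ) from None
    modified = inputs.model_copy(deep=True)
    applier(modified, transform)
    return modified


def run_univariate(
    inputs: ModelInputs, scenarios: Sequence[SensitivityScenario]
) -> list[SensitivityResult]:
    """Recompute the weighted total under each scenario's low/high settings."""
    base = build_breakdown_table(inputs).weighted_total
    results = []
    for scenario in scenarios:
        low_total = build_breakdown_table(
            apply_scenario(inputs, scenario.parameter_id, scenario.low)
        ).weighted_total
        high_total = build_breakdown_table(
            apply_scenario(inputs, scenario.parameter_id, scenario.high)
        ).weighted_total
        results.append(
            SensitivityResult(
                parameter_id=scenario.parameter_id,
                base_cost=base,
                cost_at_min=low_total,
                cost_at_max=high_total,
            )
        )
    return results


def tornado_ranking(results: Sequence[SensitivityResult]) -> list[SensitivityResult]:
    """Sort by largest absolute percent swing, ties broken alphabetically."""
    if not results:
        raise DomainError("tornado ranking requires at least one result")
    return sorted(results, key=lambda r: (-r.max_abs_pct_diff, r.parameter_id))


# --------------------------------------------------------------------------
# Scenario file handling


def _parse_transform(raw: dict) -> Transform:
    if not isinstance(raw, dict) or len(raw) != 1:
        raise ValueError(f"transform must be a one-key mapping, got {raw!r}")
    (key, value), = raw.items()
    if key == "multiply":
        return Multiply(float(value))
    if key == "set":
        return SetValue(float(value))
    if key == "column":
        if value not in ("min", "max"):
            raise ValueError(f"column transform must be 'min' or 'max', got {value!r}")
        return UnitCostColumn(value)
    raise ValueError(f"unknown transform kind {key!r}")


def load_scenarios(path: str | Path) -> list[SensitivityScenario]:
    """Read a scenario list from JSON or YAML.

    Each entry: ``{"parameter_id": ..., "low": {...}, "high": {...}}``.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"scenario file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = (
        yaml.safe_load(text)
        if path.suffix.lower() in {".yaml", ".yml"}
        else json.loads(text)
    )
    if data is None:
        return []
    if not isinstance(data, list):
        raise ValueError("scenario file must contain a list")
    return [
        SensitivityScenario(
            parameter_id=entry["parameter_id"],
            low=_parse_transform(entry["low"]),
            high=_parse_transform(entry["high"]),
        )
        for entry in data
    ]


def default_epidemiology_scenarios(swing: float = 0.25) -> list[SensitivityScenario]:
    """The +/-25 % prevalence and incidence scenarios of the base design."""
    return [
        SensitivityScenario("prevalence", Multiply(1.0 - swing), Multiply(1.0 + swing)),
        SensitivityScenario("incidence", Multiply(1.0 - swing), Multiply(1.0 + swing)),
    ]
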