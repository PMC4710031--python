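"""Input data model, file loading/validation, and result-table writing.

The model tree is a single JSON or YAML document validated against the
pydantic schema below.  Two tabular blocks — the unit-cost catalogue and
the diagnostic resource-use profile — may alternatively live in CSV
side-tables: give the path (relative to the main file) as a string in
place of the list.  CSV dialect: UTF-8, comma-separated, header row,
period decimal separator.

Error categories
----------------
* missing/unreadable file            -> ``FileNotFoundError`` / ``OSError``
* schema or invariant violation      -> ``pydantic.ValidationError``
* dangling resource identifier       -> ``ReferenceResolutionError``
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import TYPE_CHECKING, Any, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ReferenceResolutionError
from .rounding import round_half_up

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .aggregation import CostComponentTable
    from .sensitivity import SensitivityResult

__all__ = [
    "EpidemiologySpec",
    "DiseaseCourseSpec",
    "UnitCostEntry",
    "ResourceUseItem",
    "DrugRegimen",
    "AdverseEventSpec",
    "NonPharmaTherapy",
    "ExacerbationComponents",
    "EndOfLifeComponents",
    "ModelInputs",
    "load_inputs",
    "write_results",
    "read_breakdown",
    "model_inputs_schema",
]

PROPORTION_TOL = 1e-9


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EpidemiologySpec(_StrictModel):
    """Population-level epidemiology driving case counts and annualization."""

    population: int = Field(gt=0, description="Total population of the territory")
    prevalence_per_100k: float = Field(gt=0, description="Prevalent cases per 100,000 persons")
    incidence_per_100k: float = Field(ge=0, description="New cases per 100,000 person-years")
    diagnostic_rate: float = Field(ge=0, le=1, description="Fraction of prevalent cases diagnosed")

    @model_validator(mode="after")
    def _warn_incidence_above_prevalence(self) -> "EpidemiologySpec":
        # Not forbidden (short-survival diseases can have I > P) but unusual.
        if self.incidence_per_100k > self.prevalence_per_100k:
            warnings.warn(
                "incidence_per_100k exceeds prevalence_per_100k; "
                "the diagnosis annualization ratio will exceed 1",
                stacklevel=2,
            )
        return self


class DiseaseCourseSpec(_StrictModel):
    """One clinical course (e.g. stable / slow / rapid progression)."""

    label: str
    proportion: float = Field(ge=0, le=1)
    median_survival_months: float = Field(gt=0)
    exacerbations_per_year: float = Field(ge=0)


class UnitCostEntry(_StrictModel):
    """A costed resource with its plausible range (EUR)."""

    resource_id: str
    description: str = ""
    cost_mean: float = Field(ge=0)
    cost_min: float = Field(ge=0)
    cost_max: float = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "UnitCostEntry":
        if not (self.cost_min <= self.cost_mean <= self.cost_max):
            raise ValueError(
                f"unit cost {self.resource_id!r}: require cost_min <= cost_mean <= cost_max, "
                f"got {self.cost_min} / {self.cost_mean} / {self.cost_max}"
            )
        return self


class ResourceUseItem(_StrictModel):
    """Quantity of one resource, either one-off or over a recurring period.

    ``period_months is None`` marks a one-off use (diagnostic work-up);
    a positive period (typically 3) marks a recurring profile that gets
    annualized by ``12 / period_months``.
    """

    resource_id: str
    quantity: float = Field(ge=0)
    period_months: Optional[float] = Field(default=None, gt=0)

    @property
    def is_one_off(self) -> bool:
        return self.period_months is None


class DrugRegimen(_StrictModel):
    """A drug with per-course uptake; annual cost = pct x unit x dose x days."""

    drug_id: str
    pct_patients_by_course: dict[str, float]
    unit_cost: float = Field(ge=0)
    daily_dose_units: float = Field(ge=0)
    duration_days: float = Field(ge=0, le=366)

    @model_validator(mode="after")
    def _fractions(self) -> "DrugRegimen":
        for course, pct in self.pct_patients_by_course.items():
            if not 0 <= pct <= 1:
                raise ValueError(
                    f"drug {self.drug_id!r}: pct for course {course!r} must be in [0,1], got {pct}"
                )
        return self


class AdverseEventSpec(_StrictModel):
    """One adverse-event line (per grade) attached to a drug.

    Only grade >= 3 events affecting strictly more than the inclusion
    threshold (default 5 %) of patients enter the cost; grade-4 events are
    always costed as hospitalised.
    """

    ae_id: str
    grade: int = Field(ge=1, le=4)
    pct_patients: float = Field(ge=0, le=1)
    cost_nonhospitalized: float = Field(default=0.0, ge=0)
    cost_hospitalized: float = Field(default=0.0, ge=0)
    hospitalized_fraction: float = Field(default=0.0, ge=0, le=1)


class NonPharmaTherapy(_StrictModel):
    """Non-pharmacological therapy (transplant, rehabilitation)."""

    therapy_id: str
    pct_patients_by_course: dict[str, float]
    unit_cost: float = Field(ge=0)

    @model_validator(mode="after")
    def _fractions(self) -> "NonPharmaTherapy":
        for course, pct in self.pct_patients_by_course.items():
            if not 0 <= pct <= 1:
                raise ValueError(
                    f"therapy {self.therapy_id!r}: pct for course {course!r} "
                    f"must be in [0,1], got {pct}"
                )
        return self


class ExacerbationComponents(_StrictModel):
    """Per-event cost components of an acute exacerbation (EUR/event)."""

    diagnosis_cost: float = Field(ge=0)
    treatment_cost: float = Field(ge=0)
    resource_followup_cost: float = Field(ge=0)


class EndOfLifeComponents(_StrictModel):
    """Lump end-of-life cost components (EUR per dying patient)."""

    treatment_cost: float = Field(ge=0)
    visit_cost: float = Field(ge=0)


class ModelInputs(_StrictModel):
    """Complete, validated input set for one model run.

    ``treatment_override_by_course`` short-circuits the drug/AE/non-pharma
    computation with a directly supplied annual treatment cost per course;
    it exists for calibrated baselines where doses and durations are not
    itemized.  Pass-through descriptive fields (``metadata``) enter no
    formula.
    """

    epidemiology: EpidemiologySpec
    courses: list[DiseaseCourseSpec] = Field(min_length=1)
    unit_costs: list[UnitCostEntry] = Field(default_factory=list)
    diagnosis_use: list[ResourceUseItem] = Field(default_factory=list)
    monitoring_use_by_course: dict[str, list[ResourceUseItem]] = Field(default_factory=dict)
    drugs: list[DrugRegimen] = Field(default_factory=list)
    adverse_events_by_drug: dict[str, list[AdverseEventSpec]] = Field(default_factory=dict)
    nonpharma: list[NonPharmaTherapy] = Field(default_factory=list)
    exacerbation: ExacerbationComponents
    end_of_life: EndOfLifeComponents
    treatment_override_by_course: Optional[dict[str, float]] = None
    metadata: dict[str, Any] = Field(default_factory=dict)

    # ---- invariants -----------------------------------------------------

    @model_validator(mode="after")
    def _proportions_sum_to_one(self) -> "ModelInputs":
        total = sum(c.proportion for c in self.courses)
        if abs(total - 1.0) > PROPORTION_TOL:
            raise ValueError(
                f"course proportions must sum to 1 (got {total!r}); "
                f"courses: {[c.label for c in self.courses]}"
            )
        labels = [c.label for c in self.courses]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate course labels: {labels}")
        return self

    @model_validator(mode="after")
    def _unique_unit_costs(self) -> "ModelInputs":
        seen: set[str] = set()
        for entry in self.unit_costs:
            if entry.resource_id in seen:
                raise ValueError(f"duplicate unit-cost resource_id {entry.resource_id!r}")
            seen.add(entry.resource_id)
        return self

    @model_validator(mode="after")
    def _references_resolve(self) -> "ModelInputs":
        catalogue = {e.resource_id for e in self.unit_costs}
        referenced: set[str] = set()

        def check(items: list[ResourceUseItem], where: str) -> None:
            for item in items:
                if item.resource_id not in catalogue:
                    raise ReferenceResolutionError(
                        f"{where}: resource_id {item.resource_id!r} has no unit-cost entry"
                    )
                referenced.add(item.resource_id)

        check(self.diagnosis_use, "diagnosis_use")
        course_labels = {c.label for c in self.courses}
        for label, items in self.monitoring_use_by_course.items():
            if label not in course_labels:
                raise ReferenceResolutionError(
                    f"monitoring_use_by_course: unknown course label {label!r}"
                )
            check(items, f"monitoring_use_by_course[{label}]")
        if self.treatment_override_by_course is not None:
            for label in self.treatment_override_by_course:
                if label not in course_labels:
                    raise ReferenceResolutionError(
                        f"treatment_override_by_course: unknown course label {label!r}"
                    )
        drug_ids = {d.drug_id for d in self.drugs}
        for drug_id in self.adverse_events_by_drug:
            if drug_id not in drug_ids:
                raise ReferenceResolutionError(
                    f"adverse_events_by_drug: unknown drug_id {drug_id!r}"
                )
        unreferenced = catalogue - referenced
        if unreferenced:
            # Shared catalogues legitimately carry extra rows.
            warnings.warn(
                f"unit costs never referenced by a resource-use item: {sorted(unreferenced)}",
                stacklevel=2,
            )
        return self

    # ---- conveniences ---------------------------------------------------

    def unit_cost_lookup(self) -> dict[str, UnitCostEntry]:
        return {e.resource_id: e for e in self.unit_costs}

    def course_labels(self) -> list[str]:
        return [c.label for c in self.courses]

    def course(self, label: str) -> DiseaseCourseSpec:
        for c in self.courses:
            if c.label == label:
                return c
        raise ReferenceResolutionError(f"unknown disease course {label!r}")


# --------------------------------------------------------------------------
# Loading


def _read_unit_costs_csv(path: Path) -> list[dict[str, Any]]:
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return [
        {
            "resource_id": r["resource_id"],
            "description": r.get("description", "") or "",
            "cost_mean": float(r["cost_mean"]),
            "cost_min": float(r["cost_min"]),
            "cost_max": float(r["cost_max"]),
        }
        for r in rows
    ]


def _read_resource_use_csv(path: Path) -> list[dict[str, Any]]:
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for r in rows:
        period = r.get("period_months", "")
        out.append(
            {
                "resource_id": r["resource_id"],
                "quantity": float(r["quantity"]),
                "period_months": float(period) if period not in ("", None) else None,
            }
        )
    return out


def load_inputs(path: str | Path) -> ModelInputs:
    """Read and validate a model-input file (JSON or YAML).

    String values in place of the ``unit_costs`` or ``diagnosis_use`` lists
    are treated as CSV side-table paths relative to the input file.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"input file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"input file {path} must contain a mapping at top level")
    if isinstance(data.get("unit_costs"), str):
        data["unit_costs"] = _read_unit_costs_csv(path.parent / data["unit_costs"])
    if isinstance(data.get("diagnosis_use"), str):
        data["diagnosis_use"] = _read_resource_use_csv(path.parent / data["diagnosis_use"])
    return ModelInputs.model_validate(data)


def model_inputs_schema() -> dict[str, Any]:
    """JSON Schema for the model-input document."""
    return ModelInputs.model_json_schema()


# --------------------------------------------------------------------------
# Writing

BREAKDOWN_FILENAME = "breakdown.csv"
TORNADO_FILENAME = "tornado.csv"


def write_results(
    table: "CostComponentTable",
    sens: "list[SensitivityResult]",
    path: str | Path,
) -> list[Path]:
    """Write the breakdown table (and tornado table if any) as CSV.

    EUR cells are rounded half-up to 2 decimals; percent differences to
    whole percents.  Returns the written paths.  An empty ``sens`` list
    writes no tornado file.
    """
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    frame = table.frame.map(lambda v: f"{round_half_up(v, 2):.2f}")
    breakdown_path = out_dir / BREAKDOWN_FILENAME
    frame.to_csv(breakdown_path, index_label="category")
    written.append(breakdown_path)

    if sens:
        tornado_path = out_dir / TORNADO_FILENAME
        with tornado_path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["parameter", "cost_at_min", "cost_at_max", "pct_diff_min", "pct_diff_max"]
            )
            for r in sens:
                writer.writerow(
                    [
                        r.parameter_id,
                        f"{round_half_up(r.cost_at_min, 2):.2f}",
                        f"{round_half_up(r.cost_at_max, 2):.2f}",
                        f"{round_half_up(r.pct_diff_min):.0f}",
                        f"{round_half_up(r.pct_diff_max):.0f}",
                    ]
                )
        written.append(tornado_path)
    return written


def read_breakdown(path: str | Path):
    """Round-trip reader for the breakdown CSV -> pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, index_col="category")
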