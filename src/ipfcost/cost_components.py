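"""Annual per-patient cost components, computed per disease course.

Five components make up a :class:`CourseCostVector`:

diagnosis      one-off work-up cost annualized by incidence/prevalence
               (identical across courses)
treatment      drugs + includable adverse events + non-pharmacological
               therapies, or a calibrated per-course override
monitoring     recurring resource profile annualized by 12/period
exacerbations  per-event cost x annual event rate
end_of_life    lump terminal-care cost x annual mortality (DEALE)

Every component is a plain sum of (fraction x quantity x unit cost)
atoms, so each is independently checkable by flat enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .epidemiology import annualization_ratio, deale_annual_mortality
from .errors import DomainError, ReferenceResolutionError
from .model_io import (
    AdverseEventSpec,
    DrugRegimen,
    EndOfLifeComponents,
    ExacerbationComponents,
    ModelInputs,
    NonPharmaTherapy,
    ResourceUseItem,
    UnitCostEntry,
)

__all__ = [
    "CourseCostVector",
    "AE_INCLUSION_THRESHOLD",
    "resource_block_cost",
    "diagnosis_annual_cost",
    "drug_annual_cost",
    "adverse_event_annual_cost",
    "nonpharma_annual_cost",
    "monitoring_annual_cost",
    "exacerbation_event_cost",
    "exacerbation_annual_cost",
    "eol_lump_cost",
    "eol_annual_cost",
    "course_cost_vector",
]

#: Adverse events must affect strictly more than this fraction of patients
#: to be costed (grade >= 3 only).  The boundary value is excluded.
AE_INCLUSION_THRESHOLD = 0.05


@dataclass(frozen=True)
class CourseCostVector:
    """The five annual per-patient cost components for one course (EUR)."""

    course_label: str
    diagnosis: float
    treatment: float
    monitoring: float
    exacerbations: float
    end_of_life: float

    def as_dict(self) -> dict[str, float]:
        return {
            "diagnosis": self.diagnosis,
            "treatment": self.treatment,
            "monitoring": self.monitoring,
            "exacerbations": self.exacerbations,
            "end_of_life": self.end_of_life,
        }


def _lookup(costs: Mapping[str, UnitCostEntry], resource_id: str) -> UnitCostEntry:
    try:
        return costs[resource_id]
    except KeyError:
        raise ReferenceResolutionError(
            f"resource_id {resource_id!r} has no unit-cost entry"
        ) from None


def resource_block_cost(
    items: Iterable[ResourceUseItem], costs: Mapping[str, UnitCostEntry]
) -> float:
    """Sum of quantity x mean unit cost over a block of resource-use items."""
    return sum(item.quantity * _lookup(costs, item.resource_id).cost_mean for item in items)


def diagnosis_annual_cost(total_diagnosis_cost: float, ratio: float) -> float:
    """Spread a one-off diagnostic cost over prevalent patient-years."""
    if ratio < 0:
        raise DomainError(f"annualization ratio must be >= 0, got {ratio}")
    return total_diagnosis_cost * ratio


def drug_annual_cost(regimen: DrugRegimen, course: str) -> float:
    """Annual drug cost: uptake x unit cost x daily dose x treated days."""
    try:
        pct = regimen.pct_patients_by_course[course]
    except KeyError:
        raise ReferenceResolutionError(
            f"drug {regimen.drug_id!r} has no uptake for course {course!r}"
        ) from None
    return pct * regimen.unit_cost * regimen.daily_dose_units * regimen.duration_days


def adverse_event_annual_cost(
    aes: Iterable[AdverseEventSpec],
    pct_on_drug: float,
    *,
    threshold: float = AE_INCLUSION_THRESHOLD,
    include_at_threshold: bool = False,
) -> float:
    """Cost of includable adverse events for one drug, per patient-year.

    Grade 1-2 events are excluded outright.  Grade >= 3 events are costed
    only when their frequency exceeds ``threshold`` (strict by default; set
    ``include_at_threshold`` to admit the boundary).  Grade-3 costs split
    between hospitalised and non-hospitalised management by
    ``hospitalized_fraction``; grade-4 events are always hospitalised.
    """
    total = 0.0
    for ae in aes:
        if ae.grade < 3:
            continue
        included = ae.pct_patients > threshold or (
            include_at_threshold and ae.pct_patients == threshold
        )
        if not included:
            continue
        if ae.grade == 4:
            per_event = ae.cost_hospitalized
        else:
            per_event = (
                ae.hospitalized_fraction * ae.cost_hospitalized
                + (1.0 - ae.hospitalized_fraction) * ae.cost_nonhospitalized
            )
        total += pct_on_drug * ae.pct_patients * per_event
    return total


def nonpharma_annual_cost(therapies: Iterable[NonPharmaTherapy], course: str) -> float:
    """Annual non-pharmacological cost: sum of uptake x unit cost.

    Therapies without an uptake entry for ``course`` contribute nothing.
    """
    total = 0.0
    for therapy in therapies:
        pct = therapy.pct_patients_by_course.get(course, 0.0)
        total += pct * therapy.unit_cost
    return total


def monitoring_annual_cost(
    quarterly_use: Iterable[ResourceUseItem], costs: Mapping[str, UnitCostEntry]
) -> float:
    """Annualize a recurring resource profile: quantity x cost x 12/period."""
    total = 0.0
    for item in quarterly_use:
        if item.period_months is None:
            raise DomainError(
                f"monitoring item {item.resource_id!r} must declare period_months"
            )
        total += (
            item.quantity
            * _lookup(costs, item.resource_id).cost_mean
            * (12.0 / item.period_months)
        )
    return total


def exacerbation_event_cost(c: ExacerbationComponents) -> float:
    """Total per-event exacerbation cost: diagnosis + treatment + follow-up."""
    return c.diagnosis_cost + c.treatment_cost + c.resource_followup_cost


def exacerbation_annual_cost(event_cost: float, rate: float) -> float:
    """Annual exacerbation cost: per-event cost x events per patient-year."""
    if rate < 0:
        raise DomainError(f"exacerbation rate must be >= 0, got {rate}")
    return event_cost * rate


def eol_lump_cost(c: EndOfLifeComponents) -> float:
    """Lump end-of-life cost per dying patient: treatment + visits."""
    return c.treatment_cost + c.visit_cost


def eol_annual_cost(lump: float, annual_mortality: float) -> float:
    """Spread the lump terminal cost over patient-years via mortality."""
    if not 0.0 <= annual_mortality <= 1.0:
        raise DomainError(f"annual mortality must be in [0,1], got {annual_mortality}")
    return lump * annual_mortality


def _treatment_annual_cost(inputs: ModelInputs, course: str) -> float:
    if inputs.treatment_override_by_course is not None:
        override = inputs.treatment_override_by_course
        if course in override:
            return override[course]
    total = 0.0
    for regimen in inputs.drugs:
        pct = regimen.pct_patients_by_course.get(course)
        if pct is None:
            continue
        total += drug_annual_cost(regimen, course)
        aes = inputs.adverse_events_by_drug.get(regimen.drug_id, [])
        total += adverse_event_annual_cost(aes, pct)
    total += nonpharma_annual_cost(inputs.nonpharma, course)
    return total


def course_cost_vector(inputs: ModelInputs, course: str) -> CourseCostVector:
    """Assemble all five annual cost components for one disease course."""
    spec = inputs.course(course)  # raises ReferenceResolutionError if unknown
    costs = inputs.unit_cost_lookup()
    epi = inputs.epidemiology
    ratio = annualization_ratio(epi.incidence_per_100k, epi.prevalence_per_100k)
    return CourseCostVector(
        course_label=course,
        diagnosis=diagnosis_annual_cost(
            resource_block_cost(inputs.diagnosis_use, costs), ratio
        ),
        treatment=_treatment_annual_cost(inputs, course),
        monitoring=monitoring_annual_cost(
            inputs.monitoring_use_by_course.get(course, []), costs
        ),
        exacerbations=exacerbation_annual_cost(
            exacerbation_event_cost(inputs.exacerbation), spec.exacerbations_per_year
        ),
        end_of_life=eol_annual_cost(
            eol_lump_cost(inputs.end_of_life),
            deale_annual_mortality(spec.median_survival_months),
        ),
    )
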