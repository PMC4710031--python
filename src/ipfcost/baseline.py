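"""Calibrated Spanish IPF baseline input set.

Encodes the published base-case parameters: a population of 46,039,979
with prevalence 12 and incidence 3 per 100,000, an 85 % diagnostic rate,
three disease courses at 20/60/20 % with survivals of 66/42/15 months, a
diagnostic work-up totalling EUR 4,736.28, exacerbation event components
of EUR 339 + 305 + 11,074, and end-of-life components of EUR 463 + 864.

Two blocks are calibrated rather than itemized, because the underlying
doses, durations and per-test quantities were never published at line
level:

* per-course annual treatment and monitoring costs enter as calibrated
  values (treatment via ``treatment_override_by_course``; monitoring as a
  single synthetic quarterly resource per course priced at a quarter of
  the annual target);
* per-course exacerbation rates are back-calculated from the published
  per-course annual exacerbation costs divided by the per-event cost, so
  the component reproduces the published cells exactly (the rounded
  panel-elicited rates 0.76/0.82/1.8 are kept as pass-through metadata).

Unit-cost min/max ranges here are synthetic (-20 %/+25 % around the mean);
published sensitivity ranges for resource use were never itemized.
"""

from __future__ import annotations

from .model_io import (
    DiseaseCourseSpec,
    EndOfLifeComponents,
    EpidemiologySpec,
    ExacerbationComponents,
    ModelInputs,
    ResourceUseItem,
    UnitCostEntry,
)
from .synthetic_delphi import QuestionSpec

__all__ = ["baseline_inputs", "baseline_questions", "STABLE", "SLOW", "RAPID"]

STABLE = "stable"
SLOW = "slow_progression"
RAPID = "rapid_progression"

_EVENT_COST = 339.0 + 305.0 + 11074.0  # EUR per exacerbation

# Published per-course annual exacerbation costs (EUR/patient-year).
_EXAC_ANNUAL = {STABLE: 8882.22, SLOW: 9646.21, RAPID: 20511.50}

# Published per-course annual treatment costs (EUR/patient-year).
_TREATMENT_ANNUAL = {STABLE: 722.26, SLOW: 8069.33, RAPID: 10802.52}

# Published per-course annual monitoring costs (EUR/patient-year).
_MONITORING_ANNUAL = {STABLE: 453.94, SLOW: 1698.91, RAPID: 24199.00}

_SURVIVAL_MONTHS = {STABLE: 66.0, SLOW: 42.0, RAPID: 15.0}
_PROPORTIONS = {STABLE: 0.2, SLOW: 0.6, RAPID: 0.2}

_DIAGNOSIS_TOTAL = 4736.28  # EUR, one-off work-up per incident patient


def _unit_cost(resource_id: str, mean: float, description: str = "") -> UnitCostEntry:
    return UnitCostEntry(
        resource_id=resource_id,
        description=description,
        cost_mean=mean,
        cost_min=mean * 0.80,
        cost_max=mean * 1.25,
    )


def baseline_inputs() -> ModelInputs:
    """Validated model inputs reproducing the published base case."""
    courses = [
        DiseaseCourseSpec(
            label=label,
            proportion=_PROPORTIONS[label],
            median_survival_months=_SURVIVAL_MONTHS[label],
            exacerbations_per_year=_EXAC_ANNUAL[label] / _EVENT_COST,
        )
        for label in (STABLE, SLOW, RAPID)
    ]
    unit_costs = [
        _unit_cost("diagnostic_workup", _DIAGNOSIS_TOTAL, "complete diagnostic work-up"),
    ] + [
        _unit_cost(
            f"monitoring_quarter_{label}",
            _MONITORING_ANNUAL[label] / 4.0,
            f"quarterly monitoring bundle, {label}",
        )
        for label in (STABLE, SLOW, RAPID)
    ]
    return ModelInputs(
        epidemiology=EpidemiologySpec(
            population=46_039_979,
            prevalence_per_100k=12.0,
            incidence_per_100k=3.0,
            diagnostic_rate=0.85,
        ),
        courses=courses,
        unit_costs=unit_costs,
        diagnosis_use=[ResourceUseItem(resource_id="diagnostic_workup", quantity=1.0)],
        monitoring_use_by_course={
            label: [
                ResourceUseItem(
                    resource_id=f"monitoring_quarter_{label}",
                    quantity=1.0,
                    period_months=3.0,
                )
            ]
            for label in (STABLE, SLOW, RAPID)
        },
        exacerbation=ExacerbationComponents(
            diagnosis_cost=339.0, treatment_cost=305.0, resource_followup_cost=11074.0
        ),
        end_of_life=EndOfLifeComponents(treatment_cost=463.0, visit_cost=864.0),
        treatment_override_by_course=dict(_TREATMENT_ANNUAL),
        metadata={
            # Descriptive pass-through values; they enter no cost formula.
            "panel_exacerbations_per_year": {STABLE: 0.76, SLOW: 0.82, RAPID: 1.8},
            "exacerbation_mortality": {
                "fraction_dying_after_exacerbation": 0.51,
                "in_hospital_share": 0.69,
                "post_discharge_share": 0.31,
            },
            "currency_year": 2013,
        },
    )


def baseline_questions(dispersion: float = 0.15) -> list[QuestionSpec]:
    """Default elicitation question set targeting the baseline's key inputs."""
    questions = [
        QuestionSpec(
            question_id="prevalence_per_100k",
            target_field="epidemiology.prevalence_per_100k",
            true_value=12.0,
            dispersion=dispersion,
            bounds=(0.5, 100.0),
        ),
        QuestionSpec(
            question_id="incidence_per_100k",
            target_field="epidemiology.incidence_per_100k",
            true_value=3.0,
            dispersion=dispersion,
            bounds=(0.1, 100.0),
        ),
    ]
    for index, label in enumerate((STABLE, SLOW, RAPID)):
        questions.append(
            QuestionSpec(
                question_id=f"survival_months_{label}",
                target_field=f"courses[{index}].median_survival_months",
                true_value=_SURVIVAL_MONTHS[label],
                dispersion=dispersion,
                bounds=(1.0, 240.0),
            )
        )
        questions.append(
            QuestionSpec(
                question_id=f"exacerbation_rate_{label}",
                target_field=f"courses[{index}].exacerbations_per_year",
                true_value=_EXAC_ANNUAL[label] / _EVENT_COST,
                dispersion=dispersion,
                bounds=(0.0, 12.0),
            )
        )
    questions.append(
        QuestionSpec(
            question_id="exacerbation_followup_cost",
            target_field="exacerbation.resource_followup_cost",
            true_value=11074.0,
            dispersion=dispersion,
            bounds=(0.0, 1e6),
        )
    )
    questions.append(
        QuestionSpec(
            question_id="end_of_life_visit_cost",
            target_field="end_of_life.visit_cost",
            true_value=864.0,
            dispersion=dispersion,
            bounds=(0.0, 1e6),
        )
    )
    return questions
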