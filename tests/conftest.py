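import json

import numpy as np
import pytest

from ipfcost.baseline import baseline_inputs
from ipfcost.model_io import (
    AdverseEventSpec,
    DiseaseCourseSpec,
    DrugRegimen,
    EndOfLifeComponents,
    EpidemiologySpec,
    ExacerbationComponents,
    ModelInputs,
    NonPharmaTherapy,
    ResourceUseItem,
    UnitCostEntry,
)


@pytest.fixture
def baseline():
    return baseline_inputs()


@pytest.fixture
def baseline_file(tmp_path):
    path = tmp_path / "baseline.json"
    path.write_text(
        json.dumps(baseline_inputs().model_dump(mode="json"), indent=2),
        encoding="utf-8",
    )
    return path


def make_random_inputs(
    rng: np.random.Generator,
    *,
    n_courses: int | None = None,
    with_override: bool = False,
) -> ModelInputs:
    """A small, valid, fully random model-input fixture."""
    if n_courses is None:
        n_courses = int(rng.integers(1, 4))
    labels = [f"course{i}" for i in range(n_courses)]
    raw = rng.uniform(0.1, 1.0, size=n_courses)
    proportions = raw / raw.sum()
    # Renormalize exactly: push the residual onto the last course.
    proportions[-1] = 1.0 - proportions[:-1].sum()

    n_resources = int(rng.integers(2, 7))
    unit_costs = []
    for i in range(n_resources):
        mean = float(rng.uniform(5, 500))
        unit_costs.append(
            UnitCostEntry(
                resource_id=f"res{i}",
                cost_mean=mean,
                cost_min=mean * float(rng.uniform(0.5, 1.0)),
                cost_max=mean * float(rng.uniform(1.0, 2.0)),
            )
        )
    resource_ids = [e.resource_id for e in unit_costs]

    diagnosis_use = [
        ResourceUseItem(resource_id=rid, quantity=float(rng.uniform(0, 4)))
        for rid in rng.choice(resource_ids, size=int(rng.integers(1, n_resources + 1)), replace=False)
    ]
    monitoring = {
        label: [
            ResourceUseItem(
                resource_id=rid,
                quantity=float(rng.uniform(0, 3)),
                period_months=float(rng.choice([1.0, 3.0, 6.0])),
            )
            for rid in rng.choice(
                resource_ids, size=int(rng.integers(0, n_resources + 1)), replace=False
            )
        ]
        for label in labels
    }

    drugs = []
    aes_by_drug = {}
    for i in range(int(rng.integers(0, 4))):
        drug_id = f"drug{i}"
        drugs.append(
            DrugRegimen(
                drug_id=drug_id,
                pct_patients_by_course={
                    label: float(rng.uniform(0, 1)) for label in labels
                },
                unit_cost=float(rng.uniform(0.05, 20)),
                daily_dose_units=float(rng.uniform(0.5, 4)),
                duration_days=float(rng.uniform(0, 366)),
            )
        )
        aes_by_drug[drug_id] = [
            AdverseEventSpec(
                ae_id=f"{drug_id}_ae{j}",
                grade=int(rng.integers(1, 5)),
                pct_patients=float(rng.uniform(0, 0.4)),
                cost_nonhospitalized=float(rng.uniform(0, 200)),
                cost_hospitalized=float(rng.uniform(500, 8000)),
                hospitalized_fraction=float(rng.uniform(0, 1)),
            )
            for j in range(int(rng.integers(0, 4)))
        ]

    nonpharma = [
        NonPharmaTherapy(
            therapy_id=f"therapy{i}",
            pct_patients_by_course={label: float(rng.uniform(0, 0.3)) for label in labels},
            unit_cost=float(rng.uniform(100, 90000)),
        )
        for i in range(int(rng.integers(0, 3)))
    ]

    override = None
    if with_override:
        override = {label: float(rng.uniform(0, 20000)) for label in labels}

    return ModelInputs(
        epidemiology=EpidemiologySpec(
            population=int(rng.integers(10_000, 100_000_000)),
            prevalence_per_100k=float(rng.uniform(1, 50)),
            incidence_per_100k=float(rng.uniform(0.1, 20)),
            diagnostic_rate=float(rng.uniform(0, 1)),
        ),
        courses=[
            DiseaseCourseSpec(
                label=label,
                proportion=float(p),
                median_survival_months=float(rng.uniform(4, 120)),
                exacerbations_per_year=float(rng.uniform(0, 3)),
            )
            for label, p in zip(labels, proportions)
        ],
        unit_costs=unit_costs,
        diagnosis_use=diagnosis_use,
        monitoring_use_by_course=monitoring,
        drugs=drugs,
        adverse_events_by_drug=aes_by_drug,
        nonpharma=nonpharma,
        exacerbation=ExacerbationComponents(
            diagnosis_cost=float(rng.uniform(0, 1000)),
            treatment_cost=float(rng.uniform(0, 1000)),
            resource_followup_cost=float(rng.uniform(0, 20000)),
        ),
        end_of_life=EndOfLifeComponents(
            treatment_cost=float(rng.uniform(0, 2000)),
            visit_cost=float(rng.uniform(0, 2000)),
        ),
        treatment_override_by_course=override,
    )


def zeroed_inputs() -> ModelInputs:
    """A degenerate all-zero-cost fixture (one course, nothing costed)."""
    return ModelInputs(
        epidemiology=EpidemiologySpec(
            population=1000,
            prevalence_per_100k=10.0,
            incidence_per_100k=2.0,
            diagnostic_rate=0.5,
        ),
        courses=[
            DiseaseCourseSpec(
                label="only",
                proportion=1.0,
                median_survival_months=24.0,
                exacerbations_per_year=0.0,
            )
        ],
        exacerbation=ExacerbationComponents(
            diagnosis_cost=0.0, treatment_cost=0.0, resource_followup_cost=0.0
        ),
        end_of_life=EndOfLifeComponents(treatment_cost=0.0, visit_cost=0.0),
    )
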