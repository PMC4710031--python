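"""Independent brute-force oracle for the cost model.

Enumerates every atomic cost contribution as a flat (course, category,
amount) record and sums with plain Python loops — no calls into the
package's component functions.  Used to cross-check the implementation on
randomized fixtures.
"""

from __future__ import annotations

from ipfcost.model_io import ModelInputs

CATEGORIES = ("diagnosis", "treatment", "monitoring", "exacerbations", "end_of_life")

AE_THRESHOLD = 0.05


def flat_records(inputs: ModelInputs) -> list[tuple[str, str, float]]:
    records: list[tuple[str, str, float]] = []
    mean_cost = {e.resource_id: e.cost_mean for e in inputs.unit_costs}
    epi = inputs.epidemiology
    ratio = epi.incidence_per_100k / epi.prevalence_per_100k
    override = inputs.treatment_override_by_course or {}

    for course in inputs.courses:
        label = course.label

        for item in inputs.diagnosis_use:
            records.append(
                (label, "diagnosis", item.quantity * mean_cost[item.resource_id] * ratio)
            )

        if label in override:
            records.append((label, "treatment", override[label]))
        else:
            for drug in inputs.drugs:
                pct = drug.pct_patients_by_course.get(label)
                if pct is None:
                    continue
                records.append(
                    (
                        label,
                        "treatment",
                        pct * drug.unit_cost * drug.daily_dose_units * drug.duration_days,
                    )
                )
                for ae in inputs.adverse_events_by_drug.get(drug.drug_id, []):
                    if ae.grade < 3 or ae.pct_patients <= AE_THRESHOLD:
                        continue
                    if ae.grade == 4:
                        per_event = ae.cost_hospitalized
                    else:
                        per_event = (
                            ae.hospitalized_fraction * ae.cost_hospitalized
                            + (1 - ae.hospitalized_fraction) * ae.cost_nonhospitalized
                        )
                    records.append(
                        (label, "treatment", pct * ae.pct_patients * per_event)
                    )
            for therapy in inputs.nonpharma:
                pct = therapy.pct_patients_by_course.get(label, 0.0)
                records.append((label, "treatment", pct * therapy.unit_cost))

        for item in inputs.monitoring_use_by_course.get(label, []):
            records.append(
                (
                    label,
                    "monitoring",
                    item.quantity
                    * mean_cost[item.resource_id]
                    * 12.0
                    / item.period_months,
                )
            )

        exc = inputs.exacerbation
        per_event = exc.diagnosis_cost + exc.treatment_cost + exc.resource_followup_cost
        records.append((label, "exacerbations", per_event * course.exacerbations_per_year))

        eol = inputs.end_of_life
        mortality = min(12.0 / course.median_survival_months, 1.0)
        records.append(
            (label, "end_of_life", (eol.treatment_cost + eol.visit_cost) * mortality)
        )
    return records


def oracle_component(inputs: ModelInputs, course_label: str, category: str) -> float:
    return sum(
        amount
        for label, cat, amount in flat_records(inputs)
        if label == course_label and cat == category
    )


def oracle_course_total(inputs: ModelInputs, course_label: str) -> float:
    return sum(
        amount for label, _, amount in flat_records(inputs) if label == course_label
    )


def oracle_weighted_total(inputs: ModelInputs) -> float:
    proportions = {c.label: c.proportion for c in inputs.courses}
    return sum(
        proportions[label] * amount for label, _, amount in flat_records(inputs)
    )
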