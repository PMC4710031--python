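import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipfcost.cost_components import (
    adverse_event_annual_cost,
    course_cost_vector,
    diagnosis_annual_cost,
    drug_annual_cost,
    eol_annual_cost,
    eol_lump_cost,
    exacerbation_annual_cost,
    exacerbation_event_cost,
    monitoring_annual_cost,
    nonpharma_annual_cost,
    resource_block_cost,
)
from ipfcost.errors import DomainError, ReferenceResolutionError
from ipfcost.model_io import (
    AdverseEventSpec,
    DrugRegimen,
    EndOfLifeComponents,
    ExacerbationComponents,
    NonPharmaTherapy,
    ResourceUseItem,
    UnitCostEntry,
)

from conftest import make_random_inputs, zeroed_inputs
from flat_oracle import CATEGORIES, oracle_component


def _costs(**mean_by_id):
    return {
        rid: UnitCostEntry(resource_id=rid, cost_mean=m, cost_min=m, cost_max=m)
        for rid, m in mean_by_id.items()
    }


class TestResourceBlockCost:
    def test_empty(self):
        assert resource_block_cost([], {}) == 0.0

    def test_single_item(self):
        items = [ResourceUseItem(resource_id="a", quantity=2.0)]
        assert resource_block_cost(items, _costs(a=100.0)) == 200.0

    def test_three_item_enumeration(self):
        # 2 x 50 + 1 x 300 + 0.5 x 80 = 440
        items = [
            ResourceUseItem(resource_id="a", quantity=2.0),
            ResourceUseItem(resource_id="b", quantity=1.0),
            ResourceUseItem(resource_id="c", quantity=0.5),
        ]
        assert resource_block_cost(items, _costs(a=50.0, b=300.0, c=80.0)) == 440.0

    def test_dangling_id(self):
        items = [ResourceUseItem(resource_id="ghost", quantity=1.0)]
        with pytest.raises(ReferenceResolutionError):
            resource_block_cost(items, _costs(a=1.0))


class TestDiagnosisAnnualCost:
    def test_published_quarter_ratio(self):
        # 4,736 x 0.25 -> 1,184 per patient-year
        assert diagnosis_annual_cost(4736.0, 0.25) == 1184.0

    def test_identity_and_zero(self):
        assert diagnosis_annual_cost(123.4, 1.0) == 123.4
        assert diagnosis_annual_cost(123.4, 0.0) == 0.0

    def test_negative_ratio_rejected(self):
        with pytest.raises(DomainError):
            diagnosis_annual_cost(100.0, -0.1)


class TestDrugAnnualCost:
    def test_zero_uptake(self):
        regimen = DrugRegimen(
            drug_id="d",
            pct_patients_by_course={"stable": 0.0},
            unit_cost=1.0,
            daily_dose_units=3.0,
            duration_days=365.0,
        )
        assert drug_annual_cost(regimen, "stable") == 0.0

    def test_full_uptake_chronic(self):
        regimen = DrugRegimen(
            drug_id="d",
            pct_patients_by_course={"c": 1.0},
            unit_cost=1.0,
            daily_dose_units=3.0,
            duration_days=365.0,
        )
        assert drug_annual_cost(regimen, "c") == 1095.0

    def test_half_uptake(self):
        regimen = DrugRegimen(
            drug_id="d",
            pct_patients_by_course={"c": 0.5},
            unit_cost=0.10,
            daily_dose_units=2.0,
            duration_days=300.0,
        )
        assert drug_annual_cost(regimen, "c") == pytest.approx(30.0)

    def test_unknown_course(self):
        regimen = DrugRegimen(
            drug_id="d",
            pct_patients_by_course={"c": 0.5},
            unit_cost=1.0,
            daily_dose_units=1.0,
            duration_days=1.0,
        )
        with pytest.raises(ReferenceResolutionError):
            drug_annual_cost(regimen, "other")


class TestAdverseEventCost:
    def test_only_mild_events_cost_nothing(self):
        aes = [
            AdverseEventSpec(ae_id="pain", grade=1, pct_patients=0.05),
            AdverseEventSpec(ae_id="intolerance", grade=2, pct_patients=0.08),
        ]
        assert adverse_event_annual_cost(aes, 1.0) == 0.0

    def test_boundary_five_percent_excluded(self):
        aes = [
            AdverseEventSpec(
                ae_id="infection",
                grade=3,
                pct_patients=0.05,
                cost_nonhospitalized=74.66,
                cost_hospitalized=7085.52,
                hospitalized_fraction=0.5,
            )
        ]
        assert adverse_event_annual_cost(aes, 1.0) == 0.0
        assert adverse_event_annual_cost(aes, 1.0, include_at_threshold=True) > 0.0

    def test_grade3_nonhospitalized(self):
        # 0.18 x 89.43 = 16.0974
        aes = [
            AdverseEventSpec(
                ae_id="osteoporosis",
                grade=3,
                pct_patients=0.18,
                cost_nonhospitalized=89.43,
                cost_hospitalized=3495.47,
                hospitalized_fraction=0.0,
            )
        ]
        assert adverse_event_annual_cost(aes, 1.0) == pytest.approx(16.0974)

    def test_grade3_hospitalization_split(self):
        aes = [
            AdverseEventSpec(
                ae_id="x",
                grade=3,
                pct_patients=0.10,
                cost_nonhospitalized=100.0,
                cost_hospitalized=1000.0,
                hospitalized_fraction=0.25,
            )
        ]
        # 0.1 x (0.25 x 1000 + 0.75 x 100) = 32.5
        assert adverse_event_annual_cost(aes, 1.0) == pytest.approx(32.5)

    def test_grade4_always_hospitalized(self):
        aes = [
            AdverseEventSpec(
                ae_id="x",
                grade=4,
                pct_patients=0.06,
                cost_nonhospitalized=1.0,
                cost_hospitalized=2000.0,
                hospitalized_fraction=0.0,
            )
        ]
        assert adverse_event_annual_cost(aes, 0.5) == pytest.approx(0.5 * 0.06 * 2000.0)

    @given(
        pct=st.floats(min_value=0, max_value=1),
        grade=st.integers(min_value=1, max_value=4),
    )
    def test_monotone_exclusion(self, pct, grade):
        """Dropping frequency to <=5 % or grade to <=2 never raises the cost."""
        ae = AdverseEventSpec(
            ae_id="x",
            grade=grade,
            pct_patients=pct,
            cost_nonhospitalized=50.0,
            cost_hospitalized=900.0,
            hospitalized_fraction=0.3,
        )
        full = adverse_event_annual_cost([ae], 1.0)
        lowered_pct = ae.model_copy(update={"pct_patients": 0.05})
        lowered_grade = ae.model_copy(update={"grade": 2})
        assert adverse_event_annual_cost([lowered_pct], 1.0) <= full
        assert adverse_event_annual_cost([lowered_grade], 1.0) <= full


class TestNonPharma:
    def test_zero_uptake_course(self):
        therapy = NonPharmaTherapy(
            therapy_id="transplant",
            pct_patients_by_course={"stable": 0.0, "rapid": 0.08},
            unit_cost=100_000.0,
        )
        assert nonpharma_annual_cost([therapy], "stable") == 0.0
        assert nonpharma_annual_cost([therapy], "rapid") == pytest.approx(8000.0)

    def test_empty(self):
        assert nonpharma_annual_cost([], "any") == 0.0


class TestMonitoring:
    def test_all_zero_quantities(self):
        items = [ResourceUseItem(resource_id="v", quantity=0.0, period_months=3.0)]
        assert monitoring_annual_cost(items, _costs(v=100.0)) == 0.0

    def test_quarterly_visit_times_four(self):
        items = [ResourceUseItem(resource_id="v", quantity=1.0, period_months=3.0)]
        assert monitoring_annual_cost(items, _costs(v=100.0)) == pytest.approx(400.0)

    def test_mixed_profile_matches_flat_enumeration(self):
        items = [
            ResourceUseItem(resource_id="v", quantity=2.0, period_months=3.0),
            ResourceUseItem(resource_id="t", quantity=0.5, period_months=6.0),
            ResourceUseItem(resource_id="h", quantity=1.5, period_months=12.0),
        ]
        costs = _costs(v=60.0, t=200.0, h=900.0)
        expected = 2.0 * 60.0 * 4 + 0.5 * 200.0 * 2 + 1.5 * 900.0 * 1
        assert monitoring_annual_cost(items, costs) == pytest.approx(expected)

    def test_one_off_item_rejected(self):
        items = [ResourceUseItem(resource_id="v", quantity=1.0)]
        with pytest.raises(DomainError):
            monitoring_annual_cost(items, _costs(v=1.0))


class TestExacerbation:
    def test_published_event_cost(self):
        c = ExacerbationComponents(
            diagnosis_cost=339.0, treatment_cost=305.0, resource_followup_cost=11074.0
        )
        assert exacerbation_event_cost(c) == 11_718.0

    def test_trivial_sums(self):
        assert exacerbation_event_cost(
            ExacerbationComponents(
                diagnosis_cost=1, treatment_cost=2, resource_followup_cost=3
            )
        ) == 6.0

    @pytest.mark.parametrize(
        "rate,expected", [(0.0, 0.0), (1.0, 11718.0), (0.76, 8905.68)]
    )
    def test_annualization(self, rate, expected):
        assert exacerbation_annual_cost(11718.0, rate) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            exacerbation_annual_cost(100.0, -1.0)


class TestEndOfLife:
    def test_published_lump(self):
        c = EndOfLifeComponents(treatment_cost=463.0, visit_cost=864.0)
        assert eol_lump_cost(c) == 1_327.0

    def test_rapid_course_annualization(self):
        # published cell is 1,061.62; the 2-cent gap comes from the source's
        # own unrounded lump sum
        assert eol_annual_cost(1327.0, 0.80) == pytest.approx(1061.62, abs=0.05)

    def test_identity_and_zero(self):
        assert eol_annual_cost(500.0, 1.0) == 500.0
        assert eol_annual_cost(500.0, 0.0) == 0.0

    def test_mortality_out_of_range(self):
        with pytest.raises(DomainError):
            eol_annual_cost(100.0, 1.2)


class TestCourseCostVector:
    def test_zeroed_fixture_all_zero(self):
        vec = course_cost_vector(zeroed_inputs(), "only")
        assert vec.as_dict() == {cat: 0.0 for cat in CATEGORIES}

    def test_unknown_course(self, baseline):
        with pytest.raises(ReferenceResolutionError):
            course_cost_vector(baseline, "nonexistent")

    def test_diagnosis_component_course_invariant(self, baseline):
        diagnoses = {
            label: course_cost_vector(baseline, label).diagnosis
            for label in baseline.course_labels()
        }
        assert len(set(diagnoses.values())) == 1

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("with_override", [False, True])
    def test_matches_flat_oracle(self, seed, with_override):
        rng = np.random.default_rng(seed)
        inputs = make_random_inputs(rng, with_override=with_override)
        for course in inputs.course_labels():
            vec = course_cost_vector(inputs, course).as_dict()
            for cat in CATEGORIES:
                assert vec[cat] == pytest.approx(
                    oracle_component(inputs, course, cat), rel=1e-12, abs=1e-9
                )

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000), k=st.floats(min_value=0.1, max_value=10))
    def test_linear_in_unit_costs(self, seed, k):
        """Scaling all unit costs by k scales resource-backed components by k."""
        rng = np.random.default_rng(seed)
        inputs = make_random_inputs(rng)
        scaled = inputs.model_copy(deep=True)
        scaled.unit_costs = [
            e.model_copy(
                update={
                    "cost_mean": e.cost_mean * k,
                    "cost_min": e.cost_min * k,
                    "cost_max": e.cost_max * k,
                }
            )
            for e in scaled.unit_costs
        ]
        for course in inputs.course_labels():
            base = course_cost_vector(inputs, course)
            after = course_cost_vector(scaled, course)
            assert after.diagnosis == pytest.approx(k * base.diagnosis, rel=1e-9)
            assert after.monitoring == pytest.approx(k * base.monitoring, rel=1e-9)
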