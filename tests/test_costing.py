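"""Course pricing: dose rules, currency, exposure, comparator subtraction."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from oncobudget import (
    EvidenceIncompleteError,
    PatientProfile,
    REFERENCE_PATIENT,
    Regimen,
    RegimenComponent,
    Setting,
    TrialEvidence,
    convert_to_usd,
    course_cost,
    dose_per_administration,
    horizon_excess_cost,
    is_conventional_excluded,
    palliative_exposure_months,
)
from oncobudget.costing import CourseCost, cycles_for_exposure


def _component(**kw):
    defaults = dict(
        drug_name="x", dose_rule="flat_per_admin", dose_value_mg=100.0,
        administrations_per_cycle=1, cycle_length_days=21.0,
        unit_price=1.0, currency="USD",
    )
    defaults.update(kw)
    return RegimenComponent(**defaults)


@pytest.mark.parametrize(
    "rule,value,expected",
    [
        ("flat_per_admin", 1000.0, 1000.0),  # flat dose ignores the patient
        ("per_kg", 6.0, 300.0),              # 6 mg/kg x 50 kg
        ("per_m2", 175.0, 227.5),            # 175 mg/m2 x 1.3 m2
    ],
)
def test_dose_per_administration_reference_patient(rule, value, expected):
    comp = _component(dose_rule=rule, dose_value_mg=value)
    assert dose_per_administration(comp, REFERENCE_PATIENT) == pytest.approx(expected)


@pytest.mark.parametrize("lkr,usd", [(200.0, 1.0), (0.0, 0.0), (756000.0, 3780.0)])
def test_convert_to_usd_2021_rate(ctx, lkr, usd):
    assert convert_to_usd(lkr, ctx) == pytest.approx(usd)


def test_exposure_prefers_reported_treatment_duration():
    ev = TrialEvidence(outcome_measure="OS", gain_value=5.0,
                       median_treatment_duration_months=13.3, median_pfs_months=4.0)
    assert palliative_exposure_months(ev) == 13.3


def test_exposure_falls_back_to_median_pfs():
    ev = TrialEvidence(outcome_measure="PFS", gain_value=5.4, median_pfs_months=5.4)
    assert palliative_exposure_months(ev) == 5.4


def test_exposure_error_names_indication_when_nothing_reported():
    ev = TrialEvidence(outcome_measure="OS", gain_value=5.0)
    with pytest.raises(EvidenceIncompleteError, match="lung_1l"):
        palliative_exposure_months(ev, indication="lung_1l")


def test_started_cycle_is_dispensed_in_full():
    # 5.4 months at a 21-day cadence: 5.4*30.44/21 = 7.83 -> 8 cycles
    assert cycles_for_exposure(5.4, 21.0) == 8
    assert cycles_for_exposure(0.0, 21.0) == 0


def test_curative_course_cost_arithmetic(ctx):
    """flat 100 mg/admin, 1 admin per 21-day cycle, 6 planned cycles, 1 USD/mg."""
    reg = Regimen(components=[_component()], setting=Setting.curative, planned_cycles=6)
    ev = TrialEvidence(outcome_measure="DFS", gain_value=0.1, follow_up_years=5,
                       mean_age_at_diagnosis_years=50)
    cost = course_cost(reg, ev, REFERENCE_PATIENT, ctx)
    assert cost.gross_usd == pytest.approx(600.0)
    assert cost.net_usd == pytest.approx(600.0)
    assert cost.n_cycles_used == 6


def test_substitutive_course_subtracts_comparator(ctx):
    comparator = Regimen(
        components=[_component(drug_name="old", dose_value_mg=100.0, unit_price=1.0 / 6)],
        setting=Setting.curative, planned_cycles=6,
    )
    reg = Regimen(components=[_component()], setting=Setting.curative,
                  planned_cycles=6, additive=False, comparator=comparator)
    ev = TrialEvidence(outcome_measure="DFS", gain_value=0.1, follow_up_years=5,
                       mean_age_at_diagnosis_years=50)
    cost = course_cost(reg, ev, REFERENCE_PATIENT, ctx)
    assert cost.gross_usd == pytest.approx(600.0)
    assert cost.comparator_usd == pytest.approx(100.0)
    assert cost.net_usd == pytest.approx(500.0)


def test_additive_regimen_ignores_comparator_cost(ctx):
    comparator = Regimen(components=[_component(unit_price=50.0)],
                         setting=Setting.curative, planned_cycles=6)
    reg = Regimen(components=[_component()], setting=Setting.curative,
                  planned_cycles=6, additive=True, comparator=comparator)
    ev = TrialEvidence(outcome_measure="DFS", gain_value=0.1, follow_up_years=5,
                       mean_age_at_diagnosis_years=50)
    cost = course_cost(reg, ev, REFERENCE_PATIENT, ctx)
    assert cost.net_usd == cost.gross_usd
    assert cost.comparator_usd == 0.0


def _course(net):
    return CourseCost(gross_usd=net, comparator_usd=0.0, net_usd=net, n_cycles_used=1)


@pytest.mark.parametrize("net,excluded", [(180.0, True), (1000.0, False), (1502.0, False)])
def test_conventional_exclusion_is_strictly_below_1000(net, excluded):
    """Cheap conventional agents (imatinib-like, 180 USD/yr) drop out; the
    boundary itself is retained."""
    assert is_conventional_excluded(_course(net)) is excluded


@pytest.mark.parametrize(
    "novel,comp,years,expected",
    [(5480.0, 180.0, 10.0, 53000.0), (1000.0, 0.0, 3.0, 3000.0), (250.0, 250.0, 7.0, 0.0)],
)
def test_horizon_excess_cost(novel, comp, years, expected):
    assert horizon_excess_cost(novel, comp, years) == pytest.approx(expected)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    k=st.floats(min_value=0.1, max_value=100.0),
    price=st.floats(min_value=0.01, max_value=50.0),
    months=st.floats(min_value=0.5, max_value=36.0),
)
def test_price_homogeneity(ctx, k, price, months):
    """Scaling every unit price by k scales gross, comparator and net by k."""
    def build(p):
        comparator = Regimen(
            components=[_component(drug_name="old", unit_price=p * 0.3)],
            setting=Setting.palliative,
        )
        return Regimen(components=[_component(unit_price=p)], setting=Setting.palliative,
                       comparator=comparator)

    ev = TrialEvidence(outcome_measure="OS", gain_value=6.0,
                       median_treatment_duration_months=months)
    base = course_cost(build(price), ev, REFERENCE_PATIENT, ctx)
    scaled = course_cost(build(price * k), ev, REFERENCE_PATIENT, ctx)
    assert scaled.gross_usd == pytest.approx(k * base.gross_usd, rel=1e-9)
    assert scaled.comparator_usd == pytest.approx(k * base.comparator_usd, rel=1e-9)
    assert scaled.net_usd == pytest.approx(k * base.net_usd, rel=1e-9)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    m1=st.floats(min_value=0.1, max_value=24.0),
    extra=st.floats(min_value=0.0, max_value=24.0),
)
def test_longer_exposure_never_cheaper(ctx, m1, extra):
    reg = Regimen(components=[_component()], setting=Setting.palliative)

    def gross(months):
        ev = TrialEvidence(outcome_measure="OS", gain_value=6.0,
                           median_treatment_duration_months=months)
        return course_cost(reg, ev, REFERENCE_PATIENT, ctx).gross_usd

    assert gross(m1 + extra) >= gross(m1)
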