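"""Catalog domain types, validation and file round-trips."""

import pandas as pd
import pytest
from pydantic import ValidationError

from oncobudget import (
    Category,
    CatalogSchemaError,
    CatalogValidationError,
    EconomicContext,
    IndicationAssessment,
    Regimen,
    RegimenComponent,
    Setting,
    read_catalog,
    read_league_table,
    write_catalog,
    write_league_table,
)
from oncobudget.catalog import CSV_COLUMNS


def test_fixture_has_published_row_counts(fixture_rows):
    """The transcribed league tables carry 17 + 14 = 31 indication rows."""
    assert len(fixture_rows) == 31
    assert sum(r.table == 1 for r in fixture_rows) == 17
    assert sum(r.table == 2 for r in fixture_rows) == 14


def test_empty_catalog_file_reads_as_empty_list(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(",".join(CSV_COLUMNS) + "\n")
    assert read_catalog(path) == []


def test_catalog_write_read_round_trip(tmp_path, small_catalog):
    """Generated records survive a CSV write/read unchanged, in row order."""
    records, _ = small_catalog
    path = tmp_path / "catalog.csv"
    write_catalog(records, path)
    back = read_catalog(path)
    assert len(back) == len(records)
    for orig, rt in zip(records, back):
        assert rt.indication_id == orig.indication_id
        assert rt.option_group == orig.option_group
        assert rt.patient_estimates == orig.patient_estimates
        assert rt.evidence == orig.evidence
        assert rt.regimen.components == orig.regimen.components
        assert rt.regimen.setting == orig.regimen.setting
        assert rt.regimen.additive == orig.regimen.additive
        if orig.regimen.comparator is None:
            assert rt.regimen.comparator is None
        else:
            assert rt.regimen.comparator.components == orig.regimen.comparator.components


def test_patient_estimates_round_trip(tmp_path, small_catalog):
    records, _ = small_catalog
    rec = records[0].model_copy(update={"patient_estimates": [880.0, 880.0, 880.0]})
    path = tmp_path / "one.csv"
    write_catalog([rec], path)
    (back,) = [r for r in read_catalog(path) if r.indication_id == rec.indication_id]
    assert back.patient_estimates == [880.0, 880.0, 880.0]


def test_missing_mandatory_column_names_the_column(tmp_path):
    path = tmp_path / "bad.csv"
    cols = [c for c in CSV_COLUMNS if c != "unit_price"]
    path.write_text(",".join(cols) + "\n")
    with pytest.raises(CatalogSchemaError, match="unit_price"):
        read_catalog(path)


def test_negative_price_reports_row_index(tmp_path, small_catalog):
    records, _ = small_catalog
    path = tmp_path / "neg.csv"
    write_catalog(records[:2], path)
    df = pd.read_csv(path)
    df.loc[1, "unit_price"] = -5.0
    df.to_csv(path, index=False)
    with pytest.raises(CatalogValidationError, match="row 1"):
        read_catalog(path)


def test_curative_regimen_requires_planned_cycles():
    comp = RegimenComponent(
        drug_name="x", dose_rule="flat_per_admin", dose_value_mg=100,
        administrations_per_cycle=1, cycle_length_days=21, unit_price=1, currency="USD",
    )
    with pytest.raises(ValidationError):
        Regimen(components=[comp], setting=Setting.curative, planned_cycles=None)


def test_economic_context_rejects_bad_multipliers():
    with pytest.raises(ValidationError):
        EconomicContext(
            gdp_per_capita_usd=3815, exchange_rate_lkr_per_usd=200,
            life_expectancy_years=77, threshold_multipliers=(3, 1, 4),
        )
    with pytest.raises(ValidationError):
        EconomicContext(
            gdp_per_capita_usd=3815, exchange_rate_lkr_per_usd=0,
            life_expectancy_years=77,
        )


def _mk_assessment(drug, frac, **kw):
    defaults = dict(
        indication_id=drug, option_group=drug, drug_name=drug,
        setting=Setting.palliative, course_cost_usd=1000.0, ly_gained=1.0,
        cost_per_ly_usd=frac * 3815.0, gdp_fraction=frac,
        category=Category.highly_cost_effective, n_patients=10,
        annual_cost_usd=10000.0,
    )
    defaults.update(kw)
    return IndicationAssessment(**defaults)


def test_league_table_round_trip_preserves_two_decimals(tmp_path, assessments):
    path = tmp_path / "league.csv"
    write_league_table(assessments, path)
    back = read_league_table(path)
    by_id = {a.indication_id: a for a in back}
    assert len(back) == len(assessments)
    for a in assessments:
        b = by_id[a.indication_id]
        for field in ("course_cost_usd", "cost_per_ly_usd", "gdp_fraction",
                      "ly_gained", "annual_cost_usd"):
            assert getattr(b, field) == pytest.approx(getattr(a, field), abs=0.00501)
        assert b.n_patients == a.n_patients


def test_league_table_sorted_by_gdp_fraction_first_row_is_rituximab(tmp_path, assessments):
    """The cheapest palliative option per life-year leads the published table."""
    path = tmp_path / "league.csv"
    write_league_table(assessments, path)
    df = pd.read_csv(path)
    frac = df["gdp_fraction"].to_numpy()
    cats = df["category"].tolist()
    # ascending within each category block
    for i in range(1, len(df)):
        if cats[i] == cats[i - 1]:
            assert frac[i] >= frac[i - 1]
    palliative = df[df["setting"] == "palliative"]
    assert palliative.iloc[0]["indication_id"] == "rituximab_maintenance_fl"
    assert palliative.iloc[0]["gdp_fraction"] == pytest.approx(0.06)


def test_league_table_tie_broken_by_drug_name(tmp_path):
    a = _mk_assessment("zeta", 0.5)
    b = _mk_assessment("alpha", 0.5)
    path = tmp_path / "tie.csv"
    write_league_table([a, b], path)
    df = pd.read_csv(path)
    assert df["drug_name"].tolist() == ["alpha", "zeta"]


def test_league_table_single_row(tmp_path):
    path = tmp_path / "one.csv"
    write_league_table([_mk_assessment("solo", 0.2)], path)
    assert len(pd.read_csv(path)) == 1
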