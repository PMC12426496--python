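"""Domain types, validation and I/O for the drug-indication catalog.

The catalog describes, per indication-option, a dosing regimen (enough to
price a full treatment course for a reference patient), the pivotal-trial
evidence from which survival gain is read, and per-expert patient-number
estimates.  The economic context carries the country-year constants
(per-capita GDP, exchange rate, life expectancy, threshold multipliers).

Two catalog dialects are supported:

* ``csv`` — flat UTF-8 comma-separated file, "." decimal mark, no thousands
  separators; one row per regimen component.  Rows sharing ``indication_id``
  are merged into a single record (multi-component regimens).  Rows whose
  ``indication_id`` is referenced by another row's ``comparator_id`` and
  which carry no patient estimates define comparator regimens, not
  indications.
* ``json`` — a list of nested record objects mirroring the domain types.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Setting",
    "DoseRule",
    "OutcomeMeasure",
    "Category",
    "CATEGORY_ORDER",
    "PatientProfile",
    "REFERENCE_PATIENT",
    "EconomicContext",
    "RegimenComponent",
    "Regimen",
    "TrialEvidence",
    "IndicationRecord",
    "IndicationAssessment",
    "CatalogSchemaError",
    "CatalogValidationError",
    "read_catalog",
    "write_catalog",
    "read_economic_context",
    "write_league_table",
    "read_league_table",
    "round_half_up",
]


class CatalogSchemaError(ValueError):
    """The catalog file does not conform to the documented schema."""


class CatalogValidationError(ValueError):
    """A catalog row violates a domain-type invariant."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention printed reports use).

    Python's builtin ``round`` is banker's rounding; report columns follow
    the half-up convention instead (100.5 patients -> 101).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class Setting(str, enum.Enum):
    curative = "curative"
    palliative = "palliative"


class DoseRule(str, enum.Enum):
    flat_per_admin = "flat_per_admin"
    per_kg = "per_kg"
    per_m2 = "per_m2"


class OutcomeMeasure(str, enum.Enum):
    OS = "OS"
    PFS = "PFS"
    DFS = "DFS"
    DSS = "DSS"
    RMST = "RMST"


class Category(str, enum.Enum):
    highly_cost_effective = "highly_cost_effective"
    cost_effective = "cost_effective"
    potentially_cost_effective = "potentially_cost_effective"
    not_cost_effective = "not_cost_effective"


#: Categories from cheapest-looking to most expensive per life-year.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.highly_cost_effective,
    Category.cost_effective,
    Category.potentially_cost_effective,
    Category.not_cost_effective,
)


class PatientProfile(BaseModel):
    """Reference patient used to resolve weight- and BSA-based dosing."""

    weight_kg: float = Field(gt=0)
    body_surface_area_m2: float = Field(gt=0)


#: Standard reference patient: adult male, 50 kg, 1.3 m².
REFERENCE_PATIENT = PatientProfile(weight_kg=50.0, body_surface_area_m2=1.3)


class EconomicContext(BaseModel):
    """Country-year economic constants for one analysis run."""

    gdp_per_capita_usd: float = Field(gt=0)
    exchange_rate_lkr_per_usd: float = Field(gt=0)
    life_expectancy_years: float = Field(gt=0)
    threshold_multipliers: tuple[float, ...] = (1.0, 3.0, 4.0)
    reference_year: int = 2021

    @field_validator("threshold_multipliers")
    @classmethod
    def _strictly_increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v or any(m <= 0 for m in v):
            raise ValueError("threshold multipliers must be positive")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("threshold multipliers must be strictly increasing")
        return tuple(v)


class RegimenComponent(BaseModel):
    """One drug line of a regimen: dosing rule, schedule and unit price."""

    drug_name: str
    dose_rule: DoseRule
    dose_value_mg: float = Field(ge=0, description="mg per the rule's unit")
    administrations_per_cycle: int = Field(ge=1)
    cycle_length_days: float = Field(gt=0)
    unit_price: float = Field(ge=0, description="price per mg")
    currency: str = "LKR"

    @field_validator("currency")
    @classmethod
    def _known_currency(cls, v: str) -> str:
        if v not in ("LKR", "USD"):
            raise ValueError(f"unsupported currency {v!r}")
        return v


class Regimen(BaseModel):
    """A priced treatment: components, setting, protocol length, comparator."""

    components: list[RegimenComponent] = Field(min_length=1)
    setting: Setting
    planned_cycles: Optional[int] = Field(default=None, ge=1)
    additive: bool = False
    comparator: Optional["Regimen"] = None

    @model_validator(mode="after")
    def _check(self) -> "Regimen":
        # Curative protocols are fixed in advance; the costing engine needs
        # planned_cycles, so fail early here rather than mid-pipeline.
        if self.setting is Setting.curative and self.planned_cycles is None:
            raise ValueError("curative regimen requires planned_cycles")
        return self


class TrialEvidence(BaseModel):
    """Pivotal-trial outcome data for one indication.

    ``gain_value`` is months of median/mean survival gain in the palliative
    setting, or a survival-proportion gain in [0, 1] at end of follow-up in
    the curative setting.  ``toxicity_grade3plus`` and ``esmo_mcbs`` are
    pass-through metadata.
    """

    outcome_measure: OutcomeMeasure
    gain_value: float = Field(ge=0)
    follow_up_years: Optional[float] = Field(default=None, gt=0)
    crossover: bool = False
    median_treatment_duration_months: Optional[float] = Field(default=None, ge=0)
    median_pfs_months: Optional[float] = Field(default=None, ge=0)
    mean_age_at_diagnosis_years: Optional[float] = Field(default=None, gt=0)
    toxicity_grade3plus: Optional[float] = Field(default=None, ge=0, le=1)
    esmo_mcbs: Optional[str] = None


class IndicationRecord(BaseModel):
    """One indication-option: regimen + evidence + patient estimates."""

    indication_id: str
    option_group: str
    drug_name: str
    regimen: Regimen
    evidence: TrialEvidence
    patient_estimates: list[float] = Field(min_length=1)

    @field_validator("patient_estimates")
    @classmethod
    def _non_negative(cls, v: list[float]) -> list[float]:
        if any(e < 0 for e in v):
            raise ValueError("patient estimates must be non-negative")
        return v

    @model_validator(mode="after")
    def _evidence_matches_setting(self) -> "IndicationRecord":
        ev, setting = self.evidence, self.regimen.setting
        if setting is Setting.curative:
            if not 0.0 <= ev.gain_value <= 1.0:
                raise ValueError(
                    f"{self.indication_id}: curative gain must be a proportion in [0, 1]"
                )
            if ev.follow_up_years is None:
                raise ValueError(f"{self.indication_id}: curative evidence needs follow_up_years")
        return self


class IndicationAssessment(BaseModel):
    """The computed record for one indication-option — one league-table row."""

    indication_id: str
    option_group: str
    drug_name: str
    setting: Setting
    course_cost_usd: float
    ly_gained: float
    cost_per_ly_usd: float
    gdp_fraction: float
    category: Category
    n_patients: int
    annual_cost_usd: float
    basis: Optional[str] = None


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "indication_id",
    "option_group",
    "drug_name",
    "setting",
    "dose_rule",
    "dose_value_mg",
    "admins_per_cycle",
    "cycle_days",
    "planned_cycles",
    "unit_price",
    "currency",
    "additive",
    "comparator_id",
    "outcome_measure",
    "gain_value",
    "gain_unit",
    "follow_up_years",
    "crossover",
    "median_tx_months",
    "median_pfs_months",
    "age_dx_years",
    "estimates",
]

_MANDATORY = [
    "indication_id",
    "option_group",
    "drug_name",
    "setting",
    "dose_rule",
    "dose_value_mg",
    "admins_per_cycle",
    "cycle_days",
    "unit_price",
    "outcome_measure",
    "gain_value",
    "estimates",
]


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return False
    return str(v).strip().lower() in ("true", "1", "yes")


def _component_from_row(row: pd.Series, idx: int) -> RegimenComponent:
    dose = float(row["dose_value_mg"])
    price = float(row["unit_price"])
    if dose < 0:
        raise CatalogValidationError(f"row {idx}: negative dose_value_mg {dose}")
    if price < 0:
        raise CatalogValidationError(f"row {idx}: negative unit_price {price}")
    return RegimenComponent(
        drug_name=str(row["drug_name"]),
        dose_rule=DoseRule(str(row["dose_rule"])),
        dose_value_mg=dose,
        administrations_per_cycle=int(row["admins_per_cycle"]),
        cycle_length_days=float(row["cycle_days"]),
        unit_price=price,
        currency=str(row.get("currency") or "LKR"),
    )


def _parse_estimates(raw) -> list[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return []
    s = str(raw).strip()
    if not s:
        return []
    return [float(tok) for tok in s.split(";") if tok.strip() != ""]


def read_catalog(path: str | Path, schema: str = "csv") -> list[IndicationRecord]:
    """Read a drug-indication catalog; returns validated records in row order.

    Raises :class:`CatalogSchemaError` for a missing mandatory column and
    :class:`CatalogValidationError` (with the offending row index) for
    negative doses or prices.
    """
    path = Path(path)
    if schema == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return [IndicationRecord.model_validate(obj) for obj in payload]
    if schema != "csv":
        raise CatalogSchemaError(f"unknown catalog dialect {schema!r}")

    df = pd.read_csv(
        path,
        dtype={"indication_id": str, "option_group": str},
        float_precision="round_trip",
    )
    for col in _MANDATORY:
        if col not in df.columns:
            raise CatalogSchemaError(f"missing mandatory column: {col}")
    if df.empty:
        return []

    comparator_ids = {
        str(v) for v in df.get("comparator_id", pd.Series(dtype=str)).dropna() if str(v).strip()
    }

    # Group component rows by indication_id, preserving first-seen order.
    groups: dict[str, list[tuple[int, pd.Series]]] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        iid = str(row["indication_id"])
        if iid not in groups:
            groups[iid] = []
            order.append(iid)
        groups[iid].append((idx, row))

    def build_regimen(iid: str, resolving: tuple[str, ...] = ()) -> Regimen:
        if iid in resolving:
            raise CatalogValidationError(f"comparator cycle involving {iid!r}")
        rows = groups.get(iid)
        if rows is None:
            raise CatalogValidationError(f"comparator_id {iid!r} not found in catalog")
        first = rows[0][1]
        comp_id = first.get("comparator_id")
        comparator = None
        if comp_id is not None and str(comp_id).strip() and not (
            isinstance(comp_id, float) and math.isnan(comp_id)
        ):
            comparator = build_regimen(str(comp_id), resolving + (iid,))
        planned = _opt_float(first.get("planned_cycles"))
        return Regimen(
            components=[_component_from_row(r, i) for i, r in rows],
            setting=Setting(str(first["setting"])),
            planned_cycles=int(planned) if planned is not None else None,
            additive=_as_bool(first.get("additive")),
            comparator=comparator,
        )

    records: list[IndicationRecord] = []
    for iid in order:
        if iid in comparator_ids and not _parse_estimates(groups[iid][0][1].get("estimates")):
            continue  # comparator-definition row, not an indication
        idx, first = groups[iid][0]
        estimates = _parse_estimates(first.get("estimates"))
        if not estimates:
            raise CatalogValidationError(f"row {idx}: indication {iid!r} has no patient estimates")
        try:
            record = IndicationRecord(
                indication_id=iid,
                option_group=str(first["option_group"]),
                drug_name=str(first["drug_name"]),
                regimen=build_regimen(iid),
                evidence=TrialEvidence(
                    outcome_measure=OutcomeMeasure(str(first["outcome_measure"])),
                    gain_value=float(first["gain_value"]),
                    follow_up_years=_opt_float(first.get("follow_up_years")),
                    crossover=_as_bool(first.get("crossover")),
                    median_treatment_duration_months=_opt_float(first.get("median_tx_months")),
                    median_pfs_months=_opt_float(first.get("median_pfs_months")),
                    mean_age_at_diagnosis_years=_opt_float(first.get("age_dx_years")),
                ),
                patient_estimates=estimates,
            )
        except CatalogValidationError:
            raise
        except ValueError as exc:
            raise CatalogValidationError(f"row {idx}: {exc}") from exc
        records.append(record)
    return records


def _record_rows(record: IndicationRecord, comparator_id: str = "") -> list[dict]:
    rows = []
    ev = record.evidence
    for comp in record.regimen.components:
        rows.append(
            {
                "indication_id": record.indication_id,
                "option_group": record.option_group,
                "drug_name": comp.drug_name,
                "setting": record.regimen.setting.value,
                "dose_rule": comp.dose_rule.value,
                "dose_value_mg": comp.dose_value_mg,
                "admins_per_cycle": comp.administrations_per_cycle,
                "cycle_days": comp.cycle_length_days,
                "planned_cycles": record.regimen.planned_cycles,
                "unit_price": comp.unit_price,
                "currency": comp.currency,
                "additive": record.regimen.additive,
                "comparator_id": comparator_id,
                "outcome_measure": ev.outcome_measure.value,
                "gain_value": ev.gain_value,
                "gain_unit": "proportion"
                if record.regimen.setting is Setting.curative
                else "months",
                "follow_up_years": ev.follow_up_years,
                "crossover": ev.crossover,
                "median_tx_months": ev.median_treatment_duration_months,
                "median_pfs_months": ev.median_pfs_months,
                "age_dx_years": ev.mean_age_at_diagnosis_years,
                "estimates": ";".join(
                    str(int(e)) if float(e).is_integer() else str(e)
                    for e in record.patient_estimates
                ),
            }
        )
    return rows


def write_catalog(records: Sequence[IndicationRecord], path: str | Path) -> None:
    """Write records to the flat CSV dialect (inverse of :func:`read_catalog`).

    Comparator regimens are emitted as estimate-less rows with a derived id
    ``<indication_id>__comparator``.
    """
    rows: list[dict] = []
    comparator_rows: list[dict] = []
    for rec in records:
        comp_id = ""
        comparator = rec.regimen.comparator
        if comparator is not None:
            comp_id = f"{rec.indication_id}__comparator"
            for c in comparator.components:
                comparator_rows.append(
                    {
                        "indication_id": comp_id,
                        "option_group": rec.option_group,
                        "drug_name": c.drug_name,
                        "setting": comparator.setting.value,
                        "dose_rule": c.dose_rule.value,
                        "dose_value_mg": c.dose_value_mg,
                        "admins_per_cycle": c.administrations_per_cycle,
                        "cycle_days": c.cycle_length_days,
                        "planned_cycles": comparator.planned_cycles,
                        "unit_price": c.unit_price,
                        "currency": c.currency,
                        "additive": comparator.additive,
                        "comparator_id": "",
                        "outcome_measure": rec.evidence.outcome_measure.value,
                        "gain_value": rec.evidence.gain_value,
                        "gain_unit": "",
                        "follow_up_years": None,
                        "crossover": False,
                        "median_tx_months": None,
                        "median_pfs_months": None,
                        "age_dx_years": None,
                        "estimates": "",
                    }
                )
        rows.extend(_record_rows(rec, comp_id))

    def fmt(v) -> str:
        # repr round-trips floats exactly; pandas' float formatting does not
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        if isinstance(v, bool):
            return str(v)
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for row in rows + comparator_rows:
            writer.writerow([fmt(row[c]) for c in CSV_COLUMNS])


def read_economic_context(path: str | Path) -> EconomicContext:
    """Load an economic context from a YAML or JSON config file."""
    path = Path(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    aliases = {
        "exchange_rate": "exchange_rate_lkr_per_usd",
        "multipliers": "threshold_multipliers",
    }
    payload = {aliases.get(k, k): v for k, v in payload.items()}
    return EconomicContext.model_validate(payload)


# ---------------------------------------------------------------------------
# League-table I/O
# ---------------------------------------------------------------------------

LEAGUE_COLUMNS = [
    "indication_id",
    "option_group",
    "drug_name",
    "setting",
    "category",
    "ly_gained",
    "course_cost_usd",
    "cost_per_ly_usd",
    "gdp_fraction",
    "n_patients",
    "annual_cost_usd",
]


def write_league_table(assessments: Sequence[IndicationAssessment], path: str | Path) -> None:
    """Write assessments as a league-table CSV.

    Rows are ordered by category (cheapest band first) then ascending GDP
    fraction, ties broken by drug name.  Currency fields are rounded to two
    decimals at write time only.
    """
    if not assessments:
        raise ValueError("no assessments to write")
    ordered = sorted(
        assessments,
        key=lambda a: (CATEGORY_ORDER.index(a.category), a.gdp_fraction, a.drug_name),
    )
    rows = [
        {
            "indication_id": a.indication_id,
            "option_group": a.option_group,
            "drug_name": a.drug_name,
            "setting": a.setting.value,
            "category": a.category.value,
            "ly_gained": round_half_up(a.ly_gained, 2),
            "course_cost_usd": round_half_up(a.course_cost_usd, 2),
            "cost_per_ly_usd": round_half_up(a.cost_per_ly_usd, 2),
            "gdp_fraction": round_half_up(a.gdp_fraction, 2),
            "n_patients": a.n_patients,
            "annual_cost_usd": round_half_up(a.annual_cost_usd, 2),
        }
        for a in ordered
    ]
    pd.DataFrame(rows, columns=LEAGUE_COLUMNS).to_csv(path, index=False)


def read_league_table(path: str | Path) -> list[IndicationAssessment]:
    """Read back a league-table CSV written by :func:`write_league_table`."""
    df = pd.read_csv(path)
    return [
        IndicationAssessment(
            indication_id=str(r["indication_id"]),
            option_group=str(r["option_group"]),
            drug_name=str(r["drug_name"]),
            setting=Setting(str(r["setting"])),
            category=Category(str(r["category"])),
            ly_gained=float(r["ly_gained"]),
            course_cost_usd=float(r["course_cost_usd"]),
            cost_per_ly_usd=float(r["cost_per_ly_usd"]),
            gdp_fraction=float(r["gdp_fraction"]),
            n_patients=int(r["n_patients"]),
            annual_cost_usd=float(r["annual_cost_usd"]),
        )
        for _, r in df.iterrows()
    ]
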