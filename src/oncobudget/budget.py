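"""Patient numbers, annual budgets, best-option selection and the
cumulative affordability curve.

Per-indication annual cost is (net course cost) x (mean of the expert
patient estimates, rounded half-up).  Where several options serve one
indication (an option group: alternative drugs, doses or durations), only
the cheapest per life-year is retained in national totals.  The cumulative
curve ranks retained options by ascending cost per life-year and
accumulates annual cost — the league-table view of what funding up to a
given threshold buys.
"""

from __future__ import annotations

import json
import statistics
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel

from .catalog import (
    CATEGORY_ORDER,
    Category,
    EconomicContext,
    IndicationAssessment,
    IndicationRecord,
    PatientProfile,
    REFERENCE_PATIENT,
    round_half_up,
)
from .cea import ThresholdScheme, UndefinedICERError, cost_per_ly, classify, gdp_fraction
from .costing import (
    CONVENTIONAL_THRESHOLD_USD,
    EvidenceIncompleteError,
    course_cost,
    is_conventional_excluded,
)
from .effectiveness import life_years_gained

__all__ = [
    "BudgetCurve",
    "estimate_patients",
    "annual_indication_cost",
    "assess_indication",
    "assess_catalog",
    "select_best_option",
    "total_under_threshold",
    "totals_by_threshold",
    "cumulative_curve",
    "write_curve_tsv",
]


class BudgetCurve(BaseModel):
    """Cumulative annual cost against GDP fraction, sorted ascending."""

    points: list[tuple[float, float]]
    selection: list[IndicationAssessment]


def estimate_patients(estimates: Sequence[float]) -> int:
    """Pool expert patient-number estimates: arithmetic mean, half-up."""
    if not estimates:
        raise ValueError("need at least one patient estimate")
    if any(e < 0 for e in estimates):
        raise ValueError("patient estimates must be non-negative")
    return int(round_half_up(statistics.fmean(estimates), 0))


def annual_indication_cost(net_course_usd: float, n_patients: int) -> float:
    """National annual cost for one indication: course cost x patients."""
    if n_patients < 0:
        raise ValueError("patient count must be non-negative")
    return net_course_usd * n_patients


def assess_indication(
    record: IndicationRecord,
    ctx: EconomicContext,
    profile: PatientProfile = REFERENCE_PATIENT,
    scheme: Optional[ThresholdScheme] = None,
) -> IndicationAssessment:
    """Run the full per-indication pipeline: cost -> life-years -> CLYG ->
    category -> annual budget."""
    scheme = scheme or ThresholdScheme.from_context(ctx)
    course = course_cost(
        record.regimen, record.evidence, profile, ctx, indication=record.indication_id
    )
    gain = life_years_gained(record.evidence, record.regimen.setting, ctx)
    clyg = cost_per_ly(course, gain)
    n = estimate_patients(record.patient_estimates)
    return IndicationAssessment(
        indication_id=record.indication_id,
        option_group=record.option_group,
        drug_name=record.drug_name,
        setting=record.regimen.setting,
        course_cost_usd=course.net_usd,
        ly_gained=gain.years,
        cost_per_ly_usd=clyg,
        gdp_fraction=gdp_fraction(clyg, ctx),
        category=classify(clyg, scheme),
        n_patients=n,
        annual_cost_usd=annual_indication_cost(course.net_usd, n),
        basis=gain.basis,
    )


def assess_catalog(
    records: Sequence[IndicationRecord],
    ctx: EconomicContext,
    profile: PatientProfile = REFERENCE_PATIENT,
    exclusion_threshold_usd: float = CONVENTIONAL_THRESHOLD_USD,
) -> tuple[list[IndicationAssessment], list[dict]]:
    """Assess every catalog record, applying the conventional-agent filter.

    Returns the assessments plus an exclusion log: one entry per record
    dropped (cheap conventional course, undefined cost per life-year, or
    incomplete evidence), with the offending indication id and reason.
    """
    scheme = ThresholdScheme.from_context(ctx)
    out: list[IndicationAssessment] = []
    exclusions: list[dict] = []
    for rec in records:
        try:
            course = course_cost(
                rec.regimen, rec.evidence, profile, ctx, indication=rec.indication_id
            )
            if is_conventional_excluded(course, exclusion_threshold_usd):
                exclusions.append(
                    {
                        "indication_id": rec.indication_id,
                        "reason": "conventional_cost_below_threshold",
                        "net_usd": course.net_usd,
                    }
                )
                continue
            out.append(assess_indication(rec, ctx, profile, scheme))
        except UndefinedICERError:
            exclusions.append(
                {"indication_id": rec.indication_id, "reason": "undefined_cost_per_ly"}
            )
        except EvidenceIncompleteError as exc:
            exclusions.append(
                {"indication_id": rec.indication_id, "reason": "evidence_incomplete",
                 "detail": str(exc)}
            )
    return out, exclusions


def select_best_option(
    assessments: Sequence[IndicationAssessment],
) -> list[IndicationAssessment]:
    """Keep the cheapest-per-life-year option in each option group.

    Selection is applied jointly across all categories — a group's options
    may sit in different threshold bands, and the retained one is the
    group-wide minimum.  Deterministic and order-independent: ties broken
    by course cost then drug name; output ordered by ascending cost per
    life-year.
    """
    groups: dict[str, IndicationAssessment] = {}
    for a in assessments:
        cur = groups.get(a.option_group)
        if cur is None or (a.cost_per_ly_usd, a.course_cost_usd, a.drug_name) < (
            cur.cost_per_ly_usd,
            cur.course_cost_usd,
            cur.drug_name,
        ):
            groups[a.option_group] = a
    return sorted(
        groups.values(), key=lambda a: (a.cost_per_ly_usd, a.annual_cost_usd, a.drug_name)
    )


def total_under_threshold(
    assessments: Sequence[IndicationAssessment],
    boundary: Category,
) -> float:
    """Total annual cost of options at or below a threshold category.

    Expects best-option-selected input; widening the boundary can never
    decrease the total.
    """
    cutoff = CATEGORY_ORDER.index(boundary)
    return sum(
        a.annual_cost_usd for a in assessments if CATEGORY_ORDER.index(a.category) <= cutoff
    )


def totals_by_threshold(assessments: Sequence[IndicationAssessment]) -> dict:
    """Budget totals per threshold category, raw USD and millions to 1 dp."""
    report = {}
    for cat in CATEGORY_ORDER:
        total = total_under_threshold(assessments, cat)
        report[cat.value] = {
            "total_usd": total,
            "total_millions_usd": round_half_up(total / 1e6, 1),
        }
    return report


def cumulative_curve(assessments: Sequence[IndicationAssessment]) -> BudgetCurve:
    """Cumulative annual procurement cost against GDP fraction per life-year.

    Input should already be best-option-selected.  Points are sorted by
    ascending GDP fraction — the league tables' ranking column, identical to
    cost-per-life-year order whenever the two are consistent — with ties
    broken by annual cost then drug name, so the curve is invariant to input
    order and its last ordinate equals the unconstrained total.
    """
    ordered = sorted(
        assessments, key=lambda a: (a.gdp_fraction, a.annual_cost_usd, a.drug_name)
    )
    points: list[tuple[float, float]] = []
    running = 0.0
    for a in ordered:
        running += a.annual_cost_usd
        points.append((a.gdp_fraction, running))
    return BudgetCurve(points=points, selection=list(ordered))


def write_curve_tsv(curve: BudgetCurve, path: str | Path) -> None:
    """Export the curve as a two-column TSV (gdp_fraction, cumulative_usd)."""
    with open(path, "w") as fh:
        fh.write("gdp_fraction\tcumulative_annual_cost_usd\n")
        for frac, cum in curve.points:
            fh.write(f"{round_half_up(frac, 4)}\t{round_half_up(cum, 2)}\n")


def write_totals_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
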