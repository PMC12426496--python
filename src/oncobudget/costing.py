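"""Price a full treatment course in USD from regimen dosing rules.

All costing is direct drug-acquisition cost only, for a fixed reference
patient; administration consumables, staffing and investigations are out of
scope.  Vial rounding / wastage is not modelled (dose × unit price is
continuous) — consumers should treat costs as a lower bound and the
``wastage_not_modelled`` note in the run log records the limitation.

Costing conventions:

* Curative courses are priced over the protocol's ``planned_cycles``.
* Palliative courses are priced over the median treatment exposure: the
  median treatment duration when reported, else median PFS (treatment
  continues until progression).  A started cycle is dispensed in full, so
  the number of cycles is ``ceil(exposure_months * 30.44 / cycle_days)``.
* Substitutive regimens subtract the comparator arm's drug cost, priced
  identically over the same exposure; additive regimens do not.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel

from .catalog import (
    DoseRule,
    EconomicContext,
    PatientProfile,
    Regimen,
    RegimenComponent,
    Setting,
    TrialEvidence,
)

__all__ = [
    "DAYS_PER_MONTH",
    "CONVENTIONAL_THRESHOLD_USD",
    "CourseCost",
    "ConfigurationError",
    "EvidenceIncompleteError",
    "dose_per_administration",
    "convert_to_usd",
    "palliative_exposure_months",
    "cycles_for_exposure",
    "course_cost",
    "is_conventional_excluded",
    "horizon_excess_cost",
]

#: Mean Gregorian month length, used to map months of exposure onto cycles.
DAYS_PER_MONTH = 30.44

#: Courses cheaper than this are conventional agents, excluded from analysis.
CONVENTIONAL_THRESHOLD_USD = 1000.0


class ConfigurationError(ValueError):
    """A regimen or context is configured inconsistently for costing."""


class EvidenceIncompleteError(ValueError):
    """Trial evidence lacks a field the requested computation needs."""


class CourseCost(BaseModel):
    """Course cost in USD, gross and net of the comparator arm.

    ``net_usd`` equals ``gross_usd`` for additive regimens and
    ``gross_usd - comparator_usd`` for substitutive ones.  A negative net
    (novel agent cheaper than comparator) is kept as computed and flagged.
    """

    gross_usd: float
    comparator_usd: float
    net_usd: float
    n_cycles_used: float
    negative_net: bool = False


def dose_per_administration(component: RegimenComponent, profile: PatientProfile) -> float:
    """Drug quantity (mg) dispensed per administration for one component."""
    if component.dose_rule is DoseRule.flat_per_admin:
        return component.dose_value_mg
    if component.dose_rule is DoseRule.per_kg:
        return component.dose_value_mg * profile.weight_kg
    if component.dose_rule is DoseRule.per_m2:
        return component.dose_value_mg * profile.body_surface_area_m2
    raise ConfigurationError(f"unknown dose rule {component.dose_rule!r}")


def convert_to_usd(amount_lkr: float, ctx: EconomicContext) -> float:
    """Convert a local-currency amount to USD at the context's annual rate."""
    if ctx.exchange_rate_lkr_per_usd <= 0:
        raise ConfigurationError("exchange rate must be positive")
    return amount_lkr / ctx.exchange_rate_lkr_per_usd


def _unit_price_usd(component: RegimenComponent, ctx: EconomicContext) -> float:
    if component.currency == "USD":
        return component.unit_price
    return convert_to_usd(component.unit_price, ctx)


def palliative_exposure_months(evidence: TrialEvidence, indication: str = "") -> float:
    """Months of drug exposure for a palliative course.

    Median treatment duration when reported; otherwise median PFS stands in,
    since palliative treatment typically continues until progression.
    """
    if evidence.median_treatment_duration_months is not None:
        return evidence.median_treatment_duration_months
    if evidence.median_pfs_months is not None:
        return evidence.median_pfs_months
    where = f" for {indication}" if indication else ""
    raise EvidenceIncompleteError(
        f"no treatment duration or median PFS available{where}; cannot derive exposure"
    )


def cycles_for_exposure(exposure_months: float, cycle_length_days: float) -> int:
    """Number of cycles dispensed over an exposure; a started cycle counts."""
    if exposure_months <= 0:
        return 0
    return math.ceil(exposure_months * DAYS_PER_MONTH / cycle_length_days)


def _regimen_gross_usd(
    regimen: Regimen,
    profile: PatientProfile,
    ctx: EconomicContext,
    exposure_months: Optional[float],
) -> tuple[float, float]:
    """Gross USD cost of a regimen and the cycle count of its first component."""
    total = 0.0
    n_cycles_first = 0.0
    for i, comp in enumerate(regimen.components):
        if regimen.setting is Setting.curative:
            if regimen.planned_cycles is None:
                raise ConfigurationError("curative regimen without planned_cycles")
            n_cycles = regimen.planned_cycles
        else:
            if exposure_months is None:
                raise ConfigurationError("palliative regimen priced without exposure")
            n_cycles = cycles_for_exposure(exposure_months, comp.cycle_length_days)
        n_admins = n_cycles * comp.administrations_per_cycle
        total += dose_per_administration(comp, profile) * _unit_price_usd(comp, ctx) * n_admins
        if i == 0:
            n_cycles_first = float(n_cycles)
    return total, n_cycles_first


def course_cost(
    regimen: Regimen,
    evidence: TrialEvidence,
    profile: PatientProfile,
    ctx: EconomicContext,
    indication: str = "",
) -> CourseCost:
    """Price a full course: gross, comparator and net cost in USD."""
    exposure: Optional[float] = None
    if regimen.setting is Setting.palliative:
        exposure = palliative_exposure_months(evidence, indication)

    gross, n_cycles = _regimen_gross_usd(regimen, profile, ctx, exposure)

    comparator_usd = 0.0
    if not regimen.additive and regimen.comparator is not None:
        comp_reg = regimen.comparator
        # Comparator priced over the same exposure window; a curative
        # comparator falls back to the novel arm's protocol length if its
        # own is unspecified.
        if comp_reg.setting is Setting.curative and comp_reg.planned_cycles is None:
            comp_reg = comp_reg.model_copy(update={"planned_cycles": regimen.planned_cycles})
        comparator_usd, _ = _regimen_gross_usd(comp_reg, profile, ctx, exposure)

    net = gross - comparator_usd
    return CourseCost(
        gross_usd=gross,
        comparator_usd=comparator_usd,
        net_usd=net,
        n_cycles_used=n_cycles,
        negative_net=net < 0,
    )


def is_conventional_excluded(
    course: CourseCost, threshold_usd: float = CONVENTIONAL_THRESHOLD_USD
) -> bool:
    """True iff the course is cheap enough to count as a conventional agent.

    The cut is strict: a course costing exactly the threshold is retained.
    """
    return course.net_usd < threshold_usd


def horizon_excess_cost(
    annual_novel_usd: float, annual_comparator_usd: float, horizon_years: float
) -> float:
    """Excess cost of a chronic therapy over a comparator across a horizon.

    Used for chronic-phase comparisons (e.g. tyrosine-kinase inhibitors in
    CML) where per-course pricing is meaningless and trials are too short to
    estimate a survival gain.
    """
    if horizon_years <= 0:
        raise ConfigurationError("horizon must be positive")
    return (annual_novel_usd - annual_comparator_usd) * horizon_years
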