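"""Convert trial evidence into life-years gained.

Palliative indications: the survival gain is the difference in median (or
restricted-mean) survival between arms, read directly from the pivotal
trial and expressed in months; life-years gained is that gain divided
by 12.  Where control-arm crossover dilutes the OS difference, the PFS gain
stands in.

Curative (adjuvant) indications: the trial reports an absolute gain in the
proportion surviving (OS, DFS or DSS) at end of follow-up.  Survivors at
that point are assumed to live to national life expectancy, so each
percentage point of absolute gain is worth the residual years

    residual = max(0, life_expectancy - mean_age_at_diagnosis - follow_up)

and life-years gained = delta_survival x residual.  No discounting or
quality adjustment is applied anywhere.  The residual rule is registered
under a named strategy so an alternative extrapolation can be swapped in.
"""

from __future__ import annotations

from typing import Callable, Optional

from pydantic import BaseModel, Field

from .catalog import EconomicContext, OutcomeMeasure, Setting, TrialEvidence
from .costing import EvidenceIncompleteError

__all__ = [
    "LifeYearGain",
    "select_outcome_basis",
    "ly_palliative",
    "residual_life_years",
    "ly_curative",
    "life_years_gained",
    "RESIDUAL_STRATEGIES",
]


class LifeYearGain(BaseModel):
    """Life-years gained with an audit trail of how they were derived."""

    years: float = Field(ge=0)
    basis: str
    residual_years_used: Optional[float] = None


def select_outcome_basis(evidence: TrialEvidence, setting: Setting) -> str:
    """Choose the survival basis for one indication.

    Palliative: restricted-mean survival gain when reported (robust to
    long-tailed curves), else median OS, else median PFS — which is also
    the fallback when crossover makes OS unreliable.  Curative: mature OS
    when available, else DFS/DSS extrapolated to life expectancy.
    """
    m = evidence.outcome_measure
    if setting is Setting.palliative:
        if m is OutcomeMeasure.RMST:
            return "RMST"
        if m is OutcomeMeasure.OS and not evidence.crossover:
            return "median_OS"
        if m is OutcomeMeasure.PFS or evidence.crossover:
            return "median_PFS"
        raise EvidenceIncompleteError(f"no usable palliative outcome measure ({m.value})")
    if m is OutcomeMeasure.OS:
        return "OS_extrapolated"
    if m in (OutcomeMeasure.DFS, OutcomeMeasure.DSS):
        return "DFS_extrapolated"
    raise EvidenceIncompleteError(f"no usable curative outcome measure ({m.value})")


def ly_palliative(gain_months: float, basis: str = "median_OS") -> LifeYearGain:
    """Life-years gained from a palliative survival gain in months."""
    if gain_months < 0:
        raise ValueError("survival gain cannot be negative")
    return LifeYearGain(years=gain_months / 12.0, basis=basis)


def _residual_le_minus_age_minus_followup(
    ctx: EconomicContext, evidence: TrialEvidence
) -> float:
    if evidence.mean_age_at_diagnosis_years is None or evidence.follow_up_years is None:
        raise EvidenceIncompleteError(
            "curative extrapolation needs mean age at diagnosis and follow-up"
        )
    return max(
        0.0,
        ctx.life_expectancy_years
        - evidence.mean_age_at_diagnosis_years
        - evidence.follow_up_years,
    )


#: Named extrapolation strategies for the residual-years rule.
RESIDUAL_STRATEGIES: dict[str, Callable[[EconomicContext, TrialEvidence], float]] = {
    "life_expectancy_minus_age_minus_followup": _residual_le_minus_age_minus_followup,
}

DEFAULT_RESIDUAL_STRATEGY = "life_expectancy_minus_age_minus_followup"


def residual_life_years(
    ctx: EconomicContext,
    evidence: TrialEvidence,
    strategy: str = DEFAULT_RESIDUAL_STRATEGY,
) -> float:
    """Years a survivor at end of follow-up is expected to live, floored at 0."""
    try:
        fn = RESIDUAL_STRATEGIES[strategy]
    except KeyError:
        raise ValueError(f"unknown residual strategy {strategy!r}") from None
    return fn(ctx, evidence)


def ly_curative(
    delta_survival: float, residual_years: float, basis: str = "DFS_extrapolated"
) -> LifeYearGain:
    """Life-years gained from an absolute survival-proportion gain.

    Bilinear in both arguments: each extra percentage point of survival is
    worth ``residual_years / 100`` life-years.
    """
    if not 0.0 <= delta_survival <= 1.0:
        raise ValueError("delta_survival must be a proportion in [0, 1]")
    if residual_years < 0:
        raise ValueError("residual years cannot be negative")
    return LifeYearGain(
        years=delta_survival * residual_years,
        basis=basis,
        residual_years_used=residual_years,
    )


def life_years_gained(
    evidence: TrialEvidence,
    setting: Setting,
    ctx: EconomicContext,
    strategy: str = DEFAULT_RESIDUAL_STRATEGY,
) -> LifeYearGain:
    """Full evidence-to-life-years conversion for one indication."""
    basis = select_outcome_basis(evidence, setting)
    if setting is Setting.palliative:
        return ly_palliative(evidence.gain_value, basis=basis)
    residual = residual_life_years(ctx, evidence, strategy=strategy)
    return ly_curative(evidence.gain_value, residual, basis=basis)
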