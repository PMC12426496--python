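"""Cost per life-year gained, GDP-multiple thresholds and classification.

The cost-effectiveness statistic is the undiscounted cost per life-year
gained (CLYG): net course cost divided by life-years gained.  Following the
WHO GDP-multiple heuristic, CLYG below 1x per-capita GDP is highly
cost-effective, 1-3x is cost-effective, 3-4x is potentially cost-effective
with price reduction, and above 4x is not cost-effective.

Boundary convention (configurable): the 1x boundary is exclusive for the
highly-cost-effective band ("less than per-capita GDP"), while the 3x and
4x boundaries belong to the cheaper band ("between 1 and 3 times").
"""

from __future__ import annotations

from pydantic import BaseModel, field_validator

from .catalog import CATEGORY_ORDER, Category, EconomicContext, round_half_up
from .costing import CourseCost
from .effectiveness import LifeYearGain

__all__ = [
    "ThresholdScheme",
    "UndefinedICERError",
    "cost_per_ly",
    "gdp_fraction",
    "classify",
    "assess_deescalation",
]


class UndefinedICERError(ValueError):
    """Cost per life-year is undefined (no survival gain); never reported as inf."""


class ThresholdScheme(BaseModel):
    """GDP-multiple thresholds in USD per life-year, cheapest band first.

    With the default multipliers (1, 3, 4) there are three boundaries and
    four categories.  ``lower_inclusive[i]`` says whether a value exactly on
    boundary ``i`` belongs to the cheaper band; the default is exclusive for
    the first boundary and inclusive for the rest.
    """

    boundaries_usd: tuple[float, ...]
    lower_inclusive: tuple[bool, ...] = ()
    labels: tuple[Category, ...] = CATEGORY_ORDER

    @field_validator("boundaries_usd")
    @classmethod
    def _increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("threshold boundaries must be strictly increasing")
        return v

    def model_post_init(self, __context) -> None:
        if not self.lower_inclusive:
            object.__setattr__(
                self,
                "lower_inclusive",
                (False,) + (True,) * (len(self.boundaries_usd) - 1),
            )
        if len(self.labels) != len(self.boundaries_usd) + 1:
            raise ValueError("need exactly one more category than boundaries")
        if len(self.lower_inclusive) != len(self.boundaries_usd):
            raise ValueError("one inclusivity flag per boundary")

    @classmethod
    def from_context(cls, ctx: EconomicContext) -> "ThresholdScheme":
        return cls(
            boundaries_usd=tuple(m * ctx.gdp_per_capita_usd for m in ctx.threshold_multipliers)
        )


def cost_per_ly(course: CourseCost, gain: LifeYearGain) -> float:
    """Cost per life-year gained: net course cost / life-years."""
    if gain.years <= 0:
        raise UndefinedICERError("no life-year gain; cost per life-year is not assessable")
    return course.net_usd / gain.years


def gdp_fraction(clyg_usd: float, ctx: EconomicContext) -> float:
    """Cost per life-year as a fraction of per-capita GDP (full precision).

    Report columns show this to two decimals; use
    ``round_half_up(value, 2)`` at write time.
    """
    return clyg_usd / ctx.gdp_per_capita_usd


def classify(clyg_usd: float, scheme: ThresholdScheme) -> Category:
    """Map a cost per life-year onto its threshold category."""
    for i, boundary in enumerate(scheme.boundaries_usd):
        below = clyg_usd <= boundary if scheme.lower_inclusive[i] else clyg_usd < boundary
        if below:
            return scheme.labels[i]
    return scheme.labels[-1]


def assess_deescalation(deesc_course: CourseCost, standard_gain: LifeYearGain) -> float:
    """Cost per life-year of a de-escalated (non-inferior) option.

    Equal efficacy is assumed, so the de-escalated cost is divided by the
    *standard* option's life-year gain.  Both options are kept as separate
    assessments within the same option group; the cheaper per life-year wins
    at selection time.
    """
    return cost_per_ly(deesc_course, standard_gain)


def reported_cost_per_ly(clyg_usd: float) -> float:
    """Whole-USD reporting convention for cost per life-year (half-up)."""
    return round_half_up(clyg_usd, 0)
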