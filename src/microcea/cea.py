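"""Cost-effectiveness metrics for a 1000-patient cohort.

Incremental cost = cost(active laboratory) - cost(no testing); DALYs averted
= DALY(no testing) - DALY(active laboratory).  The ICER is their ratio, but a
strategy that is cheaper *and* more effective is reported as *dominant* (and
more expensive and less effective as *dominated*) rather than as a signed,
uninterpretable ratio.  Net monetary benefit at willingness-to-pay w is
w x DALYs averted - incremental cost; NMB >= 0 iff cost-effective at w.

Cohort scaling (per 1000 hospitalised patients) happens here, once, from the
per-patient tree expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .daly import DalyBreakdown, daly
from .params import ParameterSet
from .tree import build_strategy_tree, rollback


@dataclass(frozen=True)
class ICEREstimate:
    """Either a finite USD/DALY ratio or a dominance/undefined label."""

    label: str  # ratio | dominant | dominated | undefined
    value: float | None
    quadrant: str

    def __str__(self) -> str:
        if self.label == "ratio":
            return f"{self.value:.2f}"
        return self.label


@dataclass
class CEAComparison:
    """Active-laboratory vs no-testing comparison for one regimen, per cohort."""

    regimen: str
    cost_intervention: float
    cost_comparator: float
    daly_intervention: float
    daly_comparator: float
    delta_cost: float
    dalys_averted: float
    deaths_averted: float
    icer: ICEREstimate
    nmb: float
    wtp: float
    breakdown_intervention: DalyBreakdown
    breakdown_comparator: DalyBreakdown


def incremental_cost(cost_intervention: float, cost_comparator: float) -> float:
    """Intervention minus comparator; negative means cost-saving."""
    return cost_intervention - cost_comparator


def dalys_averted(daly_comparator: float, daly_intervention: float) -> float:
    """Comparator minus intervention; positive means health gained."""
    return daly_comparator - daly_intervention


def classify_quadrant(dalys_averted_: float, delta_cost_: float) -> str:
    """Cost-effectiveness-plane quadrant (x = DALYs averted, y = incremental
    cost): lower-right (south_east) is cheaper and more effective."""
    if dalys_averted_ >= 0:
        return "south_east" if delta_cost_ <= 0 else "north_east"
    return "south_west" if delta_cost_ <= 0 else "north_west"


def icer(delta_cost_: float, dalys_averted_: float) -> ICEREstimate:
    """ICER with dominance handling; a zero-DALY denominator is flagged
    undefined, never turned into infinite arithmetic."""
    quadrant = classify_quadrant(dalys_averted_, delta_cost_)
    if dalys_averted_ == 0:
        return ICEREstimate("undefined", None, quadrant)
    if delta_cost_ < 0 and dalys_averted_ > 0:
        return ICEREstimate("dominant", None, quadrant)
    if delta_cost_ > 0 and dalys_averted_ < 0:
        return ICEREstimate("dominated", None, quadrant)
    return ICEREstimate("ratio", delta_cost_ / dalys_averted_, quadrant)


def nmb(delta_cost_: float, dalys_averted_: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` USD per DALY."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp!r}")
    return wtp * dalys_averted_ - delta_cost_


def compare(params: ParameterSet, regimen: str, wtp: float | None = None) -> CEAComparison:
    """Evaluate both arms for one regimen and compare them per cohort."""
    if wtp is None:
        wtp = params.daly.wtp_per_daly
    res_active = rollback(build_strategy_tree(params, "active_lab", regimen))
    res_none = rollback(build_strategy_tree(params, "no_testing", regimen))
    cohort = params.daly.cohort_size
    bd_active = daly(res_active, params.daly)
    bd_none = daly(res_none, params.daly)
    cost_active = res_active.expected_cost_per_patient * cohort
    cost_none = res_none.expected_cost_per_patient * cohort
    dc = incremental_cost(cost_active, cost_none)
    da = dalys_averted(bd_none.daly, bd_active.daly)
    return CEAComparison(
        regimen=regimen,
        cost_intervention=cost_active,
        cost_comparator=cost_none,
        daly_intervention=bd_active.daly,
        daly_comparator=bd_none.daly,
        delta_cost=dc,
        dalys_averted=da,
        deaths_averted=bd_none.deaths - bd_active.deaths,
        icer=icer(dc, da),
        nmb=nmb(dc, da, wtp),
        wtp=wtp,
        breakdown_intervention=bd_active,
        breakdown_comparator=bd_none,
    )


def evaluate_all(
    params: ParameterSet,
    regimens: tuple[str, ...] | None = None,
    wtp: float | None = None,
) -> tuple[pd.DataFrame, list[CEAComparison]]:
    """Results table (one row per regimen) mirroring the arm-level summary."""
    names = tuple(regimens) if regimens else tuple(params.regimens)
    comparisons = [compare(params, name, wtp) for name in names]
    frame = pd.DataFrame(
        [
            {
                "regimen": c.regimen,
                "cost_active": c.cost_intervention,
                "daly_active": c.daly_intervention,
                "cost_none": c.cost_comparator,
                "daly_none": c.daly_comparator,
                "incremental_cost": c.delta_cost,
                "dalys_averted": c.dalys_averted,
                "deaths_averted": c.deaths_averted,
                "icer_or_label": str(c.icer),
                "nmb": c.nmb,
            }
            for c in comparisons
        ]
    )
    return frame, comparisons
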