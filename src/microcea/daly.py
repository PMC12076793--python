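"""DALY computation: years of life lost (YLL) plus years lived with disability (YLD).

YLL = deaths x L, with L a per-death constant number of years lost (11 for
the 55-59 adult band, 66 for under-4s, 20 in a life-table sensitivity
analysis).  YLD = hospital days / days-per-year x disability weight (0.133
adult, 0.402 under-4, severe acute infectious episode).  One DALY is one
lost year of full health; no age weighting or discounting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import DalyParams
from .tree import StrategyResult


@dataclass
class DalyBreakdown:
    """Cohort-level DALY decomposition."""

    yll: float
    yld: float
    daly: float
    deaths: float
    hospital_days: float


def yll(deaths: float, years_lost_per_death: float) -> float:
    """Years of life lost: deaths times the per-death loss constant."""
    if deaths < 0:
        raise ValueError(f"deaths must be >= 0, got {deaths!r}")
    if years_lost_per_death <= 0:
        raise ValueError(f"years_lost_per_death must be > 0, got {years_lost_per_death!r}")
    return deaths * years_lost_per_death


def yld(hospital_days: float, disability_weight: float, days_per_year: float = 365.0) -> float:
    """Years lived with disability: time in hospital weighted by disability."""
    if hospital_days < 0 or disability_weight < 0:
        raise ValueError("hospital_days and disability_weight must be >= 0")
    if days_per_year <= 0:
        raise ValueError(f"days_per_year must be > 0, got {days_per_year!r}")
    return hospital_days / days_per_year * disability_weight


def daly(result: StrategyResult, daly_params: DalyParams) -> DalyBreakdown:
    """Cohort-scaled DALY breakdown for one arm's expected outcomes."""
    cohort = daly_params.cohort_size
    deaths = result.expected_deaths_per_patient * cohort
    days = result.expected_los_days_per_patient * cohort
    y_ll = yll(deaths, daly_params.years_lost_per_death) if deaths > 0 else 0.0
    y_ld = yld(days, daly_params.disability_weight, daly_params.days_per_year)
    return DalyBreakdown(yll=y_ll, yld=y_ld, daly=y_ll + y_ld,
                         deaths=deaths, hospital_days=days)
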