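"""One-way deterministic sensitivity analysis and break-even threshold search.

``one_way`` re-evaluates the full comparison while a single parameter sweeps
a value list (all others at baseline).  ``breakeven`` bisects the laboratory
cost/volume axis for the value at which a criterion (cost saving, or cost
effectiveness at a willingness-to-pay threshold) flips: per-sample
maintenance cost is searched to the cent, annual sample volume to the
smallest integer satisfying the criterion, recomputing the per-sample cost
from the fixed annual laboratory cost at every step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cea import CEAComparison, compare
from .params import (
    ConfigValidationError,
    ParameterSet,
    get_by_path,
    maintenance_cost_per_sample,
    set_by_path,
    validate,
)

CRITERIA = ("cost_saving", "cost_effective_at_wtp")
THRESHOLD_VARIABLES = ("maintenance_per_sample", "annual_samples")


class BracketError(Exception):
    """The criterion does not differ across the supplied bounds."""


@dataclass
class ThresholdResult:
    variable: str
    criterion: str
    threshold: float
    below_value: float
    below_satisfied: bool
    above_value: float
    above_satisfied: bool
    tolerance: float
    wtp: float

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "criterion": self.criterion,
            "threshold": self.threshold,
            "bracket": {
                "below": {"value": self.below_value, "satisfied": self.below_satisfied},
                "above": {"value": self.above_value, "satisfied": self.above_satisfied},
            },
            "tolerance": self.tolerance,
            "wtp": self.wtp,
        }


def apply_value(params: ParameterSet, path: str, value) -> ParameterSet:
    """Copy ``params`` with one parameter overridden.

    The laboratory cost/volume pair is kept self-consistent: overriding the
    per-sample maintenance cost rescales the annual fixed cost, and
    overriding the annual volume recomputes the per-sample cost from the
    fixed annual cost.
    """
    out = params.copy()
    set_by_path(out, path, value)
    if path == "costs.maintenance_per_sample" and out.costs.annual_samples > 0:
        out.costs.annual_fixed_lab_cost = round(value * out.costs.annual_samples, 2)
    elif path == "costs.annual_samples" and out.costs.annual_fixed_lab_cost > 0:
        out.costs.maintenance_per_sample = maintenance_cost_per_sample(
            out.costs.annual_fixed_lab_cost, int(value)
        )
    return out


def one_way(
    params: ParameterSet,
    path: str,
    values: Sequence,
    regimen: str,
    wtp: float | None = None,
) -> pd.DataFrame:
    """Sweep one parameter; returns one row per value, baseline included.

    An out-of-bounds value aborts the whole scenario with a validation error.
    """
    baseline = get_by_path(params, path)
    sweep = list(values)
    if not any(v == baseline for v in sweep):
        sweep.append(baseline)
    try:
        sweep = sorted(sweep)
    except TypeError:
        pass
    rows = []
    for value in sweep:
        candidate = apply_value(params, path, value)
        violations = validate(candidate)
        if violations:
            raise ConfigValidationError(violations)
        comp = compare(candidate, regimen, wtp)
        rows.append(
            {
                "parameter": path,
                "value": value,
                "is_baseline": value == baseline,
                "delta_cost": comp.delta_cost,
                "dalys_averted": comp.dalys_averted,
                "deaths_averted": comp.deaths_averted,
                "icer_or_label": str(comp.icer),
            }
        )
    return pd.DataFrame(rows)


def tornado(
    params: ParameterSet,
    scenarios: dict[str, tuple],
    regimen: str,
    wtp: float | None = None,
) -> pd.DataFrame:
    """Low/high sweeps for several parameters, ordered by the absolute swing
    in incremental cost (standard tornado presentation)."""
    frames = []
    for path, values in scenarios.items():
        frame = one_way(params, path, values, regimen, wtp)
        frame["swing"] = frame["delta_cost"].max() - frame["delta_cost"].min()
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["swing", "parameter", "value"],
                           ascending=[False, True, True], ignore_index=True)


def _criterion_met(comp: CEAComparison, criterion: str) -> bool:
    if criterion == "cost_saving":
        return comp.delta_cost < 0
    if criterion == "cost_effective_at_wtp":
        return comp.nmb >= 0
    raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")


def breakeven(
    params: ParameterSet,
    variable: str,
    criterion: str,
    bounds: tuple[float, float],
    regimen: str,
    wtp: float | None = None,
    tol: float | None = None,
) -> ThresholdResult:
    """Bisection for the value at which the criterion flips.

    Preconditions: the criterion differs at the two bounds (otherwise a
    :class:`BracketError` with endpoint diagnostics).  For
    ``annual_samples`` the result is the smallest integer sample volume
    satisfying the criterion.
    """
    if variable not in THRESHOLD_VARIABLES:
        raise ValueError(f"variable must be one of {THRESHOLD_VARIABLES}, got {variable!r}")
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    if wtp is None:
        wtp = params.daly.wtp_per_daly

    path = {"maintenance_per_sample": "costs.maintenance_per_sample",
            "annual_samples": "costs.annual_samples"}[variable]

    def met(value) -> bool:
        return _criterion_met(compare(apply_value(params, path, value), regimen, wtp),
                              criterion)

    lo, hi = bounds
    if lo >= hi:
        raise ValueError(f"bounds must satisfy lo < hi, got {bounds!r}")
    met_lo, met_hi = met(lo), met(hi)
    if met_lo == met_hi:
        raise BracketError(
            f"criterion {criterion!r} is {met_lo} at both bounds "
            f"({variable}={lo} and {variable}={hi}); nothing to bracket"
        )

    if variable == "annual_samples":
        tol = 1.0
        lo_i, hi_i = int(lo), int(hi)
        # Invariant: criterion differs between lo_i and hi_i; shrink to
        # adjacent integers, then report the value on the satisfied side.
        while hi_i - lo_i > 1:
            mid = (lo_i + hi_i) // 2
            if met(mid) == met_lo:
                lo_i = mid
            else:
                hi_i = mid
        threshold = hi_i if met_hi else lo_i
        below, above = lo_i, hi_i
        below_sat, above_sat = met_lo, met_hi
        if not met_hi:  # criterion satisfied on the low side
            threshold = lo_i
        return ThresholdResult(variable, criterion, float(threshold),
                               float(below), below_sat, float(above), above_sat,
                               tol, wtp)

    tol = 0.01 if tol is None else tol
    lo_f, hi_f = float(lo), float(hi)
    while hi_f - lo_f > tol:
        mid = (lo_f + hi_f) / 2.0
        if met(mid) == met_lo:
            lo_f = mid
        else:
            hi_f = mid
    threshold = round((lo_f + hi_f) / 2.0, 2)
    return ThresholdResult(variable, criterion, threshold,
                           lo_f, met_lo, hi_f, met_hi, tol, wtp)
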