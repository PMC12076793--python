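"""Probabilistic sensitivity analysis.

Each uncertain parameter gets a distribution matched to its baseline value:
multinomial transition nodes -> Dirichlet (concentration = mean vector x
effective sample size), binary probabilities -> beta (alpha = mean x ess,
beta = (1-mean) x ess), patient-care daily costs -> lognormal matched to the
arithmetic mean and coefficient of variation (keeping costs positive).  Every
iteration redraws the uncertain parameters, rebuilds both arms' trees, rolls
them back and records the cohort-level comparison.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical seed + configuration gives a bitwise
identical summary.  Draws violating a parameter invariant are resampled (up
to a bounded retry count) rather than clipped, to avoid silent bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import compare, nmb
from .params import ParameterSet, get_by_path, set_by_path, validate

logger = logging.getLogger(__name__)

FAMILIES = ("dirichlet", "beta", "lognormal", "fixed")
DEFAULT_ESS = 30.0
DEFAULT_COST_CV = 0.3
DEFAULT_WTP_GRID = (0.0, 100.0, 250.0, 500.0, 1000.0, 2500.0)


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling recipe for one parameter path."""

    path: str
    family: str
    hyper: dict = field(default_factory=dict)


def default_uncertainty(params: ParameterSet, ess: float = DEFAULT_ESS,
                        cost_cv: float = DEFAULT_COST_CV) -> dict[str, dict]:
    """The bundled uncertainty specification.

    Elicited probabilities get beta/Dirichlet with a moderate effective
    sample size (default 30, typical of elicitation panels); ICU and ward
    daily costs get lognormal with default cv = 0.3.  Both defaults are
    placeholder-tagged and overridable.
    """
    unc: dict[str, dict] = {
        "test.prevalence": {"family": "beta", "ess": ess},
        "test.sensitivity": {"family": "beta", "ess": ess},
        "test.false_positive": {"family": "beta", "ess": ess},
        "costs.icu_cost_per_day": {"family": "lognormal", "cv": cost_cv},
        "costs.ward_cost_per_day": {"family": "lognormal", "cv": cost_cv},
    }
    for name in params.regimens:
        unc[f"regimens.{name}.coverage"] = {"family": "beta", "ess": ess}
    for ctx in params.transitions.clinical_change:
        unc[f"transitions.clinical_change.{ctx}"] = {"family": "dirichlet", "ess": ess}
    for ctx in params.transitions.switch:
        unc[f"transitions.switch.{ctx}"] = {"family": "dirichlet", "ess": ess}
    return unc


def assign_distributions(params: ParameterSet,
                         uncertainty: Mapping[str, Mapping]) -> list[DistributionSpec]:
    """Moment-match hyperparameters to the baseline values.

    Raises ``KeyError`` for an unresolvable path, ``ValueError`` for an
    invalid family or a non-positive effective sample size / cv.
    """
    specs: list[DistributionSpec] = []
    for path in sorted(uncertainty):
        entry = uncertainty[path]
        family = entry.get("family")
        if family not in FAMILIES:
            raise ValueError(f"{path}: unknown distribution family {family!r}")
        current = get_by_path(params, path)
        if family == "fixed":
            specs.append(DistributionSpec(path, "fixed"))
            continue
        if family == "dirichlet":
            ess = float(entry["ess"])
            if ess <= 0:
                raise ValueError(f"{path}: ess must be > 0, got {ess!r}")
            keys = list(current.keys())
            conc = [current[k] * ess for k in keys]
            specs.append(DistributionSpec(path, "dirichlet",
                                          {"keys": keys, "concentration": conc}))
        elif family == "beta":
            ess = float(entry["ess"])
            if ess <= 0:
                raise ValueError(f"{path}: ess must be > 0, got {ess!r}")
            mean = float(current)
            specs.append(DistributionSpec(path, "beta",
                                          {"alpha": mean * ess, "beta": (1.0 - mean) * ess}))
        else:  # lognormal
            cv = float(entry["cv"])
            if cv <= 0:
                raise ValueError(f"{path}: cv must be > 0, got {cv!r}")
            mean = float(current)
            sigma2 = math.log1p(cv * cv)
            mu = math.log(mean) - sigma2 / 2.0
            specs.append(DistributionSpec(path, "lognormal",
                                          {"mu": mu, "sigma": math.sqrt(sigma2)}))
    return specs


def sample_spec(spec: DistributionSpec, rng: np.random.Generator):
    """Draw one value (or distribution dict) from a spec; fixed -> None."""
    if spec.family == "fixed":
        return None
    if spec.family == "dirichlet":
        vec = rng.dirichlet(spec.hyper["concentration"])
        return dict(zip(spec.hyper["keys"], vec.tolist()))
    if spec.family == "beta":
        a, b = spec.hyper["alpha"], spec.hyper["beta"]
        if a <= 0:
            return 0.0
        if b <= 0:
            return 1.0
        return float(rng.beta(a, b))
    return float(rng.lognormal(spec.hyper["mu"], spec.hyper["sigma"]))


@dataclass
class PSASummary:
    """Per-iteration comparisons and their distributional summaries."""

    regimen: str
    n_iterations: int
    seed: int
    wtp: float
    delta_cost: np.ndarray
    dalys_averted: np.ndarray
    deaths_averted: np.ndarray
    means: dict[str, float]
    quartiles: dict[str, tuple[float, float, float]]
    probability_cost_saving: float
    probability_cost_effective: dict[float, float]

    def iqr(self, name: str) -> tuple[float, float]:
        q25, _, q75 = self.quartiles[name]
        return q25, q75

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "regimen": self.regimen,
                "delta_cost": self.delta_cost,
                "dalys_averted": self.dalys_averted,
                "deaths_averted": self.deaths_averted,
            }
        )


def _summaries(name_arrays: dict[str, np.ndarray]):
    means = {k: float(np.mean(v)) for k, v in name_arrays.items()}
    # Percentiles use linear interpolation between order statistics, pinned
    # for bit-reproducibility.
    quartiles = {
        k: tuple(float(x) for x in np.percentile(v, [25, 50, 75], method="linear"))
        for k, v in name_arrays.items()
    }
    return means, quartiles


def run_psa(
    params: ParameterSet,
    specs: Sequence[DistributionSpec],
    n: int,
    seed: int,
    regimen: str,
    wtp: float | None = None,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    max_retries: int = 100,
) -> PSASummary:
    """Monte Carlo propagation of parameter uncertainty for one regimen."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if wtp is None:
        wtp = params.daly.wtp_per_daly
    rng = np.random.default_rng(seed)
    dc = np.empty(n)
    da = np.empty(n)
    dd = np.empty(n)
    for i in range(n):
        for attempt in range(max_retries):
            trial = params.copy()
            for spec in specs:
                value = sample_spec(spec, rng)
                if value is not None:
                    set_by_path(trial, spec.path, value)
            violations = validate(trial)
            if not violations:
                break
            logger.debug("iteration %d attempt %d invalid: %s", i, attempt, violations)
        else:
            raise RuntimeError(
                f"iteration {i}: exceeded {max_retries} resampling attempts; "
                f"last violations: {violations}"
            )
        comp = compare(trial, regimen, wtp)
        dc[i], da[i], dd[i] = comp.delta_cost, comp.dalys_averted, comp.deaths_averted

    means, quartiles = _summaries(
        {"delta_cost": dc, "dalys_averted": da, "deaths_averted": dd}
    )
    return PSASummary(
        regimen=regimen,
        n_iterations=n,
        seed=seed,
        wtp=wtp,
        delta_cost=dc,
        dalys_averted=da,
        deaths_averted=dd,
        means=means,
        quartiles=quartiles,
        probability_cost_saving=float(np.mean(dc < 0)),
        probability_cost_effective={
            float(w): float(np.mean(w * da - dc >= 0)) for w in wtp_grid
        },
    )


@dataclass
class CEPlane:
    """Scatter of (DALYs averted, incremental cost) pairs across draws."""

    points: np.ndarray  # (n, 2): column 0 DALYs averted, column 1 delta cost
    quadrant_counts: dict[str, int]
    fraction_cost_effective: float
    wtp: float


def ce_plane(summary: PSASummary, wtp: float | None = None) -> CEPlane:
    """Cost-effectiveness-plane points, quadrant tallies and the fraction of
    draws on the acceptable side of the WTP line (NMB >= 0)."""
    if summary.n_iterations == 0:
        raise ValueError("empty PSA summary")
    if wtp is None:
        wtp = summary.wtp
    da, dc = summary.dalys_averted, summary.delta_cost
    points = np.column_stack([da, dc])
    counts = {
        "south_east": int(np.sum((da >= 0) & (dc <= 0))),
        "north_east": int(np.sum((da >= 0) & (dc > 0))),
        "south_west": int(np.sum((da < 0) & (dc <= 0))),
        "north_west": int(np.sum((da < 0) & (dc > 0))),
    }
    frac = float(np.mean(wtp * da - dc >= 0))
    return CEPlane(points=points, quadrant_counts=counts,
                   fraction_cost_effective=frac, wtp=wtp)


def ceac(summary: PSASummary, wtp_grid: Sequence[float]) -> np.ndarray:
    """Cost-effectiveness acceptability curve: P(NMB >= 0) per WTP value."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be nonempty")
    if (grid < 0).any():
        raise ValueError("wtp_grid values must be >= 0")
    da, dc = summary.dalys_averted, summary.delta_cost
    return np.array([float(np.mean(nmb(dc, da, w) >= 0)) for w in grid])
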