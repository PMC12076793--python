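"""Synthetic model inputs with the statistical structure the analysis assumes.

The original study's elicited transition probabilities, per-trajectory
mortalities and lengths of stay, care costs and regimen coverages live in a
supplementary appendix that is not reproduced in the main text.  This module
generates complete, valid parameter sets in which every value printed in the
main text is held fixed and every appendix-only value is drawn from a
documented plausible range (``data/placeholder_ranges.json``), enforcing only
the qualitative orderings the analysis states: the broad-spectrum regimen
has the highest coverage, ICU daily cost exceeds ward daily cost, and
mortality after deterioration exceeds mortality after improvement.

It also generates antibiogram-style isolate susceptibility tables whose
computed regimen coverage matches requested targets to within binomial
sampling error, so the coverage model can be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .coverage import SusceptibilityTable
from .params import (
    CLINICAL_CHANGES,
    CLINICAL_CONTEXTS,
    ConfigValidationError,
    ParameterSet,
    baseline_parameters,
    set_by_path,
    validate,
)

#: Component agents of each empiric regimen (antibiogram column names).
REGIMEN_AGENTS = {
    "ceftriaxone_gentamicin": ["ceftriaxone", "gentamicin"],
    "ampicillin_gentamicin": ["ampicillin", "gentamicin"],
    "meropenem_vancomycin": ["meropenem", "vancomycin"],
}
_AGENTS = ["ceftriaxone", "ampicillin", "gentamicin", "meropenem", "vancomycin"]
_NARROW = ("ceftriaxone_gentamicin", "ampicillin_gentamicin")
_BROAD = "meropenem_vancomycin"


class FeasibilityError(ValueError):
    """The requested generation targets cannot be realised."""


@dataclass(frozen=True)
class ElicitationSummary:
    """A PERT-style expert judgement about a probability-valued parameter."""

    path: str
    mode: float
    lower: float
    upper: float
    weight: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.mode <= self.upper <= 1.0):
            raise ValueError(
                f"{self.path}: need 0 <= lower <= mode <= upper <= 1, "
                f"got ({self.lower}, {self.mode}, {self.upper})"
            )
        if self.weight <= 0:
            raise ValueError(f"{self.path}: weight must be > 0")


@dataclass(frozen=True)
class BetaEncoding:
    """Beta hyperparameters, or a point mass for degenerate bounds."""

    alpha: float | None
    beta: float | None
    point_mass: float | None = None

    @property
    def mean(self) -> float:
        if self.point_mass is not None:
            return self.point_mass
        return self.alpha / (self.alpha + self.beta)


def elicitation_to_beta(summary: ElicitationSummary) -> BetaEncoding:
    """Encode an elicited (lower, mode, upper, weight) as a beta distribution.

    The PERT mean (lower + 4 mode + upper)/6 becomes the beta mean and the
    confidence weight acts as the effective sample size: alpha = mean x w,
    beta = (1 - mean) x w.  Degenerate bounds collapse to a point mass.
    """
    if summary.lower == summary.upper:
        return BetaEncoding(alpha=None, beta=None, point_mass=summary.mode)
    mean = (summary.lower + 4.0 * summary.mode + summary.upper) / 6.0
    return BetaEncoding(alpha=mean * summary.weight, beta=(1.0 - mean) * summary.weight)


def placeholder_ranges() -> dict:
    """The documented plausible ranges for appendix-only values."""
    text = resources.files(__package__).joinpath(
        "data", "placeholder_ranges.json"
    ).read_text(encoding="utf-8")
    d = json.loads(text)
    d.pop("_comment", None)
    return d


def _uniform(rng: np.random.Generator, ranges: dict, key: str) -> float:
    r = ranges[key]
    return float(rng.uniform(r["low"], r["high"]))


def generate_parameter_set(
    seed: int,
    population: str = "adult",
    overrides: dict | None = None,
) -> ParameterSet:
    """A validated ParameterSet: printed values fixed, the rest drawn.

    Identical seeds give identical parameter sets.  ``overrides`` maps
    dotted parameter paths to values applied after generation; an override
    that violates an invariant raises :class:`ConfigValidationError`.
    """
    rng = np.random.default_rng(seed)
    ranges = placeholder_ranges()
    params = baseline_parameters(population)

    # Care and AMR costs; ward < ICU by construction of the ranges, asserted
    # anyway because only stated orderings are enforced.
    params.costs.icu_cost_per_day = _uniform(rng, ranges, "costs.icu_cost_per_day")
    params.costs.ward_cost_per_day = _uniform(rng, ranges, "costs.ward_cost_per_day")
    assert params.costs.icu_cost_per_day > params.costs.ward_cost_per_day
    params.costs.amr_cost_per_course = _uniform(rng, ranges, "costs.amr_cost_per_course")

    # Coverages: the broad regimen strictly exceeds both narrow regimens.
    narrow_cov = {n: _uniform(rng, ranges, "regimens.narrow.coverage") for n in _NARROW}
    margin = _uniform(rng, ranges, "regimens.broad.coverage_margin")
    broad_cov = min(max(narrow_cov.values()) + margin, 0.95)
    for name in _NARROW:
        params.regimens[name].coverage = narrow_cov[name]
        params.regimens[name].stepup_drug_cost_per_day = _uniform(
            rng, ranges, "regimens.narrow.stepup_drug_cost_per_day")
        params.regimens[name].stepdown_drug_cost_per_day = _uniform(
            rng, ranges, "regimens.narrow.stepdown_drug_cost_per_day")
    params.regimens[_BROAD].coverage = broad_cov
    params.regimens[_BROAD].stepup_drug_cost_per_day = _uniform(
        rng, ranges, "regimens.broad.stepup_drug_cost_per_day")
    params.regimens[_BROAD].stepdown_drug_cost_per_day = _uniform(
        rng, ranges, "regimens.broad.stepdown_drug_cost_per_day")

    # Transition distributions: Dirichlet jitter around the baseline
    # elicitation-style values.
    conc = ranges["transitions.dirichlet_concentration"]["low"]
    for table in (params.transitions.clinical_change, params.transitions.switch):
        for ctx, dist in table.items():
            keys = list(dist)
            draw = rng.dirichlet([max(dist[k], 1e-3) * conc for k in keys])
            table[ctx] = dict(zip(keys, draw.tolist()))

    # Outcomes: deterioration mortality > improvement mortality per context.
    for ctx in CLINICAL_CONTEXTS:
        improve = _uniform(rng, ranges, "outcomes.mortality.improve")
        deteriorate = _uniform(rng, ranges, "outcomes.mortality.deteriorate")
        unchanged = float(rng.uniform(improve, deteriorate))
        params.outcomes.mortality[ctx] = {
            "improve": improve, "unchanged": unchanged, "deteriorate": deteriorate,
        }
        params.outcomes.los_days[ctx] = {
            change: _uniform(rng, ranges, f"outcomes.los_days.{change}")
            for change in CLINICAL_CHANGES
        }

    params.test.definitive_days = _uniform(rng, ranges, "test.definitive_days")

    if overrides:
        for path, value in overrides.items():
            set_by_path(params, path, value)
    violations = validate(params)
    if violations:
        raise ConfigValidationError(violations)
    return params


def generate_antibiogram(
    seed: int,
    n_organisms: int,
    n_isolates: int,
    target_coverage: dict[str, float],
) -> SusceptibilityTable:
    """An isolate table whose per-regimen coverage (any-agent rule) matches
    the targets to within binomial sampling error at ``n_isolates``.

    Each isolate's covered/uncovered status per regimen is an independent
    Bernoulli draw at the target rate, then a consistent S/R pattern over the
    component antibiotics is constructed (the shared gentamicin column is
    resolved jointly for the two regimens that contain it).  Isolates are
    assigned to organisms round-robin; rows aggregate identical patterns
    within an organism, so labels stay unique while coverage remains an
    exact per-isolate tally.
    """
    if n_organisms < 1 or n_isolates < 1:
        raise FeasibilityError("n_organisms and n_isolates must be >= 1")
    unknown = sorted(set(target_coverage) - set(REGIMEN_AGENTS))
    if unknown:
        raise FeasibilityError(f"unknown regimen(s) in targets: {unknown}")
    for name, t in target_coverage.items():
        if not (0.0 <= t <= 1.0):
            raise FeasibilityError(f"target for {name} must be in [0, 1], got {t!r}")

    rng = np.random.default_rng(seed)
    t_cg = target_coverage.get("ceftriaxone_gentamicin", 0.5)
    t_ag = target_coverage.get("ampicillin_gentamicin", 0.5)
    t_mv = target_coverage.get("meropenem_vancomycin", 0.5)

    organisms = [f"organism_{i + 1:02d}" for i in range(n_organisms)]
    counts: dict[tuple[str, tuple[str, ...]], int] = {}
    for i in range(n_isolates):
        org = organisms[i % n_organisms]
        cov_cg = rng.random() < t_cg
        cov_ag = rng.random() < t_ag
        cov_mv = rng.random() < t_mv
        status = dict.fromkeys(_AGENTS, "R")
        if cov_cg and cov_ag and rng.random() < 0.5:
            status["gentamicin"] = "S"
            # Either partner may independently also be susceptible.
            if rng.random() < 0.5:
                status["ceftriaxone"] = "S"
            if rng.random() < 0.5:
                status["ampicillin"] = "S"
        else:
            if cov_cg:
                status["ceftriaxone"] = "S"
            if cov_ag:
                status["ampicillin"] = "S"
        if cov_mv:
            status["meropenem"] = "S"
            if rng.random() < 0.5:
                status["vancomycin"] = "S"
        key = (org, tuple(status[a] for a in _AGENTS))
        counts[key] = counts.get(key, 0) + 1

    rows = [
        {"organism": f"{org}|pattern_{''.join(pattern)}", "isolates": n,
         **dict(zip(_AGENTS, pattern))}
        for (org, pattern), n in sorted(counts.items())
    ]
    return SusceptibilityTable(pd.DataFrame(rows))
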