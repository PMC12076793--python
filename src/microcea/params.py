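"""Parameter model for the two-arm microbiology-laboratory cost-effectiveness analysis.

The full model input is a :class:`ParameterSet`: diagnostic-test parameters,
three empiric antibiotic regimens, elicited transition distributions,
unit costs (2022 USD), per-trajectory outcomes (mortality, length of stay)
and DALY constants for one population (adult or under-4).

Every value carries a provenance tag in ``ParameterSet.sources`` — ``"paper"``
for values printed in the source study's main text, ``"placeholder"`` for
values that in the original analysis live in an unavailable supplementary
appendix and are shipped here as documented, realistic stand-ins.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

PROB_TOL = 1e-9
_CENT = Decimal("0.01")

CLINICAL_CHANGES = ("improve", "unchanged", "deteriorate")
#: Clinical-change / outcome contexts: arm x culture-result x infection-coverage state.
CLINICAL_CONTEXTS = (
    "uninfected",
    "infected_covered",
    "infected_uncovered_detected",
    "infected_uncovered_missed",
)
SWITCH_ACTIONS = ("step_up", "step_down", "no_change")
#: Switching is either informed by a positive culture or by clinical condition only.
SWITCH_CONTEXTS = ("informed", "clinical")
REGIMEN_NAMES = (
    "ceftriaxone_gentamicin",
    "ampicillin_gentamicin",
    "meropenem_vancomycin",
)
POPULATIONS = ("adult", "under4")
FP_BRANCH_POLICIES = ("informed", "clinical")
MAINTENANCE_UNITS = ("bottle", "set")
SOURCE_TAGS = ("paper", "placeholder")


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigFormatError(ConfigError):
    """The file could not be parsed or has an unexpected schema."""


class ConfigValidationError(ConfigError):
    """The file parsed but one or more invariants are violated."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__(
            "invalid parameter set: " + "; ".join(str(v) for v in violations)
        )


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the field it concerns and the rule it breaks."""

    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.field} [{self.rule}]: {self.message}"


def _check_keys(
    mapping: Mapping[str, Any], required: tuple[str, ...], where: str
) -> None:
    if not isinstance(mapping, Mapping):
        raise ConfigFormatError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    unknown = sorted(set(mapping) - set(required))
    if unknown:
        raise ConfigFormatError(f"{where}: unknown key(s) {unknown}")
    missing = sorted(set(required) - set(mapping))
    if missing:
        raise ConfigFormatError(f"{where}: missing key(s) {missing}")


@dataclass
class TestParams:
    """Diagnostic-pathway parameters for suspected bloodstream infection."""

    prevalence: float
    sensitivity: float
    false_positive: float
    bottles_per_patient: int
    empiric_days: float
    definitive_days: float

    _FIELDS = (
        "prevalence",
        "sensitivity",
        "false_positive",
        "bottles_per_patient",
        "empiric_days",
        "definitive_days",
    )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TestParams":
        _check_keys(d, cls._FIELDS, "test")
        return cls(**{k: d[k] for k in cls._FIELDS})

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass
class RegimenParams:
    """An empiric antibiotic regimen: daily drug costs and organism coverage."""

    name: str
    drug_cost_per_day: float
    coverage: float
    stepup_drug_cost_per_day: float
    stepdown_drug_cost_per_day: float

    _FIELDS = (
        "name",
        "drug_cost_per_day",
        "coverage",
        "stepup_drug_cost_per_day",
        "stepdown_drug_cost_per_day",
    )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RegimenParams":
        _check_keys(d, cls._FIELDS, "regimen")
        return cls(**{k: d[k] for k in cls._FIELDS})

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass
class TransitionSet:
    """Elicited multinomial transitions.

    ``clinical_change`` holds one {improve, unchanged, deteriorate}
    distribution per clinical context; ``switch`` holds one
    {step_up, step_down, no_change} distribution per switching context
    (culture-informed vs clinical-condition-only).
    """

    clinical_change: dict[str, dict[str, float]]
    switch: dict[str, dict[str, float]]

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TransitionSet":
        _check_keys(d, ("clinical_change", "switch"), "transitions")
        _check_keys(d["clinical_change"], CLINICAL_CONTEXTS, "transitions.clinical_change")
        _check_keys(d["switch"], SWITCH_CONTEXTS, "transitions.switch")
        cc = {}
        for ctx in CLINICAL_CONTEXTS:
            _check_keys(d["clinical_change"][ctx], CLINICAL_CHANGES,
                        f"transitions.clinical_change.{ctx}")
            cc[ctx] = {k: float(d["clinical_change"][ctx][k]) for k in CLINICAL_CHANGES}
        sw = {}
        for ctx in SWITCH_CONTEXTS:
            _check_keys(d["switch"][ctx], SWITCH_ACTIONS, f"transitions.switch.{ctx}")
            sw[ctx] = {k: float(d["switch"][ctx][k]) for k in SWITCH_ACTIONS}
        return cls(clinical_change=cc, switch=sw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "clinical_change": {c: dict(v) for c, v in self.clinical_change.items()},
            "switch": {c: dict(v) for c, v in self.switch.items()},
        }


@dataclass
class CostParams:
    """Unit costs in 2022 USD."""

    culture_positive_bottle: float
    culture_negative_bottle: float
    maintenance_per_sample: float
    icu_cost_per_day: float
    ward_cost_per_day: float
    amr_cost_per_course: float
    annual_fixed_lab_cost: float
    annual_samples: int

    _FIELDS = (
        "culture_positive_bottle",
        "culture_negative_bottle",
        "maintenance_per_sample",
        "icu_cost_per_day",
        "ward_cost_per_day",
        "amr_cost_per_course",
        "annual_fixed_lab_cost",
        "annual_samples",
    )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CostParams":
        _check_keys(d, cls._FIELDS, "costs")
        return cls(**{k: d[k] for k in cls._FIELDS})

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass
class OutcomeParams:
    """Per-trajectory outcomes keyed by clinical context and clinical change."""

    mortality: dict[str, dict[str, float]]
    los_days: dict[str, dict[str, float]]

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "OutcomeParams":
        _check_keys(d, ("mortality", "los_days"), "outcomes")
        out = {}
        for name in ("mortality", "los_days"):
            _check_keys(d[name], CLINICAL_CONTEXTS, f"outcomes.{name}")
            table = {}
            for ctx in CLINICAL_CONTEXTS:
                _check_keys(d[name][ctx], CLINICAL_CHANGES, f"outcomes.{name}.{ctx}")
                table[ctx] = {k: float(d[name][ctx][k]) for k in CLINICAL_CHANGES}
            out[name] = table
        return cls(mortality=out["mortality"], los_days=out["los_days"])

    def to_dict(self) -> dict[str, Any]:
        return {
            "mortality": {c: dict(v) for c, v in self.mortality.items()},
            "los_days": {c: dict(v) for c, v in self.los_days.items()},
        }


@dataclass
class DalyParams:
    """DALY constants: loss function L, disability weight, cohort and WTP."""

    years_lost_per_death: float
    disability_weight: float
    days_per_year: float
    cohort_size: int
    wtp_per_daly: float

    _FIELDS = (
        "years_lost_per_death",
        "disability_weight",
        "days_per_year",
        "cohort_size",
        "wtp_per_daly",
    )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DalyParams":
        _check_keys(d, cls._FIELDS, "daly")
        return cls(**{k: d[k] for k in cls._FIELDS})

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass
class Policies:
    """Pinned modelling choices that the source text leaves open."""

    fp_branch_policy: str = "informed"
    maintenance_unit: str = "bottle"
    coverage_stepup_rule: str = "one_minus_coverage"

    _FIELDS = ("fp_branch_policy", "maintenance_unit", "coverage_stepup_rule")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Policies":
        _check_keys(d, cls._FIELDS, "policies")
        return cls(**{k: d[k] for k in cls._FIELDS})

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass
class ParameterSet:
    """Complete model input for one population."""

    population: str
    test: TestParams
    regimens: dict[str, RegimenParams]
    transitions: TransitionSet
    costs: CostParams
    outcomes: OutcomeParams
    daly: DalyParams
    policies: Policies = field(default_factory=Policies)
    sources: dict[str, str] = field(default_factory=dict)

    _SECTIONS = (
        "population", "test", "regimens", "transitions",
        "costs", "outcomes", "daly", "policies", "sources",
    )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        _check_keys(d, cls._SECTIONS, "parameter set")
        regimen_list = d["regimens"]
        if not isinstance(regimen_list, (list, tuple)):
            raise ConfigFormatError("regimens: expected a list of regimen mappings")
        regimens: dict[str, RegimenParams] = {}
        for entry in regimen_list:
            reg = RegimenParams.from_dict(entry)
            if reg.name in regimens:
                raise ConfigFormatError(f"regimens: duplicate regimen {reg.name!r}")
            regimens[reg.name] = reg
        return cls(
            population=d["population"],
            test=TestParams.from_dict(d["test"]),
            regimens=regimens,
            transitions=TransitionSet.from_dict(d["transitions"]),
            costs=CostParams.from_dict(d["costs"]),
            outcomes=OutcomeParams.from_dict(d["outcomes"]),
            daly=DalyParams.from_dict(d["daly"]),
            policies=Policies.from_dict(d["policies"]),
            sources=dict(d["sources"]),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "population": self.population,
            "test": self.test.to_dict(),
            "regimens": [r.to_dict() for r in self.regimens.values()],
            "transitions": self.transitions.to_dict(),
            "costs": self.costs.to_dict(),
            "outcomes": self.outcomes.to_dict(),
            "daly": self.daly.to_dict(),
            "policies": self.policies.to_dict(),
            "sources": dict(self.sources),
        }

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def source_of(self, path: str) -> str:
        """Provenance tag for a parameter path (longest-prefix lookup)."""
        probe = path
        while probe:
            if probe in self.sources:
                return self.sources[probe]
            probe = probe.rpartition(".")[0]
        return "placeholder"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _prob_violations(name: str, value: float) -> list[Violation]:
    if not (0.0 <= value <= 1.0):
        return [Violation(name, "probability_range", f"{value!r} not in [0, 1]")]
    return []


def _nonneg(name: str, value: float) -> list[Violation]:
    if value < 0:
        return [Violation(name, "nonnegative", f"{value!r} is negative")]
    return []


def _distribution_violations(name: str, dist: Mapping[str, float]) -> list[Violation]:
    out: list[Violation] = []
    for k, v in dist.items():
        if v < 0:
            out.append(Violation(f"{name}.{k}", "nonnegative", f"{v!r} is negative"))
    total = sum(dist.values())
    if abs(total - 1.0) > PROB_TOL:
        out.append(Violation(name, "sums_to_one", f"distribution sums to {total!r}"))
    return out


def validate(params: ParameterSet) -> list[Violation]:
    """Check every invariant; return the (possibly empty) list of violations.

    Violations are returned, never raised, so callers can report all problems
    at once.
    """
    v: list[Violation] = []
    if params.population not in POPULATIONS:
        v.append(Violation("population", "enum", f"{params.population!r} not in {POPULATIONS}"))

    t = params.test
    v += _prob_violations("test.prevalence", t.prevalence)
    v += _prob_violations("test.sensitivity", t.sensitivity)
    v += _prob_violations("test.false_positive", t.false_positive)
    if t.bottles_per_patient not in (2, 4):
        v.append(Violation("test.bottles_per_patient", "enum", f"{t.bottles_per_patient!r} not in (2, 4)"))
    if t.empiric_days <= 0:
        v.append(Violation("test.empiric_days", "positive", f"{t.empiric_days!r} must be > 0"))
    if t.definitive_days <= 0:
        v.append(Violation("test.definitive_days", "positive", f"{t.definitive_days!r} must be > 0"))

    if len(params.regimens) != 3:
        v.append(Violation("regimens", "count", f"expected exactly 3 regimens, got {len(params.regimens)}"))
    for name, reg in params.regimens.items():
        prefix = f"regimens.{name}"
        v += _prob_violations(f"{prefix}.coverage", reg.coverage)
        for f_ in ("drug_cost_per_day", "stepup_drug_cost_per_day", "stepdown_drug_cost_per_day"):
            v += _nonneg(f"{prefix}.{f_}", getattr(reg, f_))

    for ctx, dist in params.transitions.clinical_change.items():
        v += _distribution_violations(f"transitions.clinical_change.{ctx}", dist)
    for ctx, dist in params.transitions.switch.items():
        v += _distribution_violations(f"transitions.switch.{ctx}", dist)

    c = params.costs
    for f_ in CostParams._FIELDS:
        v += _nonneg(f"costs.{f_}", getattr(c, f_))
    if c.annual_fixed_lab_cost > 0 and c.annual_samples > 0 and c.maintenance_per_sample > 0:
        implied = c.annual_fixed_lab_cost / c.annual_samples
        if abs(c.maintenance_per_sample - implied) > 0.01 + 1e-12:
            v.append(Violation(
                "costs.maintenance_per_sample", "maintenance_consistency",
                f"{c.maintenance_per_sample} differs from "
                f"annual_fixed_lab_cost/annual_samples = {implied:.4f} by more than one cent",
            ))

    for ctx in CLINICAL_CONTEXTS:
        for change in CLINICAL_CHANGES:
            v += _prob_violations(f"outcomes.mortality.{ctx}.{change}",
                                  params.outcomes.mortality[ctx][change])
            v += _nonneg(f"outcomes.los_days.{ctx}.{change}",
                         params.outcomes.los_days[ctx][change])

    d = params.daly
    if d.years_lost_per_death <= 0:
        v.append(Violation("daly.years_lost_per_death", "positive", f"{d.years_lost_per_death!r} must be > 0"))
    v += _prob_violations("daly.disability_weight", d.disability_weight)
    if d.days_per_year <= 0:
        v.append(Violation("daly.days_per_year", "positive", f"{d.days_per_year!r} must be > 0"))
    if d.cohort_size <= 0:
        v.append(Violation("daly.cohort_size", "positive", f"{d.cohort_size!r} must be > 0"))
    v += _nonneg("daly.wtp_per_daly", d.wtp_per_daly)

    p = params.policies
    if p.fp_branch_policy not in FP_BRANCH_POLICIES:
        v.append(Violation("policies.fp_branch_policy", "enum", f"{p.fp_branch_policy!r} not in {FP_BRANCH_POLICIES}"))
    if p.maintenance_unit not in MAINTENANCE_UNITS:
        v.append(Violation("policies.maintenance_unit", "enum", f"{p.maintenance_unit!r} not in {MAINTENANCE_UNITS}"))
    if p.coverage_stepup_rule != "one_minus_coverage":
        v.append(Violation("policies.coverage_stepup_rule", "enum", f"{p.coverage_stepup_rule!r} unsupported"))

    for path, tag in params.sources.items():
        if tag not in SOURCE_TAGS:
            v.append(Violation(f"sources.{path}", "enum", f"{tag!r} not in {SOURCE_TAGS}"))
    return v


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> ParameterSet:
    """Load and validate a JSON or YAML parameter file.

    Raises :class:`ConfigFormatError` on parse/schema problems (with line
    context where the parser provides it) and :class:`ConfigValidationError`
    when an invariant is violated, naming the offending field.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigFormatError(f"{path}: YAML parse error{where}: {exc}") from exc
    else:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigFormatError(f"{path}: JSON parse error at line {exc.lineno}: {exc.msg}") from exc
    params = ParameterSet.from_dict(raw)
    violations = validate(params)
    if violations:
        raise ConfigValidationError(violations)
    return params


def save_config(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set to JSON or YAML, lossless at full float precision."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(d, indent=2) + "\n", encoding="utf-8")


def baseline_parameters(population: str = "adult") -> ParameterSet:
    """The bundled baseline configuration for the requested population."""
    if population not in POPULATIONS:
        raise ValueError(f"population must be one of {POPULATIONS}, got {population!r}")
    fname = f"baseline_{population}.json"
    text = resources.files(__package__).joinpath("data", fname).read_text(encoding="utf-8")
    params = ParameterSet.from_dict(json.loads(text))
    violations = validate(params)
    if violations:  # pragma: no cover - bundled file is kept valid
        raise ConfigValidationError(violations)
    return params


def maintenance_cost_per_sample(annual_cost: float, annual_samples: int) -> float:
    """Per-sample maintenance cost: annual cost / annual samples, rounded
    half-up at the cent."""
    if annual_samples <= 0:
        raise ValueError(f"annual_samples must be > 0, got {annual_samples!r}")
    if annual_cost < 0:
        raise ValueError(f"annual_cost must be >= 0, got {annual_cost!r}")
    q = Decimal(str(annual_cost)) / Decimal(str(annual_samples))
    return float(q.quantize(_CENT, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Parameter-path addressing (shared by the PSA and DSA engines)
# ---------------------------------------------------------------------------

def get_by_path(params: ParameterSet, path: str) -> Any:
    """Resolve a dotted path like ``costs.icu_cost_per_day`` or
    ``transitions.clinical_change.uninfected``."""
    obj: Any = params
    for part in path.split("."):
        try:
            if isinstance(obj, Mapping):
                obj = obj[part]
            else:
                obj = getattr(obj, part)
        except (KeyError, AttributeError):
            raise KeyError(f"unknown parameter path {path!r} (failed at {part!r})") from None
    return obj


def set_by_path(params: ParameterSet, path: str, value: Any) -> None:
    head, _, leaf = path.rpartition(".")
    if not head:
        raise KeyError(f"cannot set top-level path {path!r}")
    parent = get_by_path(params, head)
    if isinstance(parent, Mapping):
        if leaf not in parent:
            raise KeyError(f"unknown parameter path {path!r}")
        parent[leaf] = value  # type: ignore[index]
    else:
        if not hasattr(parent, leaf):
            raise KeyError(f"unknown parameter path {path!r}")
        setattr(parent, leaf, value)


def _leaf_paths(prefix: str, obj: Any):
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            yield from _leaf_paths(f"{prefix}.{k}" if prefix else str(k), v)
    else:
        yield prefix, obj


def flatten_parameters(
    params: ParameterSet, distributions: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """One row per scalar parameter: name, value, source tag, PSA distribution.

    ``distributions`` maps parameter paths (or path prefixes) to a
    distribution-family label; unlisted parameters are ``fixed``.
    """
    d = params.to_dict()
    d.pop("sources")
    regimens = d.pop("regimens")
    rows = list(_leaf_paths("", d))
    for reg in regimens:
        name = reg["name"]
        rows += [(f"regimens.{name}.{k}", v) for k, v in reg.items() if k != "name"]

    def dist_of(path: str) -> str:
        if not distributions:
            return "fixed"
        probe = path
        while probe:
            if probe in distributions:
                return distributions[probe]
            probe = probe.rpartition(".")[0]
        return "fixed"

    frame = pd.DataFrame(
        [
            {
                "name": path,
                "value": value,
                "source": "paper" if path == "population" else params.source_of(path),
                "distribution": dist_of(path),
            }
            for path, value in rows
        ]
    )
    return frame.sort_values("name", ignore_index=True)
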