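"""Two-arm decision tree: construction, path enumeration, expected-value rollback.

The model compares an *active laboratory* arm (blood cultures taken, therapy
switched on results) against a *no testing* arm (switching driven by clinical
condition only) for hospitalised patients with suspected bloodstream
infection.  Canonical topology per patient:

    start (empiric drugs + AMR course [+ lab maintenance, active arm])
      -> infection?            (prevalence)
      -> covered by empiric?   (regimen coverage; infected patients)
      -> culture result        (sensitivity / false-positive; active arm only,
                                bottle costs attach here)
      -> antibiotic switch     (culture-informed or clinical-condition-only;
                                definitive drug costs and second AMR course)
      -> clinical change       (improve / unchanged / deteriorate; ICU or ward
                                care costs x length of stay)
      -> terminal              (trajectory mortality and length of stay)

A positive culture in a patient whose empiric regimen does not cover the
organism forces a step-up (switch to covering therapy); for covered patients
the informed switch distribution is renormalised over step-down/no-change.
Clinical-change and outcome distributions are keyed by the infection/coverage
/detection context, so detection benefits exactly the patients whose empiric
therapy was inadequate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .params import (
    CLINICAL_CHANGES,
    ParameterSet,
)

ARMS = ("active_lab", "no_testing")
PROB_TOL = 1e-9


class StructuralError(Exception):
    """The tree violates a structural invariant (e.g. contains a cycle)."""


@dataclass
class Node:
    kind: str  # decision | chance | terminal
    label: str
    branches: list["Branch"] = field(default_factory=list)
    death_probability: float | None = None  # terminal payload
    los_days: float | None = None


@dataclass
class Branch:
    label: str
    probability: float | None  # None on decision branches
    cost: float
    child: Node


@dataclass
class StrategyTree:
    root: Node
    arm: str
    regimen: str
    fingerprint: str


@dataclass
class PathOutcome:
    probability: float
    total_cost: float
    death_probability: float
    los_days: float
    labels: tuple[str, ...] = ()


@dataclass
class StrategyResult:
    """Per-patient expectations for one arm/regimen."""

    expected_cost_per_patient: float
    expected_deaths_per_patient: float
    expected_los_days_per_patient: float


def _chance(label: str, branches: list[Branch]) -> Node:
    kept = [b for b in branches if b.probability > 0.0]
    total = sum(b.probability for b in kept)
    if abs(total - 1.0) > PROB_TOL:
        raise StructuralError(f"chance node {label!r}: probabilities sum to {total!r}")
    return Node("chance", label, kept)


def build_strategy_tree(params: ParameterSet, arm: str, regimen: str) -> StrategyTree:
    """Build the canonical tree for one arm and one empiric regimen."""
    if arm not in ARMS:
        raise LookupError(f"unknown arm {arm!r}; expected one of {ARMS}")
    try:
        reg = params.regimens[regimen]
    except KeyError:
        raise LookupError(
            f"unknown regimen {regimen!r}; expected one of {tuple(params.regimens)}"
        ) from None

    t, c, tr, pol = params.test, params.costs, params.transitions, params.policies
    bottles = t.bottles_per_patient
    active = arm == "active_lab"

    def terminal(ctx: str, change: str) -> Node:
        return Node(
            "terminal",
            f"{ctx}/{change}",
            death_probability=params.outcomes.mortality[ctx][change],
            los_days=params.outcomes.los_days[ctx][change],
        )

    def clinical_node(ctx: str) -> Node:
        dist = tr.clinical_change[ctx]
        branches = []
        for change in CLINICAL_CHANGES:
            daily = c.icu_cost_per_day if change == "deteriorate" else c.ward_cost_per_day
            care = daily * params.outcomes.los_days[ctx][change]
            branches.append(Branch(change, dist[change], care, terminal(ctx, change)))
        return _chance(f"clinical[{ctx}]", branches)

    def switch_cost(action: str) -> float:
        if action == "step_up":
            return reg.stepup_drug_cost_per_day * t.definitive_days + c.amr_cost_per_course
        if action == "step_down":
            return reg.stepdown_drug_cost_per_day * t.definitive_days + c.amr_cost_per_course
        return reg.drug_cost_per_day * t.definitive_days

    def switch_node(dist: dict[str, float], ctx: str, tag: str) -> Node:
        branches = [
            Branch(action, p, switch_cost(action), clinical_node(ctx))
            for action, p in dist.items()
        ]
        return _chance(f"switch[{tag},{ctx}]", branches)

    informed = tr.switch["informed"]
    clinical = tr.switch["clinical"]

    def informed_covered_dist() -> dict[str, float]:
        # Coverage step-up rule: P(step_up | true positive) = 1 - coverage,
        # realised by the explicit coverage split; covered patients keep the
        # informed distribution renormalised over step-down / no-change.
        rest = informed["step_down"] + informed["no_change"]
        if rest <= 0.0:
            return {"no_change": 1.0}
        return {
            "step_down": informed["step_down"] / rest,
            "no_change": informed["no_change"] / rest,
        }

    def culture_node(infected: bool, covered: bool) -> Node:
        if infected:
            p_pos = t.sensitivity
            if covered:
                pos = switch_node(informed_covered_dist(), "infected_covered", "informed")
                neg = switch_node(clinical, "infected_covered", "clinical")
            else:
                pos = switch_node({"step_up": 1.0}, "infected_uncovered_detected", "informed")
                neg = switch_node(clinical, "infected_uncovered_missed", "clinical")
        else:
            p_pos = t.false_positive
            if pol.fp_branch_policy == "informed":
                pos = switch_node(dict(informed), "uninfected", "informed")
            else:
                pos = switch_node(clinical, "uninfected", "clinical")
            neg = switch_node(clinical, "uninfected", "clinical")
        return _chance(
            f"culture[{'infected' if infected else 'uninfected'}]",
            [
                Branch("culture_positive", p_pos, c.culture_positive_bottle * bottles, pos),
                Branch("culture_negative", 1.0 - p_pos, c.culture_negative_bottle * bottles, neg),
            ],
        )

    def infected_subtree() -> Node:
        if active:
            covered_child = culture_node(True, True)
            uncovered_child = culture_node(True, False)
        else:
            covered_child = switch_node(clinical, "infected_covered", "clinical")
            uncovered_child = switch_node(clinical, "infected_uncovered_missed", "clinical")
        return _chance(
            "coverage",
            [
                Branch("covered", reg.coverage, 0.0, covered_child),
                Branch("uncovered", 1.0 - reg.coverage, 0.0, uncovered_child),
            ],
        )

    def uninfected_subtree() -> Node:
        if active:
            return culture_node(False, False)
        return switch_node(clinical, "uninfected", "clinical")

    infection = _chance(
        "infection",
        [
            Branch("infected", t.prevalence, 0.0, infected_subtree()),
            Branch("uninfected", 1.0 - t.prevalence, 0.0, uninfected_subtree()),
        ],
    )

    base_cost = reg.drug_cost_per_day * t.empiric_days + c.amr_cost_per_course
    if active:
        per_sample_units = bottles if pol.maintenance_unit == "bottle" else 1
        base_cost += c.maintenance_per_sample * per_sample_units

    root = Node("chance", "start", [Branch("cohort_entry", 1.0, base_cost, infection)])
    fingerprint = hashlib.sha1(
        json.dumps(params.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]
    return StrategyTree(root=root, arm=arm, regimen=regimen, fingerprint=fingerprint)


def _arm_branch(node: Node, arm: str) -> Branch:
    for b in node.branches:
        if b.label == arm:
            return b
    raise StructuralError(f"decision node {node.label!r} has no branch for arm {arm!r}")


def enumerate_paths(tree: StrategyTree) -> list[PathOutcome]:
    """Exhaustive root-to-terminal enumeration (the rollback oracle).

    Probabilities multiply and costs sum along each path; zero-probability
    branches are never emitted.  Raises :class:`StructuralError` on cycles.
    """
    out: list[PathOutcome] = []

    def visit(node: Node, p: float, cost: float, labels: tuple[str, ...], seen: frozenset[int]):
        if id(node) in seen:
            raise StructuralError(f"cycle detected at node {node.label!r}")
        seen = seen | {id(node)}
        if node.kind == "terminal":
            out.append(PathOutcome(p, cost, node.death_probability, node.los_days, labels))
            return
        branches = [_arm_branch(node, tree.arm)] if node.kind == "decision" else node.branches
        for b in branches:
            bp = 1.0 if node.kind == "decision" else b.probability
            if bp > 0.0:
                visit(b.child, p * bp, cost + b.cost, labels + (b.label,), seen)

    visit(tree.root, 1.0, 0.0, (), frozenset())
    return out


def rollback(tree: StrategyTree) -> StrategyResult:
    """Bottom-up expectation over chance nodes.

    Decision nodes select the tree's designated arm branch; no expected-value
    optimisation is performed (the analysis compares fixed policies).
    """

    def value(node: Node) -> tuple[float, float, float]:
        if node.kind == "terminal":
            return 0.0, node.death_probability, node.los_days
        if node.kind == "decision":
            b = _arm_branch(node, tree.arm)
            cost, deaths, los = value(b.child)
            return b.cost + cost, deaths, los
        cost = deaths = los = 0.0
        for b in node.branches:
            c_, d_, l_ = value(b.child)
            cost += b.probability * (b.cost + c_)
            deaths += b.probability * d_
            los += b.probability * l_
        return cost, deaths, los

    cost, deaths, los = value(tree.root)
    return StrategyResult(cost, deaths, los)


# ---------------------------------------------------------------------------
# Serialisation for audit / re-import
# ---------------------------------------------------------------------------

def _node_to_dict(node: Node) -> dict:
    d: dict = {"kind": node.kind, "label": node.label}
    if node.kind == "terminal":
        d["death_probability"] = node.death_probability
        d["los_days"] = node.los_days
    else:
        d["branches"] = [
            {
                "label": b.label,
                "probability": b.probability,
                "cost": b.cost,
                "child": _node_to_dict(b.child),
            }
            for b in node.branches
        ]
    return d


def _node_from_dict(d: dict) -> Node:
    if d["kind"] == "terminal":
        return Node("terminal", d["label"],
                    death_probability=d["death_probability"], los_days=d["los_days"])
    return Node(
        d["kind"], d["label"],
        [Branch(b["label"], b["probability"], b["cost"], _node_from_dict(b["child"]))
         for b in d["branches"]],
    )


def tree_to_json(tree: StrategyTree) -> str:
    return json.dumps(
        {
            "arm": tree.arm,
            "regimen": tree.regimen,
            "fingerprint": tree.fingerprint,
            "root": _node_to_dict(tree.root),
        },
        indent=2,
    )


def tree_from_json(text: str) -> StrategyTree:
    d = json.loads(text)
    return StrategyTree(
        root=_node_from_dict(d["root"]), arm=d["arm"],
        regimen=d["regimen"], fingerprint=d["fingerprint"],
    )


def tree_to_dot(tree: StrategyTree) -> str:
    """GraphViz DOT export for visual inspection."""
    lines = ["digraph strategy {", '  node [shape=circle];']
    counter = [0]

    def visit(node: Node) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        shape = {"decision": "box", "chance": "circle", "terminal": "triangle"}[node.kind]
        extra = ""
        if node.kind == "terminal":
            extra = f"\\nd={node.death_probability:g} los={node.los_days:g}"
        lines.append(f'  {nid} [shape={shape}, label="{node.label}{extra}"];')
        for b in node.branches:
            cid = visit(b.child)
            p = "" if b.probability is None else f"p={b.probability:.4g} "
            lines.append(f'  {nid} -> {cid} [label="{b.label}\\n{p}${b.cost:,.2f}"];')
        return nid

    visit(tree.root)
    lines.append("}")
    return "\n".join(lines)
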