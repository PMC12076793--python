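"""Decision-tree construction, enumeration oracle, and rollback."""

import math

import pytest

from microcea import (
    StructuralError,
    build_strategy_tree,
    enumerate_paths,
    generate_parameter_set,
    rollback,
    tree_from_json,
    tree_to_dot,
    tree_to_json,
)
from microcea.tree import Branch, Node, StrategyTree


def toy_tree():
    t1 = Node("terminal", "a", death_probability=0.0, los_days=1.0)
    t2 = Node("terminal", "b", death_probability=0.0, los_days=3.0)
    root = Node("chance", "root", [Branch("a", 0.5, 10.0, t1), Branch("b", 0.5, 20.0, t2)])
    return StrategyTree(root=root, arm="active_lab", regimen="toy", fingerprint="toy")


class TestRollback:
    def test_two_branch_expected_cost(self):
        result = rollback(toy_tree())
        assert result.expected_cost_per_patient == pytest.approx(15.0)
        assert result.expected_deaths_per_patient == 0.0
        assert result.expected_los_days_per_patient == pytest.approx(2.0)

    def test_zero_mortality_tree_has_zero_expected_deaths(self, baseline):
        for ctx in baseline.outcomes.mortality:
            for change in baseline.outcomes.mortality[ctx]:
                baseline.outcomes.mortality[ctx][change] = 0.0
        result = rollback(build_strategy_tree(baseline, "active_lab", "meropenem_vancomycin"))
        assert result.expected_deaths_per_patient == 0.0


class TestEnumeration:
    def test_toy_paths(self):
        paths = enumerate_paths(toy_tree())
        assert sorted((p.probability, p.total_cost) for p in paths) == [(0.5, 10.0), (0.5, 20.0)]

    @pytest.mark.parametrize("arm", ["active_lab", "no_testing"])
    def test_path_probabilities_sum_to_one(self, baseline, arm):
        tree = build_strategy_tree(baseline, arm, "ceftriaxone_gentamicin")
        paths = enumerate_paths(tree)
        assert math.isclose(sum(p.probability for p in paths), 1.0, abs_tol=1e-9)
        assert all(0.0 < p.probability <= 1.0 for p in paths)

    def test_cycle_detected(self):
        t = Node("terminal", "t", death_probability=0.0, los_days=0.0)
        a = Node("chance", "a", [])
        b = Node("chance", "b", [Branch("back", 0.5, 0.0, a), Branch("out", 0.5, 0.0, t)])
        a.branches = [Branch("fwd", 1.0, 0.0, b)]
        with pytest.raises(StructuralError, match="cycle"):
            enumerate_paths(StrategyTree(a, "active_lab", "toy", "x"))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_rollback_equals_path_expectation(self, seed):
        params = generate_parameter_set(seed)
        regimen = list(params.regimens)[seed % 3]
        arm = ("active_lab", "no_testing")[seed % 2]
        tree = build_strategy_tree(params, arm, regimen)
        paths = enumerate_paths(tree)
        rb = rollback(tree)
        for got, want in [
            (rb.expected_cost_per_patient,
             sum(p.probability * p.total_cost for p in paths)),
            (rb.expected_deaths_per_patient,
             sum(p.probability * p.death_probability for p in paths)),
            (rb.expected_los_days_per_patient,
             sum(p.probability * p.los_days for p in paths)),
        ]:
            assert math.isclose(got, want, rel_tol=1e-9, abs_tol=1e-9)


class TestTopology:
    def test_first_chance_split_is_prevalence(self, baseline):
        tree = build_strategy_tree(baseline, "active_lab", "ceftriaxone_gentamicin")
        infection = tree.root.branches[0].child
        assert infection.label == "infection"
        assert sorted(b.probability for b in infection.branches) == [0.40, 0.60]

    def test_no_testing_arm_has_no_culture_nodes_or_lab_costs(self, baseline):
        tree = build_strategy_tree(baseline, "no_testing", "ceftriaxone_gentamicin")
        labels = []

        def walk(node):
            labels.append(node.label)
            for b in node.branches:
                walk(b.child)

        walk(tree.root)
        assert not any(label.startswith("culture") for label in labels)
        # base cost excludes all laboratory components
        base = tree.root.branches[0].cost
        assert base == pytest.approx(1.76 * 3 + 100.0)

    def test_prevalence_one_routes_all_paths_through_infection(self, baseline):
        baseline.test.prevalence = 1.0
        tree = build_strategy_tree(baseline, "active_lab", "ceftriaxone_gentamicin")
        paths = enumerate_paths(tree)
        assert all("infected" in p.labels for p in paths)
        pos_mass = sum(p.probability for p in paths if "culture_positive" in p.labels)
        assert pos_mass == pytest.approx(baseline.test.sensitivity, abs=1e-12)

    def test_unknown_arm_and_regimen_raise_lookup_error(self, baseline):
        with pytest.raises(LookupError, match="arm"):
            build_strategy_tree(baseline, "placebo", "ceftriaxone_gentamicin")
        with pytest.raises(LookupError, match="regimen"):
            build_strategy_tree(baseline, "active_lab", "phage_cocktail")

    def test_sensitivity_never_increases_active_arm_deaths(self, baseline):
        deaths = []
        for s in (0.0, 0.2, 0.5, 0.8, 1.0):
            baseline.test.sensitivity = s
            tree = build_strategy_tree(baseline, "active_lab", "ceftriaxone_gentamicin")
            deaths.append(rollback(tree).expected_deaths_per_patient)
        assert all(a >= b - 1e-12 for a, b in zip(deaths, deaths[1:]))


class TestSerialisation:
    def test_json_round_trip_preserves_rollback(self, baseline):
        tree = build_strategy_tree(baseline, "active_lab", "meropenem_vancomycin")
        clone = tree_from_json(tree_to_json(tree))
        assert rollback(clone) == rollback(tree)

    def test_dot_export_mentions_all_node_kinds(self, baseline):
        dot = tree_to_dot(build_strategy_tree(baseline, "active_lab", "ampicillin_gentamicin"))
        assert dot.startswith("digraph")
        assert "triangle" in dot and "circle" in dot
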