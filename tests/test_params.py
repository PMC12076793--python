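"""Parameter model: loading, validation, persistence, path addressing."""

import json

import pytest

from microcea import (
    ConfigFormatError,
    ConfigValidationError,
    ParameterSet,
    baseline_parameters,
    flatten_parameters,
    load_config,
    maintenance_cost_per_sample,
    save_config,
    validate,
)
from microcea.params import get_by_path, set_by_path


class TestBaseline:
    def test_baseline_is_valid(self, baseline):
        assert validate(baseline) == []

    def test_baseline_printed_values(self, baseline):
        assert baseline.test.prevalence == 0.40
        assert baseline.test.sensitivity == 0.80
        assert baseline.test.false_positive == 0.05
        assert baseline.costs.culture_positive_bottle == 31.90
        assert baseline.costs.culture_negative_bottle == 5.80
        assert baseline.costs.maintenance_per_sample == 34.53
        assert [r.drug_cost_per_day for r in baseline.regimens.values()] == [1.76, 3.04, 35.16]

    def test_under4_daly_constants(self, baseline_under4):
        assert baseline_under4.daly.years_lost_per_death == 66.0
        assert baseline_under4.daly.disability_weight == 0.402
        assert validate(baseline_under4) == []

    def test_source_tags(self, baseline):
        assert baseline.source_of("test.prevalence") == "paper"
        assert baseline.source_of("costs.icu_cost_per_day") == "placeholder"
        # prefix lookup: the whole transitions block is placeholder-tagged
        assert baseline.source_of("transitions.switch.informed.step_up") == "placeholder"


class TestValidation:
    def test_single_violation_names_field(self, baseline):
        baseline.test.prevalence = 1.2
        violations = validate(baseline)
        assert len(violations) == 1
        assert violations[0].field == "test.prevalence"
        assert violations[0].rule == "probability_range"

    def test_distribution_not_summing_to_one(self, baseline):
        baseline.transitions.clinical_change["uninfected"]["improve"] = 0.68
        violations = validate(baseline)
        assert len(violations) == 1
        assert violations[0].field == "transitions.clinical_change.uninfected"
        assert violations[0].rule == "sums_to_one"

    def test_maintenance_consistency(self, baseline):
        # printed per-sample value within one cent of 131697/3813: accepted
        assert validate(baseline) == []
        baseline.costs.maintenance_per_sample = 30.00
        violations = validate(baseline)
        assert [v.rule for v in violations] == ["maintenance_consistency"]

    def test_bottles_must_be_two_or_four(self, baseline):
        baseline.test.bottles_per_patient = 3
        assert [v.field for v in validate(baseline)] == ["test.bottles_per_patient"]


class TestIO:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_round_trip_is_lossless(self, baseline, tmp_path, suffix):
        path = tmp_path / f"config{suffix}"
        save_config(baseline, path)
        reloaded = load_config(path)
        assert reloaded.to_dict() == baseline.to_dict()

    def test_unknown_keys_rejected(self, baseline, tmp_path):
        d = baseline.to_dict()
        d["test"]["speciation_rate"] = 0.1
        path = tmp_path / "config.json"
        path.write_text(json.dumps(d))
        with pytest.raises(ConfigFormatError, match="speciation_rate"):
            load_config(path)

    def test_parse_error_reports_line(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{\n  "population": "adult",\n  oops\n}')
        with pytest.raises(ConfigFormatError, match="line 3"):
            load_config(path)

    def test_invalid_distribution_in_file_names_it(self, baseline, tmp_path):
        d = baseline.to_dict()
        d["transitions"]["clinical_change"]["uninfected"]["improve"] = 0.68  # sums to 0.98
        path = tmp_path / "config.json"
        path.write_text(json.dumps(d))
        with pytest.raises(ConfigValidationError, match="clinical_change.uninfected"):
            load_config(path)


class TestMaintenanceCost:
    @pytest.mark.parametrize(
        "annual,samples,expected",
        [
            (95176, 3813, 24.96),
            (131697, 1200, 109.75),
            (0, 3813, 0.00),
            (1, 3, 0.33),
            (5, 2, 2.50),
        ],
    )
    def test_quotient_rounds_half_up_at_cents(self, annual, samples, expected):
        assert maintenance_cost_per_sample(annual, samples) == expected

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            maintenance_cost_per_sample(100, 0)

    @pytest.mark.parametrize("annual,samples", [(95176, 3813), (131697, 3813), (123.45, 7)])
    def test_product_recovers_annual_within_half_cent_per_sample(self, annual, samples):
        per_sample = maintenance_cost_per_sample(annual, samples)
        assert abs(per_sample * samples - annual) <= samples / 2 * 0.01 + 1e-9


class TestPaths:
    def test_get_and_set_scalar(self, baseline):
        assert get_by_path(baseline, "costs.icu_cost_per_day") == 300.0
        set_by_path(baseline, "costs.icu_cost_per_day", 250.0)
        assert baseline.costs.icu_cost_per_day == 250.0

    def test_get_distribution_and_nested_leaf(self, baseline):
        dist = get_by_path(baseline, "transitions.switch.clinical")
        assert dist["no_change"] == 0.75
        assert get_by_path(baseline, "outcomes.mortality.uninfected.improve") == 0.005

    def test_unknown_path_raises(self, baseline):
        with pytest.raises(KeyError, match="unknown parameter path"):
            get_by_path(baseline, "costs.helipad_cost")
        with pytest.raises(KeyError):
            set_by_path(baseline, "test.does_not_exist", 1)


def test_flatten_parameters_table(baseline):
    frame = flatten_parameters(baseline, {"costs.icu_cost_per_day": "lognormal",
                                          "transitions": "dirichlet"})
    assert set(frame.columns) == {"name", "value", "source", "distribution"}
    row = frame.set_index("name")
    assert row.loc["test.prevalence", "source"] == "paper"
    assert row.loc["costs.icu_cost_per_day", "distribution"] == "lognormal"
    assert row.loc["transitions.switch.informed.step_up", "distribution"] == "dirichlet"
    assert row.loc["regimens.meropenem_vancomycin.drug_cost_per_day", "value"] == 35.16
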