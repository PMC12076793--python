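{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "microcea/parameterset",
  "title": "ParameterSet",
  "description": "Complete input for the two-arm microbiology-laboratory cost-effectiveness model. Money is decimal 2022 USD; probabilities are decimals in [0,1]. The 'sources' map tags each parameter path (longest-prefix match) as 'paper' (printed in the source study's main text) or 'placeholder' (appendix-only value shipped as a documented stand-in). The package's loader performs the authoritative validation, including cross-field rules (distributions sum to one within 1e-9; maintenance_per_sample within one cent of annual_fixed_lab_cost/annual_samples when all three are positive).",
  "type": "object",
  "required": ["population", "test", "regimens", "transitions", "costs", "outcomes", "daly", "policies", "sources"],
  "additionalProperties": false,
  "properties": {
    "population": {"enum": ["adult", "under4"]},
    "test": {
      "type": "object",
      "required": ["prevalence", "sensitivity", "false_positive", "bottles_per_patient", "empiric_days", "definitive_days"],
      "additionalProperties": false,
      "properties": {
        "prevalence": {"type": "number", "minimum": 0, "maximum": 1},
        "sensitivity": {"type": "number", "minimum": 0, "maximum": 1},
        "false_positive": {"type": "number", "minimum": 0, "maximum": 1},
        "bottles_per_patient": {"enum": [2, 4]},
        "empiric_days": {"type": "number", "exclusiveMinimum": 0},
        "definitive_days": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "regimens": {
      "type": "array",
      "minItems": 3,
      "maxItems": 3,
      "items": {
        "type": "object",
        "required": ["name", "drug_cost_per_day", "coverage", "stepup_drug_cost_per_day", "stepdown_drug_cost_per_day"],
        "additionalProperties": false,
        "properties": {
          "name": {"type": "string"},
          "drug_cost_per_day": {"type": "number", "minimum": 0},
          "coverage": {"type": "number", "minimum": 0, "maximum": 1},
          "stepup_drug_cost_per_day": {"type": "number", "minimum": 0},
          "stepdown_drug_cost_per_day": {"type": "number", "minimum": 0}
        }
      }
    },
    "transitions": {
      "type": "object",
      "required": ["clinical_change", "switch"],
      "additionalProperties": false,
      "properties": {
        "clinical_change": {
          "type": "object",
          "description": "One {improve, unchanged, deteriorate} distribution per clinical context.",
          "required": ["uninfected", "infected_covered", "infected_uncovered_detected", "infected_uncovered_missed"],
          "additionalProperties": false,
          "patternProperties": {"": {"$ref": "#/$defs/clinicalChangeDistribution"}}
        },
        "switch": {
          "type": "object",
          "description": "One {step_up, step_down, no_change} distribution per switching context (culture-informed vs clinical-condition-only).",
          "required": ["informed", "clinical"],
          "additionalProperties": false,
          "patternProperties": {"": {"$ref": "#/$defs/switchDistribution"}}
        }
      }
    },
    "costs": {
      "type": "object",
      "required": ["culture_positive_bottle", "culture_negative_bottle", "maintenance_per_sample", "icu_cost_per_day", "ward_cost_per_day", "amr_cost_per_course", "annual_fixed_lab_cost", "annual_samples"],
      "additionalProperties": false,
      "patternProperties": {"": {"type": "number", "minimum": 0}}
    },
    "outcomes": {
      "type": "object",
      "required": ["mortality", "los_days"],
      "additionalProperties": false,
      "properties": {
        "mortality": {"$ref": "#/$defs/contextTable"},
        "los_days": {"$ref": "#/$defs/contextTable"}
      }
    },
    "daly": {
      "type": "object",
      "required": ["years_lost_per_death", "disability_weight", "days_per_year", "cohort_size", "wtp_per_daly"],
      "additionalProperties": false,
      "properties": {
        "years_lost_per_death": {"type": "number", "exclusiveMinimum": 0},
        "disability_weight": {"type": "number", "minimum": 0, "maximum": 1},
        "days_per_year": {"type": "number", "exclusiveMinimum": 0},
        "cohort_size": {"type": "integer", "exclusiveMinimum": 0},
        "wtp_per_daly": {"type": "number", "minimum": 0}
      }
    },
    "policies": {
      "type": "object",
      "required": ["fp_branch_policy", "maintenance_unit", "coverage_stepup_rule"],
      "additionalProperties": false,
      "properties": {
        "fp_branch_policy": {
          "enum": ["informed", "clinical"],
          "description": "How an uninfected patient with a (false) positive culture is switched: by the culture-informed distribution or by clinical condition only."
        },
        "maintenance_unit": {
          "enum": ["bottle", "set"],
          "description": "Whether the per-sample maintenance cost applies per culture bottle or once per patient blood-culture set."
        },
        "coverage_stepup_rule": {"enum": ["one_minus_coverage"]}
      }
    },
    "sources": {
      "type": "object",
      "patternProperties": {"": {"enum": ["paper", "placeholder"]}}
    }
  },
  "$defs": {
    "clinicalChangeDistribution": {
      "type": "object",
      "required": ["improve", "unchanged", "deteriorate"],
      "additionalProperties": false,
      "patternProperties": {"": {"type": "number", "minimum": 0, "maximum": 1}}
    },
    "switchDistribution": {
      "type": "object",
      "required": ["step_up", "step_down", "no_change"],
      "additionalProperties": false,
      "patternProperties": {"": {"type": "number", "minimum": 0, "maximum": 1}}
    },
    "contextTable": {
      "type": "object",
      "required": ["uninfected", "infected_covered", "infected_uncovered_detected", "infected_uncovered_missed"],
      "additionalProperties": false,
      "patternProperties": {"": {"$ref": "#/$defs/clinicalChangeDistribution"}}
    }
  }
}
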