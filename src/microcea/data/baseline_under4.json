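{
  "population": "under4",
  "test": {
    "prevalence": 0.4,
    "sensitivity": 0.8,
    "false_positive": 0.05,
    "bottles_per_patient": 2,
    "empiric_days": 3,
    "definitive_days": 7
  },
  "regimens": [
    {
      "name": "ceftriaxone_gentamicin",
      "drug_cost_per_day": 1.76,
      "coverage": 0.42,
      "stepup_drug_cost_per_day": 12.0,
      "stepdown_drug_cost_per_day": 1.0
    },
    {
      "name": "ampicillin_gentamicin",
      "drug_cost_per_day": 3.04,
      "coverage": 0.42,
      "stepup_drug_cost_per_day": 12.0,
      "stepdown_drug_cost_per_day": 1.5
    },
    {
      "name": "meropenem_vancomycin",
      "drug_cost_per_day": 35.16,
      "coverage": 0.68,
      "stepup_drug_cost_per_day": 80.0,
      "stepdown_drug_cost_per_day": 5.0
    }
  ],
  "transitions": {
    "clinical_change": {
      "uninfected": {
        "improve": 0.7,
        "unchanged": 0.25,
        "deteriorate": 0.05
      },
      "infected_covered": {
        "improve": 0.75,
        "unchanged": 0.15,
        "deteriorate": 0.1
      },
      "infected_uncovered_detected": {
        "improve": 0.6,
        "unchanged": 0.2,
        "deteriorate": 0.2
      },
      "infected_uncovered_missed": {
        "improve": 0.15,
        "unchanged": 0.25,
        "deteriorate": 0.6
      }
    },
    "switch": {
      "informed": {
        "step_up": 0.6,
        "step_down": 0.15,
        "no_change": 0.25
      },
      "clinical": {
        "step_up": 0.1,
        "step_down": 0.15,
        "no_change": 0.75
      }
    }
  },
  "costs": {
    "culture_positive_bottle": 31.9,
    "culture_negative_bottle": 5.8,
    "maintenance_per_sample": 34.53,
    "icu_cost_per_day": 300.0,
    "ward_cost_per_day": 50.0,
    "amr_cost_per_course": 100.0,
    "annual_fixed_lab_cost": 131697.0,
    "annual_samples": 3813
  },
  "outcomes": {
    "mortality": {
      "uninfected": {
        "improve": 0.005,
        "unchanged": 0.01,
        "deteriorate": 0.1
      },
      "infected_covered": {
        "improve": 0.01,
        "unchanged": 0.05,
        "deteriorate": 0.25
      },
      "infected_uncovered_detected": {
        "improve": 0.02,
        "unchanged": 0.08,
        "deteriorate": 0.3
      },
      "infected_uncovered_missed": {
        "improve": 0.05,
        "unchanged": 0.15,
        "deteriorate": 0.45
      }
    },
    "los_days": {
      "uninfected": {
        "improve": 4.0,
        "unchanged": 6.0,
        "deteriorate": 10.0
      },
      "infected_covered": {
        "improve": 5.0,
        "unchanged": 8.0,
        "deteriorate": 12.0
      },
      "infected_uncovered_detected": {
        "improve": 7.0,
        "unchanged": 10.0,
        "deteriorate": 14.0
      },
      "infected_uncovered_missed": {
        "improve": 9.0,
        "unchanged": 12.0,
        "deteriorate": 14.0
      }
    }
  },
  "daly": {
    "years_lost_per_death": 66.0,
    "disability_weight": 0.402,
    "days_per_year": 365.0,
    "cohort_size": 1000,
    "wtp_per_daly": 500.0
  },
  "policies": {
    "fp_branch_policy": "informed",
    "maintenance_unit": "bottle",
    "coverage_stepup_rule": "one_minus_coverage"
  },
  "sources": {
    "test.prevalence": "paper",
    "test.sensitivity": "paper",
    "test.false_positive": "paper",
    "test.bottles_per_patient": "paper",
    "test.empiric_days": "paper",
    "test.definitive_days": "placeholder",
    "regimens.ceftriaxone_gentamicin.drug_cost_per_day": "paper",
    "regimens.ampicillin_gentamicin.drug_cost_per_day": "paper",
    "regimens.meropenem_vancomycin.drug_cost_per_day": "paper",
    "regimens.ceftriaxone_gentamicin.coverage": "placeholder",
    "regimens.ampicillin_gentamicin.coverage": "placeholder",
    "regimens.meropenem_vancomycin.coverage": "placeholder",
    "regimens.ceftriaxone_gentamicin.stepup_drug_cost_per_day": "placeholder",
    "regimens.ampicillin_gentamicin.stepup_drug_cost_per_day": "placeholder",
    "regimens.meropenem_vancomycin.stepup_drug_cost_per_day": "placeholder",
    "regimens.ceftriaxone_gentamicin.stepdown_drug_cost_per_day": "placeholder",
    "regimens.ampicillin_gentamicin.stepdown_drug_cost_per_day": "placeholder",
    "regimens.meropenem_vancomycin.stepdown_drug_cost_per_day": "placeholder",
    "transitions": "placeholder",
    "costs.culture_positive_bottle": "paper",
    "costs.culture_negative_bottle": "paper",
    "costs.maintenance_per_sample": "paper",
    "costs.annual_fixed_lab_cost": "paper",
    "costs.annual_samples": "paper",
    "costs.icu_cost_per_day": "placeholder",
    "costs.ward_cost_per_day": "placeholder",
    "costs.amr_cost_per_course": "placeholder",
    "outcomes": "placeholder",
    "daly.years_lost_per_death": "paper",
    "daly.disability_weight": "paper",
    "daly.days_per_year": "placeholder",
    "daly.cohort_size": "paper",
    "daly.wtp_per_daly": "paper",
    "policies": "placeholder"
  }
}
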