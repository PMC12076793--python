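{
  "_comment": "Plausible sampling ranges for values that the source study keeps in its supplementary appendix. The synthetic generator draws uniformly within these ranges, then enforces only the qualitative orderings stated in the main analysis (broadest-spectrum regimen has the highest coverage; ICU daily cost exceeds ward daily cost; mortality after deterioration exceeds mortality after improvement). Every entry carries a one-line justification.",
  "costs.icu_cost_per_day": {
    "low": 200.0, "high": 400.0,
    "why": "ICU bed-day costs in lower-middle-income tertiary hospitals cluster in the low hundreds of USD."
  },
  "costs.ward_cost_per_day": {
    "low": 30.0, "high": 80.0,
    "why": "General-medicine ward bed-day cost, an order of magnitude below ICU."
  },
  "costs.amr_cost_per_course": {
    "low": 50.0, "high": 200.0,
    "why": "Published per-course societal AMR cost estimates span roughly this band."
  },
  "regimens.narrow.coverage": {
    "low": 0.30, "high": 0.55,
    "why": "Narrow/older empiric combinations cover a minority-to-half of local bloodstream isolates."
  },
  "regimens.broad.coverage_margin": {
    "low": 0.10, "high": 0.30,
    "why": "Carbapenem+glycopeptide coverage sits clearly above the narrow regimens; margin added to the larger narrow draw, capped at 0.95."
  },
  "regimens.narrow.stepup_drug_cost_per_day": {
    "low": 8.0, "high": 20.0,
    "why": "Escalation from a cheap combination to a broader agent."
  },
  "regimens.broad.stepup_drug_cost_per_day": {
    "low": 50.0, "high": 120.0,
    "why": "Escalation beyond carbapenems (e.g. colistin-class) is expensive."
  },
  "regimens.narrow.stepdown_drug_cost_per_day": {
    "low": 0.5, "high": 3.0,
    "why": "De-escalation to a narrow single agent."
  },
  "regimens.broad.stepdown_drug_cost_per_day": {
    "low": 2.0, "high": 8.0,
    "why": "De-escalation from the broad combination still uses mid-price agents."
  },
  "transitions.dirichlet_concentration": {
    "low": 50.0, "high": 50.0,
    "why": "Transition distributions are drawn from a Dirichlet centred on the baseline elicitation-style values with moderate concentration."
  },
  "outcomes.mortality.improve": {
    "low": 0.002, "high": 0.05,
    "why": "Death is rare once the clinical condition improves."
  },
  "outcomes.mortality.deteriorate": {
    "low": 0.20, "high": 0.50,
    "why": "ICU-level deterioration in suspected BSI carries high case fatality."
  },
  "outcomes.los_days.improve": {
    "low": 3.0, "high": 7.0,
    "why": "Short residual stay after improvement."
  },
  "outcomes.los_days.unchanged": {
    "low": 5.0, "high": 12.0,
    "why": "Intermediate stay when the condition is static."
  },
  "outcomes.los_days.deteriorate": {
    "low": 8.0, "high": 21.0,
    "why": "Deterioration prolongs hospitalisation, often via ICU."
  },
  "test.definitive_days": {
    "low": 7.0, "high": 7.0,
    "why": "Definitive-therapy duration after the 3-day empiric reassessment is fixed at 7 days (typical remaining BSI course)."
  }
}
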