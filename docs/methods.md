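# Methods

## Model structure

The model is a static decision tree, evaluated by expected-value rollback,
comparing two fixed policies for every hospitalised patient with suspected
bloodstream infection: an **active laboratory** arm (two blood-culture
bottles drawn, empiric antibiotics started, therapy reassessed after three
days with culture results) and a **no testing** arm (identical empiric
start, all switching driven by clinical condition). Decision nodes are
evaluated by arm selection only — the comparison is between policies, not
an optimisation. There is no time discounting, no Markov extension and no
patient-level microsimulation; every quantity is an expectation over the
tree.

The patient's journey resolves through five chance layers: true infection
(prevalence), empiric coverage of the causative organism (regimen coverage
*c*), culture result (sensitivity / false-positive rate; active arm only),
antibiotic switching, and clinical change. Terminal payloads carry
trajectory-specific mortality and post-diagnosis length of stay.

**Context keying.** Clinical-change distributions, mortalities and stays
are keyed by four contexts: `uninfected`, `infected_covered`,
`infected_uncovered_detected` and `infected_uncovered_missed`. The choice
encodes the causal story: outcomes depend on whether the *final* therapy is
adequate. A covered infection does equally well with or without testing; an
uncovered infection does well only if the culture detects it and triggers
escalation. This is also what makes the benefit of testing scale with
prevalence and with (1 − coverage), and makes expected deaths in the active
arm monotone non-increasing in test sensitivity. The switch layer has two
contexts (`informed`, `clinical`); switching choice does not further modify
the clinical-change distribution, since the coverage state already captures
therapy adequacy.

**Coverage-driven step-up rule.** Given a true-positive culture,
P(step up) = 1 − *c*, realised structurally: the explicit coverage chance
node sends uncovered detected patients to a forced step-up, while covered
patients use the elicitation-style informed switch distribution
renormalised over step-down/no-change. A false-positive culture in an
uninfected patient triggers result-informed switching (the full informed
distribution) but keeps the uninfected outcome distribution; the
alternative — ignore the false positive — is available as
`policies.fp_branch_policy: "clinical"`.

**Costs** (2022 USD) attach to branches: empiric drug-days and one
antimicrobial-resistance (AMR) course cost at entry; laboratory maintenance
per sample at entry (active arm; per bottle by default,
`policies.maintenance_unit: "set"` charges it once per two-bottle set);
bottle costs on the culture-result branch (positive $31.90, negative
$5.80, × bottles); definitive drug-days plus a second AMR course cost on
step-up/step-down branches (a switch completes two courses); ICU daily
cost × stay on deteriorate branches, ward daily cost × stay otherwise.
Monetary quotients (annual cost / annual volume) are rounded half-up at
the cent; the bundled baseline keeps the conventional printed per-sample
value of $34.53 even though the exact quotient 131,697/3,813 = 34.5377
rounds to 34.54, and the validator's consistency rule therefore uses an
absolute one-cent band rather than re-rounding.

## Outcome measure

DALYs = YLL + YLD with no age weighting or discounting. YLL uses a constant
loss per death *L* (11 years for the 55–59 adult band, 66 for under-4s, 20
in a life-table sensitivity variant) rather than a life-table integral; *L*
is a direct input, never recomputed from age. YLD = hospital days ÷ 365 ×
disability weight (0.133 adult, 0.402 under-4, severe acute infectious
episode). `days_per_year` is config-exposed (365, not 365.25). Cohort
scaling (×1000 patients) happens once, in the comparison layer.

The ICER is reported as a label, not a signed ratio, when one arm dominates
(cheaper and more effective) or is dominated; a zero-DALY denominator is
flagged undefined rather than producing infinities. South-west-quadrant
pairs (cheaper, less effective) keep their positive ratio but carry the
quadrant flag.

## Baseline parameter values and placeholders

Every value printed in the source study's main text is fixed in the
bundled baseline and tagged `source: "paper"`: prevalence 0.40, sensitivity
0.80, false-positive 0.05, two bottles, three empiric days, drug costs
$1.76/$3.04/$35.16 per day, bottle costs $31.90/$5.80, maintenance $34.53
(annual $131,697 over 3,813 samples), DALY constants, WTP $500.

Everything else in the original analysis lives in an unpublished appendix
and is shipped as a `"placeholder"`-tagged stand-in with a documented
range (`src/microcea/data/placeholder_ranges.json`). Two calibration
anchors were used when fixing the baseline placeholders, both printed in
the source's main text: regimen coverages (0.42, 0.42, 0.68) were chosen so
that the implied deterioration proportion among false-culture-negative
infections, c·P(det|covered) + (1−c)·P(det|uncovered missed), equals the
reported 39%, 39% and 26% for the three regimens; and ICU ($300/day) and
ward ($50/day) placeholder costs put the baseline cohort savings in the
reported low-hundreds-of-thousands range. Absolute baseline outputs remain
illustrative: with these placeholders the model reproduces the qualitative
findings (dominance for all three regimens, ~20–45 deaths averted per 1000,
savings largest for the cheap narrow regimens, break-even near ~1100
annual samples) but not, and not intended to, the published tables row by
row. In particular the published ordering that puts the broad-spectrum
regimen highest in deaths averted depends on appendix-only elicited
distributions; under the coverage-mediated topology used here the broad
regimen averts the fewest deaths because fewer of its patients need
rescue.

## Probabilistic sensitivity analysis

Multinomial transition nodes draw from Dirichlet distributions
(concentration = baseline vector × effective sample size), binary
probabilities from beta (α = m·ess, β = (1−m)·ess), and ICU/ward daily
costs from lognormal matched to the arithmetic mean and coefficient of
variation (keeping costs positive). The dispersion hyperparameters are not
stated in the source's main text; defaults are ess = 30 (moderate
elicitation-panel confidence) and cv = 0.3, both config-overridable and
placeholder-tagged — PSA interval *widths* therefore characterise this
package's uncertainty model, not the original study's. Parameters are
drawn independently (no correlation structure). A draw that violates any
invariant is resampled, up to 100 attempts, then the run aborts with
diagnostics; resampling avoids the bias of clipping. Summaries use
mean and 25th/50th/75th percentiles with linear interpolation between
order statistics, pinned for bit-reproducibility; all randomness flows
from one integer seed through a single `numpy.random.Generator`, and the
per-iteration evaluation rebuilds both arms' trees from the drawn
parameter set. Default size: 5000 iterations (≈5 s on one CPU).

## Deterministic sensitivity analysis and break-even searches

One-way sweeps re-evaluate the full comparison with a single parameter
path overridden (baseline value always included); an out-of-range value
aborts the scenario. Low/high defaults of ±50% apply where the source
prints none. Sweeping the per-sample maintenance cost (or the annual
volume) rescales its partner field so the annual-cost/volume pair stays
self-consistent. Break-even searches bisect: per-sample cost to a $0.01
tolerance, annual volume to the smallest integer satisfying the criterion
(per-sample cost recomputed as fixed annual cost ÷ volume at every step),
with an explicit bracket check at the bounds and the criterion values just
below/above the threshold reported as evidence. Incremental cost is exactly
linear in the per-sample maintenance cost with slope = bottles ×
cohort size, which the tests verify against the closed form.

## Coverage model

Regimen coverage from an antibiogram (CSV; organism, isolate count, S/R/U
per antibiotic) is the isolate-count-weighted fraction of isolates covered.
Default rule `any_agent` (a combination covers if ≥1 component is
susceptible; `all_agents` available); intermediate results map to R
(conservative, pinned); rows whose verdict an unknown status could flip are
excluded from numerator and denominator with a logged tally.

## Synthetic-data generator

`generate_parameter_set(seed)` emulates the *form* of the study inputs:
printed values held fixed (checked field-by-field in the tests), appendix
-style values drawn uniformly from the documented ranges, transition
distributions jittered by a Dirichlet (concentration 50) around the
baseline. Only the orderings the analysis states are enforced — broad
-regimen coverage strictly highest, ICU > ward daily cost, deterioration
mortality > improvement mortality — everything else is free within range,
to avoid inventing unstated structure. `generate_antibiogram` draws each
isolate's per-regimen covered status as an independent Bernoulli at the
target coverage and constructs a consistent S/R pattern (the shared
gentamicin column resolved jointly), so computed coverage converges to the
target at the binomial 1/√n rate.

What the generator does **not** emulate: correlation between parameters,
organism-mix structure in the antibiogram, regimen-specific outcome
distributions beyond the coverage mechanism, or any appendix value's true
location within its range. Tests passing on generated data therefore
demonstrate the *machinery* (tree algebra, metric arithmetic, Monte Carlo
plumbing) on realistic inputs, not agreement with the original study's
data.

## Numerical choices and degenerate inputs

Probability distributions must sum to 1 within 1e-9. Zero-probability
branches are pruned at construction, so enumerated path probabilities are
strictly positive and sum to 1 within 1e-9; rollback and exhaustive path
enumeration agree to 1e-9 (property-tested over random generated parameter
sets). A test with zero sensitivity and zero false-positive rate leaves
health outcomes identical across arms and shifts cost by exactly
bottles × (negative-bottle + maintenance) per patient — a closed-form
limit used as an acceptance check. If the informed switch distribution has
zero mass outside step-up, covered detected patients fall back to
no-change. Beta draws with a degenerate hyperparameter (mean 0 or 1)
return the corresponding point mass.

## Known limitations

* Absolute costs/DALYs depend on placeholder inputs; only qualitative and
  structural results are meaningful out of the box. Users with access to
  locally elicited values should supply their own config
  (`schema/parameterset.schema.json`).
* Clinical-change distributions do not depend on the switching action
  taken, only on the coverage/detection context.
* The same transition placeholders serve the adult and under-4 populations;
  only the DALY constants differ between the bundled configs.
* No EVPI/EVPPI, no multi-way DSA surfaces, no >2-arm frontier.
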