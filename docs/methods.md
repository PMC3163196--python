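# Methods

## Model structure and assumptions

A model describes one region and one condition. The diagnosed
population (population × diagnosed prevalence, rounded half-to-even) is
characterised by:

* **Level 2** — disease type/stage categories, assumed *mutually
  exclusive and exhaustive*: their prevalences must sum to 10,000 per
  10,000 diagnosed persons (tolerance 1e-6). "Newly diagnosed" is
  modelled as its own category (e.g. "type 2, newly diagnosed" with a
  first-year protocol) rather than a cross-cutting flag, so the five
  exemplar categories count disease type and recency together.
* **Levels 3 and 4** — complications and threats to self-care
  capacity, modelled as *independent* Bernoulli flags with the stated
  marginal prevalences. Only marginal prevalences are observable from
  population surveys, so the joint distribution is the maximum-entropy
  independent one. Real comorbidities are correlated (obesity and
  cardiovascular disease co-occur more than independence predicts);
  under the max rule positive correlation would *lower* true demand
  slightly, so independence errs conservative there. A user-supplied
  joint distribution is not supported; `sample_patient_need` is the
  extension point if one is ever needed.
* **Level 1** — prevention/screening strata of the *general* regional
  population, treated as disjoint programs whose person counts are left
  real-valued (population × prevalence/10,000, no rounding). They are
  assumed disjoint from the diagnosed population and never enter
  patient types.

Each attribute has exactly one care protocol: consults/year ×
minutes/consult per competency. The canonical quantity is *annual
minutes*; duplicate items for one competency are merged at load time by
summing annual minutes. The model is a single-year steady state — no
incidence, progression or mortality dynamics.

## Combination calculus

Per patient type, need combines as max-within-level (per competency,
independently; ties need no tie-break because equal values commute) and
add-across-levels. Level 2 contributes a single category, so both
within-level rules coincide there. The `add` within-level rule is the
sensitivity variant; for every patient type and competency
`need(max) ≤ need(add)`, so the default is a floor on demand. Level-4
attributes contribute their own consult items additively across levels
like any other module; the alternative reading of threats as
*multipliers* on other protocols was considered and not implemented —
nothing in the protocol formalism supplies a multiplier scale, and it
would break the cross-level additivity that makes the calculus
auditable.

## Demand computation: three routes

**Analytic** (`regional_demand`). Exact expectation over the
patient-type distribution. Level 2 contributes Σ p<sub>c</sub>
m<sub>c</sub>; levels 3/4 under `max` contribute, per competency, the
expectation of the maximum of independently present values via the
sorted survival-product formula

    E[max] = Σ_i m_i · p_i · Π_{j<i} (1 − p_j),   m_1 ≥ m_2 ≥ …

(term *i* = probability attribute *i* is present and nothing larger
is; the descending sort makes the product the survival function of
"some larger-minutes attribute present"). Attributes with zero minutes
for a competency are skipped — they cannot raise a non-negative
maximum. O(k log k) per competency versus 2^k enumeration, so the full
exemplar is instant.

**Exhaustive enumeration** (`brute_force_demand`). The oracle. Builds,
per level, the need vector and joint probability of *every* subset by
bitmask recursion (max or sum over members — deliberately independent
of the survival-product formula), then forms every joint patient type
(level-2 × level-3 subset × level-4 subset) explicitly, weighting each
type's need by p₂ · Π present p · Π absent (1−p). Guarded by a cap on
the type count (default 2²², refusing with the count); the inner level-4
loop is vectorised, so the exemplar's 2,621,440 types take ~1 s. When
some p = 1 the incremental probability recursion would divide by zero,
so subset probabilities are recomputed by direct products in that case.

**Monte Carlo** (`monte_carlo_demand`). Samples patients (categorical
level 2; independent Bernoulli levels 3/4) with one
`numpy.random.default_rng(seed)` generator — no global state — in
chunks of 20,000 to bound memory, and reports per-competency standard
errors (ddof=1). Level-1 program demand is deterministic and is added
to all three routes without error.

## Workforce mapping

Scenario share matrices must have rows summing to one (tolerance 1e-9),
so occupation hours conserve competency hours exactly; scenarios only
redistribute. FTE = hours / (contracted h/wk × wk/yr × clinical
activity fraction); headcount = FTE / participation rate. Both are left
real-valued by default — planning aggregates should not accumulate
rounding — with ceiling available as a report option (`--round-up`).
Which occupations may deliver which competency is asserted by the
scenario author; no eligibility matrix is enforced beyond coverage of
every competency with nonzero demand. Productivity differences by
experience and role-substitution dynamics are out of scope, as is any
supply-side stock-and-flow projection.

## The diabetes exemplar

The packaged exemplar reproduces the documented *structure* of a
primary-care diabetes model for a region of 250,000 at 4% known
prevalence: 24 attributes — 5 level-2 categories, 10 complications, 9
threats to self-care capacity — and 12 competencies at two skill
levels, with generalist and specialist delivery scenarios. The numeric
cells are another matter: all prevalences and protocol timings carry
`provenance: "placeholder"` and were chosen once to be clinically
plausible and to satisfy every invariant (level-2 partition; morbidity
gradients such as newly diagnosed ≫ established in education minutes).
Attribute names not attested in published sources are marked
"(reconstruction)". Conclusions about real diabetes services should not
be drawn from the exemplar's numbers, only from its mechanics; the
exemplar deliberately contains no level-1 strata, so its 24 attributes
are exactly the diagnosed-population attributes.

## Synthetic models

`generate_random_model` emulates the structure above at configurable
size: level-2 prevalences drawn Dirichlet and pinned to partition
10,000 exactly; level-1/3/4 prevalences log-uniform in (50, 4000) per
10,000 by default, exercising both rare and common attributes; consult
counts uniform integers in 1–12; durations from the clinic-typical grid
{10, 15, 20, 30, 45, 60} min; each protocol includes each competency
with probability `sparsity` (default 0.35) and never ends up empty.
Defaults mirror the exemplar's sizes (5/10/9 attributes, 12
competencies, 250,000 persons at 4%). Generated models mimic structure
only — no real epidemiology, no attribute correlation, no association
between prevalence and care intensity — so passing property tests shows
the *calculus* is right, not that any particular region's numbers are.

## Numerical choices

* Prevalences are stored per 10,000 (the natural survey framing) and
  divided by 10,000 internally; hours = minutes/60 exactly at reporting.
* Person counts round half-to-even (Python/IEEE `round`); only the
  diagnosed count is rounded.
* Oracle agreement is asserted at 1e-9 relative; observed agreement is
  ~1e-15 (pure floating-point reordering).
* Monte-Carlo checks use a 4-standard-error band (nominal exceedance
  ~6e-5 per comparison). Prevalence recovery is checked against exact
  binomial 99% intervals per marginal with a family-wise allowance —
  misses up to the 99.9th percentile of Binomial(k, 0.01) — because
  with k marginals ~1% fall outside their own interval by design.
* Enumeration sizes use exact integer arithmetic; iteration order is
  documented (level-2 declaration order, then level-3/level-4 subset
  bitmasks ascending, level 4 fastest).
* CSV output fixes floats at 10 significant digits, so a rerun with
  the same seed reproduces files byte-for-byte.

## Problem sizes used in the shipped checks

Oracle-equivalence runs compare 200 random models (2 level-2, 3
level-3, 3 level-4 attributes, 5 competencies) under both rules plus
the full exemplar; the minimum-estimate sweep uses 1,000 random models
regionally and every patient type of 50 smaller ones; Monte-Carlo
consistency uses 20 models × 100,000 simulated patients. These sizes
give sub-minute wall time while leaving the statistical tolerances
meaningful.

## Known limitations

Independence of comorbidities (above); single condition per model — no
shared care time across conditions; strict cross-level additivity even
where one consult might address a complication and a threat together;
no longitudinal variation over the course of the condition or life
stages; placeholder exemplar numbers. These are properties of the
planning formalism, not bugs in the implementation.
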