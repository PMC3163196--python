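# webforce

Needs-based health workforce planning for chronic disease care.

Most workforce planning extrapolates the *current* supply of providers.
`webforce` instead derives regional workforce requirements from
population health need: the prevalence of clinically meaningful patient
attributes, and the best-practice care each attribute requires. It is
aimed at health-services researchers and regional planners who want to
ask "how many hours of which clinical competencies does this population
need per year, and what staffing mix could deliver them?"

## The model

A region's diagnosed population is described by a four-level
patient-attribute taxonomy:

1. **prevention/screening strata** of the general or at-risk population,
2. **type or stage of disease** — mutually exclusive categories that
   partition the diagnosed population,
3. **complications** — independent binary flags,
4. **threats to self-care capacity** (e.g. impaired physical ability,
   poor language proficiency) — independent binary flags.

Each attribute *a* carries a prevalence per 10,000 of its reference
population and a care protocol giving annual consult minutes
m<sub>a,c</sub> per competency *c*. A patient type is one level-2
category plus any subset of level-3 and level-4 attributes; with 5
categories, 10 complications and 9 threats that is 5 × 2¹⁰ × 2⁹ =
2,621,440 types. Per patient, care time combines as:

* **within a level**: per competency, take the *maximum* annual minutes
  over the attributes present (related issues can share a consult) —
  the conservative default, making results a *minimum* estimate of
  need. An additive within-level rule (`add`) is available as a
  sensitivity variant and always dominates `max`.
* **across levels**: add, since levels address distinct kinds of need.

Regional demand is the exact expectation over the patient-type
distribution, scaled by the diagnosed count. Under independent
attribute presence the within-level maximum has a closed form: sorting
a competency's minutes m₁ ≥ m₂ ≥ … with presence probabilities pᵢ,

&nbsp;&nbsp;&nbsp;&nbsp;E[max] = Σᵢ mᵢ pᵢ Π<sub>j&lt;i</sub> (1 − pⱼ).

An exhaustive patient-type enumerator and a Monte-Carlo microsimulator
compute the same quantity by independent routes and serve as
cross-checks. Competency hours are then mapped to occupations through
delivery scenarios (share matrices — e.g. generalist- vs
specialist-led), and converted to FTE and headcount:

&nbsp;&nbsp;&nbsp;&nbsp;FTE = hours / (contracted h/wk × wk/yr × clinical activity fraction),
&nbsp;&nbsp;&nbsp;&nbsp;headcount = FTE / participation rate.

## Worked example

The packaged diabetes exemplar describes a region of 250,000 persons at
4% known-diabetes prevalence (10,000 diagnosed) with 24 patient
attributes. Its prevalences and protocol timings are documented
placeholders that satisfy all model invariants — structure is real,
numbers are illustrative.

Annual care need of one patient type — established type 2 diabetes with
eye disease and poor English proficiency:

```
$ webforce need --model src/webforce/models/diabetes_exemplar.json \
    --patient "t2_established+eye_disease+low_english"
competency_id,skill_level,annual_hours
care_planning,advanced,0.75
clinical_review,basic,1.333333333
cultural_liaison,basic,2
diabetes_education,basic,1.5
foot_care,basic,0.3333333333
medical_nutrition,basic,0.5
retinal_assessment,advanced,1.166666667
```

This patient needs 7.6 clinical hours/year; the 1.17 h of retinal
assessment is the *maximum* of the routine (0.17 h) and eye-disease
(1 h) protocol entries at level 3 plus the level-2 schedule — not their
sum across complications.

Regional demand and a staffing plan under the generalist scenario:

```
$ webforce demand --model src/webforce/models/diabetes_exemplar.json | head -4
competency_id,skill_level,annual_hours
care_planning,advanced,8870
clinical_review,basic,17091.29797
cultural_liaison,basic,3256

$ webforce plan --model src/webforce/models/diabetes_exemplar.json --scenario generalist
occupation,annual_hours,fte,headcount
diabetes_educator,4783.52,3.420709382,3.800788202
dietitian,7468.176,5.696549199,6.701822587
endocrinologist,382.5,0.3812799043,0.4013472677
gp,26888.0075,21.9745076,24.41611956
...
```

Under the conservative rule the region needs ≈91,669 competency-hours
per year (≈94,417 under the additive variant), about 70 FTE across the
multidisciplinary team; the specialist scenario redistributes the same
hours toward endocrinology, psychology and allied health. Other
subcommands: `validate`, `compare` (all scenarios side by side),
`synth` (random valid models for testing), with `--rule max|add`,
`--method analytic|mc|brute`, `--format csv|json` and `--seed` flags.
Library equivalents live in `webforce.schema`, `.protocols`, `.demand`,
`.workforce` and `.synth`.

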