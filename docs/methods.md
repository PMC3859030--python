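# Methods

## The staging model

The engine implements a TNM-analogue staging of heart failure as a pure,
deterministic function from a structured patient record to three ordinal
components and their concatenated code.

**Heart (H).** Six tristate criteria are derived from the cardiac panel:
systolic dysfunction, diastolic dysfunction, structural damage (LV
hypertrophy or previous myocardial infarction, NSTEMI or STEMI), LV
remodeling, severe ejection fraction (EF strictly below 35 %), and
biventricular involvement (RV dysfunction together with any LV dysfunction).
The rules are evaluated highest-first:

| stage | rule |
|---|---|
| H4 | biventricular dysfunction |
| H3 | remodeling AND (systolic + diastolic dysfunction, or severe EF) |
| H2 | any LV dysfunction evidence AND structural damage |
| H1 | any LV dysfunction evidence without structural damage |
| not stageable | no dysfunction evidence |

"LV dysfunction evidence" includes severe EF, so an isolated EF < 35 % is
stageable (H1 or H2 depending on structure) even when the adjudicated
dysfunction flags are unknown; in H3 severe EF may substitute for the
dysfunction pair but remodeling remains mandatory — the severity
parenthetical attaches to the dysfunction clause, not to remodeling. The
ladder has no H0; a record with no dysfunction evidence is reported as not
stageable (`H?` in the code) rather than forced into a stage.

**Lung (L).** Hemodynamics are classified first: pulmonary hypertension (PH)
is resting mPAP strictly above 25 mmHg, or — only when no resting value
exists — exercise mPAP above 30 mmHg. Among PH patients, PAWP ≤ 15 mmHg is
precapillary (boundary inclusive) and > 15 mmHg postcapillary; PH with a
missing wedge pressure has unknown subtype and, conservatively, contributes
no congestion evidence. The ladder: L3 cardiac lung; L2 clinical congestion
(signs/symptoms, pulmonary edema — which always forces at least L2 — and,
by default, pleural effusion); L1 hemodynamic congestion (postcapillary PH,
precapillary PH under the default configuration, or bedside surrogates of
elevated filling pressure: abnormal Valsalva response, orthostatic
blood-pressure changes, abnormal nitroglycerin response); L0 no involvement.
L0 extends the published ladder, which starts at L1 and leaves the
no-involvement case undefined; results carry a warning noting the extension.

**Malfunction of other organs (M).** Kidney, liver and brain each get a
tristate verdict with an evidence list:

* *kidney* — creatinine clearance below its sex-specific reference range
  (the measured clearance when available, otherwise the Cockcroft–Gault
  estimate), simplified-MDRD GFR below 60 mL/min/1.73 m², or elevated
  cystatin C. Serum creatinine outside 0.7–1.3 mg/dL and elevated BUN are
  recorded as supportive evidence only: creatinine is confounded by muscle
  mass and BUN by catabolic state, so neither triggers alone.
* *liver* — at least two abnormal laboratory tests among bilirubin, ALT,
  AST, ALP, γ-GT, decreased albumin and abnormal INR (the INR is excluded
  from evidence in anticoagulated patients, roughly a third of this
  population), since single liver tests are aspecific; alternatively any
  hemodynamic/structural sign — ascites, reduced portal flow, a
  non-collapsing inferior vena cava — suffices alone.
* *brain* — cerebral hypoperfusion or depression.

The count of malfunctioning organs attributable to heart failure maps
0/1/2/≥3 → M0/M1/M2/M3. Attribution is an input tristate defaulting to
unknown, and unknown attribution *counts*: the engine cannot adjudicate
etiology and excluding unknowns would systematically understage. Low BMI
(cachexia) is surfaced as a severity warning, not a counted organ, because
no cutoff is established; the configuration can add it as a fourth organ
with a user-supplied cutoff, and the ≥3 mapping already accommodates that.

## Missing-data semantics

Every clinical flag is a tristate; "unknown" is distinct from a value absent
from the input file only at the I/O layer (both parse to unknown, but
serialization writes the explicit word so round-trips are lossless). The
single global rule is: **unknown never satisfies a criterion.** Its
consequence, verified by property tests, is monotone degradation — removing
information can lower a stage component or make the heart unstageable, never
raise anything. Nothing is imputed; instead each result reports the
fraction of the 31 staging-relevant clinical fields that were observed.

## Parameters

All thresholds live in `ReferenceConfig` and are overridable via a flat YAML
file (unknown keys rejected):

| parameter | default | unit | provenance |
|---|---|---|---|
| `mpap_rest_cutoff` | 25 | mmHg | published PH definition (strict >) |
| `mpap_exercise_cutoff` | 30 | mmHg | published exercise threshold |
| `pawp_cutoff` | 15 | mmHg | pre/postcapillary split (≤ is precapillary) |
| `ef_severe_cutoff` | 35 | % | published severe-EF criterion (strict <) |
| `ef_systolic_cutoff` | 50 | % | extra-source heuristic; see below |
| `scr_normal` | [0.7, 1.3] | mg/dL | published reference interval |
| `clcr_normal_female` | [57, 115] | mL/min | published reference interval |
| `clcr_normal_male` | [95, 145] | mL/min | published reference interval |
| `lvdd_normal` | 50 ± 5 | mm | published LV diameter reference |
| `lvsd_normal` | 31 ± 5 | mm | published LV diameter reference |
| `gfr_malfunction_cutoff` | 60 | mL/min/1.73 m² | chronic-kidney-disease convention |
| `liver_min_abnormal_labs` | 2 | count | single tests deemed aspecific |
| `bun_upper` | 20 | mg/dL | extra-source laboratory convention |
| `cystatin_upper` | 1.0 | mg/L | extra-source laboratory convention |

Reference intervals are closed: boundary values count as within. The source
material lists the two LV diameter references as "systolic and diastolic
… 50 ± 5 and 31 ± 5"; that pairing contradicts the universal clinical fact
that the end-diastolic diameter is the larger, so 50 ± 5 maps to
end-diastolic and 31 ± 5 to end-systolic, overridable in configuration.

Systolic dysfunction is primarily a site-adjudicated flag; when the flag is
unknown but an EF is present it is auto-derived as EF < 50 % (the published
rules name the criterion but print no cutoff other than the severe 35 %).
The heuristic is configurable and can be disabled
(`auto_systolic_from_ef: false`). Diastolic dysfunction (transmitral-flow
based) and cardiac lung (vascular arterialization) are adjudicated flags
with no numeric criterion. The "diminished INR" wording in the source is
direction-ambiguous relative to the usual hepatic scores, so the engine uses
a direction-agnostic `inr_abnormal` flag.

Units are fixed: creatinine mg/dL (the MDRD constant 186 belongs to that
convention; creatinine supplied in µmol/L is converted ÷ 88.4 on read),
pressures mmHg, weight kg, height m, diameters mm. Derived values are
carried at full precision; rounding to one decimal happens only in reports.

## Synthetic cohorts

No clinical dataset accompanies the staging proposal, so the
`cohort` module generates stage-conditional records: for a target
(h, l, m) triple it samples physiology that provably satisfies exactly that
stage's rules. Sampling is *threshold-adjacent* rather than
population-realistic — e.g. an L1 target draws resting mPAP uniformly in
(25, 45] mmHg with PAWP in (15, 25] mmHg and all sign flags absent; a
malfunctioning kidney back-solves the serum creatinine that puts the
Cockcroft–Gault clearance at a chosen point below the reference range.
Demographic ranges (age 45–80, weight 55–95 kg, height 1.55–1.90 m) reflect
the predominantly older heart-failure population. Cohort composition is
stratified by largest-remainder apportionment, so requested stage mixes are
hit exactly at zero missingness; per-patient randomness comes from numpy
substreams seeded by (seed, index), making cohorts reproducible and
order-stable. The generator emulates rule-relevant physiology only: it does
not model correlations between panels, longitudinal course, measurement
noise around adjudicated flags, or realistic prevalence — passing round-trip
tests therefore demonstrates rule correctness and conservative missing-data
behaviour, not performance on real clinical distributions.

## Numerical and design notes

* All comparisons are exact floating-point comparisons against configured
  cutoffs with the strictness stated above (PH strictly >, severe EF
  strictly <, precapillary boundary inclusive); no tolerances are applied,
  so bisection over any boundary recovers the configured value to machine
  precision.
* Stage precedence is strict highest-first; the decision tables are total
  (every tristate combination maps to exactly one outcome) and monotone
  (worsening a single criterion never lowers a stage), both verified
  exhaustively against declarative re-encodings of the tables.
* Reference-range flags are four-valued (within/below/above/unknown) rather
  than plain tristates because the kidney rule is directional: only a *low*
  clearance is malfunction.
* The classifier validates before staging and rejects invalid records with
  the complete violation list; validation itself returns violations as data
  and never mutates or raises.
* Degenerate inputs: an entirely empty clinical record stages as
  `H?L0M0` with completeness 0 and explicit warnings, not an error.
* The Cockcroft–Gault domain is scr > 0, 18 ≤ age < 140, weight > 0;
  simplified MDRD requires adult age unless diagnostics mode
  (`check_ranges=False`) is selected for analytic probes.

## Problem sizes

The exhaustive suites cover all 3⁶ cardiac truth-table combinations (with
single-criterion perturbations), all sign/PH combinations for the lung
table, the full 4×4×4 target grid across ten seeds for the
generate-classify round-trip, and 10⁴-point grids for the formula oracles;
the whole suite runs in a few seconds on one CPU.

## Known limitations

* The engine is cross-sectional: it does not model congestion time-course,
  therapy response, or prognosis, and emits therapy-tier notes as
  descriptive text only.
* Cardiorenal-syndrome typing (types 1–5) is directional taxonomy, not a
  decision rule; the engine only annotates when cardiac and renal findings
  co-occur.
* MELD and Child–Pugh composite scores are out of scope (their formulas are
  not part of the staging rules); so is any image/signal acquisition — the
  engine consumes adjudicated numeric and flag outputs.
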