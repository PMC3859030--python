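# hlmstage

A deterministic, auditable rule engine for **HLM staging of heart failure** —
a TNM-like clinical classification that grades, per patient:

* **H** (Heart, H1–H4): extent of cardiac damage, from isolated systolic or
  diastolic left-ventricular dysfunction (H1), through dysfunction with
  structural damage — hypertrophy or previous myocardial infarction — (H2)
  and combined dysfunction (and/or EF < 35 %) with LV remodeling (H3), to
  biventricular failure (H4);
* **L** (Lung, L0–L3): pulmonary involvement — hemodynamic congestion (L1),
  clinical congestion including pulmonary edema (L2), cardiac lung (L3);
  L0 marks no involvement;
* **M** (Malfunction of other organs, M0–M3): the number of extra-cardiac
  organs (kidney, liver, brain) malfunctioning due to heart failure,
  mapped 0 / 1 / 2 / ≥3 → M0 / M1 / M2 / M3.

The three components concatenate into a code such as `H2L2M1`. The engine is
built for clinical researchers and methodologists who want the staging rules
applied reproducibly to tabular cohort data, with per-criterion provenance
for audit.

The rules consume formula-derived quantities computed here as well:

* Cockcroft–Gault creatinine clearance (mL/min):
  `ClCr = (140 − age) · weight / (72 · SCr)`, × 0.85 in women
  (reference 57–115 mL/min women, 95–145 mL/min men);
* simplified MDRD GFR (mL/min/1.73 m²):
  `GFR = 186 · SCr^−1.154 · age^−0.203`, × 0.742 in women, × 1.21 in black
  patients (SCr in mg/dL);
* BMI = weight (kg) / height (m)².

Pulmonary hemodynamics use the standard cutoffs: pulmonary hypertension at
resting mPAP > 25 mmHg (> 30 mmHg on exercise), precapillary vs
postcapillary split at PAWP ≤ 15 vs > 15 mmHg.

Missing data are first-class: every clinical flag is a tristate
(present/absent/unknown) and an unknown criterion never satisfies a rule, so
incomplete records can only understage, never overstage. Each result carries
a completeness fraction and the full list of evaluated criteria.

## Worked example

Generate a tiny synthetic cohort spanning four milestone stages, stage it,
and inspect one patient:

```sh
hlmstage simulate --n 4 --mix "H1L1M0:1,H2L2M1:1,H3L2M2:1,H4L3M3:1" --seed 17 -o toy.csv
hlmstage stage toy.csv
```

```
patient_id,h_stage,l_stage,m_stage,code,malfunctioning_organs,completeness,warnings
P00000,1,1,0,H1L1M0,,1.000,
P00001,2,2,1,H2L2M1,kidney,1.000,cardiac dysfunction with renal malfunction: consistent with a cardiorenal syndrome (descriptive annotation only)
P00002,3,2,2,H3L2M2,kidney|liver,1.000,...
P00003,4,3,3,H4L3M3,brain|kidney|liver,1.000,...
```

Each row is one patient: the three stage components, the assembled HLM code,
which organs counted toward M, and the fraction of staging-relevant inputs
that were observed. `hlmstage explain toy.csv P00001` prints the audit
trail — every criterion with its value and whether it fired:

```
patient P00001
HLM code: H2L2M1
completeness: 1.000
note: second-tier, organ-protective therapy orientation
criteria:
 * h.systolic_dysfunction = present
   h.diastolic_dysfunction = absent
 * h.structural_damage = present
   ...
 * m.kidney = present  [evidence: creatinine_clearance_below_reference, smdrd_gfr_below_cutoff, cystatin_c_elevated; supportive: bun_elevated, serum_creatinine_outside_reference]
```

The same functionality is available as a library:

```python
from hlmstage import classify, generate_patient

record = generate_patient((2, 2, 1), seed=17)
result = classify(record)
print(result.code)          # H2L2M1
print(result.completeness)  # 1.0
```

Thresholds live in a `ReferenceConfig` (overridable via a flat YAML file
passed as `--config`); the input column dictionary is in
`docs/column_dictionary.md` and the modeling notes in `docs/methods.md`.

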