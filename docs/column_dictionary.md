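# Cohort file column dictionary

Cohort tables are comma-separated UTF-8 text with a mandatory header row and
one row per patient. An empty cell means missing. Tristate columns accept
`present`/`absent`/`unknown`, `1`/`0`, `true`/`false`, `yes`/`no`; an empty
tristate cell reads as unknown. Unknown columns are rejected unless the
reader is invoked with `--lax`.

Mandatory columns: `patient_id` (unique), `age`, `sex`, `black_ethnicity`,
`weight_kg`, `height_m`. Everything else is optional.

| column | type | unit / values | notes |
|---|---|---|---|
| `patient_id` | string | — | unique within the file |
| `age` | integer | years | ≥ 18 |
| `sex` | enum | `female`/`male` (or `f`/`m`) | |
| `black_ethnicity` | boolean | `1`/`0`, `true`/`false` | MDRD ethnicity factor |
| `weight_kg` | number | kg | > 0 |
| `height_m` | number | m | > 0 |
| `ejection_fraction` | number | % | 0–100 |
| `systolic_dysfunction` | tristate | | adjudicated; auto-derived from EF when unknown |
| `diastolic_dysfunction` | tristate | | transmitral-flow adjudicated |
| `lv_hypertrophy` | tristate | | structural damage |
| `previous_mi` | enum | `none`/`nstemi`/`stemi`/blank | blank = unknown |
| `lv_end_diastolic_diameter_mm` | number | mm | reference 45–55 |
| `lv_end_systolic_diameter_mm` | number | mm | reference 26–36 |
| `lv_remodeling` | tristate | | inferred present when a diameter is dilated |
| `rv_dysfunction` | tristate | | |
| `mpap_rest_mmhg` | number | mmHg | PH if > 25 |
| `mpap_exercise_mmhg` | number | mmHg | used only without a resting value; PH if > 30 |
| `pawp_mmhg` | number | mmHg | ≤ 15 precapillary, > 15 postcapillary |
| `hemo_source` | enum | `catheterization`/`echo_estimate`/blank | informational |
| `clinical_congestion_signs` | tristate | | cardiopulmonary + systemic signs |
| `pulmonary_edema` | tristate | | forces at least L2 |
| `pleural_effusion` | tristate | | clinical-congestion evidence by default |
| `cardiac_lung` | tristate | | L3 criterion |
| `abnormal_valsalva` | tristate | | bedside filling-pressure surrogate |
| `orthostatic_bp_abnormal` | tristate | | bedside surrogate |
| `nitroglycerin_response_abnormal` | tristate | | bedside surrogate |
| `serum_creatinine` | number | per `creatinine_unit` | |
| `creatinine_unit` | enum | `mg/dL` (default) or `umol/L` | µmol/L converted ÷ 88.4 |
| `bun_mg_dl` | number | mg/dL | supportive evidence only |
| `cystatin_c_mg_l` | number | mg/L | |
| `measured_clcr_ml_min` | number | mL/min | preferred over the Cockcroft–Gault estimate |
| `bilirubin_elevated` | tristate | | liver lab |
| `alt_elevated` | tristate | | liver lab |
| `ast_elevated` | tristate | | liver lab |
| `alp_elevated` | tristate | | liver lab |
| `ggt_elevated` | tristate | | liver lab |
| `albumin_decreased` | tristate | | liver lab |
| `inr_abnormal` | tristate | | ignored as evidence when anticoagulated |
| `on_anticoagulants` | boolean | blank = false | |
| `ascites` | tristate | | hemodynamic liver sign |
| `portal_flow_reduced` | tristate | | hemodynamic liver sign |
| `ivc_noncollapsing` | tristate | | hemodynamic liver sign |
| `cerebral_hypoperfusion` | tristate | | brain criterion |
| `depression` | tristate | | brain criterion |
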