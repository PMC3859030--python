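"""Orchestration: run the three stage engines and assemble the HLM code.

``classify`` is deterministic and side-effect free.  It never imputes:
unknown inputs lower the completeness fraction and are surfaced in the
provenance trail, but they never satisfy a rule.
"""

from __future__ import annotations

import re

from .derived import bmi as compute_bmi
from .derived import derive_renal
from .heart import derive_cardiac_findings, stage_h
from .lung import classify_ph, derive_pulmonary_findings, stage_l_from_findings
from .model import (
    HStage,
    PatientRecord,
    PHType,
    PRESENT,
    ProvenanceEntry,
    ReferenceConfig,
    StageResult,
    Tristate,
    UNKNOWN,
    ValidationError,
    validate_record,
)
from .organs import (
    assess_brain,
    assess_kidney,
    assess_liver,
    malfunctioning_organs,
    stage_m,
)

#: Clinical inputs counted in the completeness fraction (demographics are
#: mandatory at validation and therefore not counted).
_REQUIRED_FIELDS: tuple[tuple[str, str], ...] = (
    ("cardiac", "ejection_fraction"),
    ("cardiac", "systolic_dysfunction"),
    ("cardiac", "diastolic_dysfunction"),
    ("cardiac", "lv_hypertrophy"),
    ("cardiac", "previous_mi"),
    ("cardiac", "lv_remodeling"),
    ("cardiac", "rv_dysfunction"),
    ("hemodynamics", "mpap_rest"),
    ("hemodynamics", "pawp"),
    ("pulmonary", "clinical_congestion_signs"),
    ("pulmonary", "pulmonary_edema"),
    ("pulmonary", "pleural_effusion"),
    ("pulmonary", "cardiac_lung"),
    ("pulmonary", "abnormal_valsalva"),
    ("pulmonary", "orthostatic_bp_abnormal"),
    ("pulmonary", "nitroglycerin_response_abnormal"),
    ("renal", "serum_creatinine"),
    ("renal", "bun"),
    ("renal", "cystatin_c"),
    ("hepatic", "total_bilirubin_elevated"),
    ("hepatic", "alt_elevated"),
    ("hepatic", "ast_elevated"),
    ("hepatic", "alp_elevated"),
    ("hepatic", "ggt_elevated"),
    ("hepatic", "albumin_decreased"),
    ("hepatic", "inr_abnormal"),
    ("hepatic", "ascites"),
    ("hepatic", "portal_flow_reduced"),
    ("hepatic", "ivc_noncollapsing"),
    ("neuro", "cerebral_hypoperfusion"),
    ("neuro", "depression"),
)


def _observed(value) -> bool:
    if value is None:
        return False
    if isinstance(value, Tristate):
        return value is not UNKNOWN
    if hasattr(value, "name") and value.name == "UNKNOWN":  # enum sentinels
        return False
    return True


def completeness(record: PatientRecord) -> float:
    """Fraction of staging-relevant clinical fields that are observed."""
    n_obs = sum(
        1
        for panel, name in _REQUIRED_FIELDS
        if _observed(getattr(getattr(record, panel), name))
    )
    return n_obs / len(_REQUIRED_FIELDS)


def format_code(h: HStage, l_stage: int, m_stage: int) -> str:
    return f"H{h.label}L{l_stage}M{m_stage}"


_CODE_RE = re.compile(r"^H([1-4])L([0-3])M([0-3])$", re.IGNORECASE)


class CodeParseError(ValueError):
    def __init__(self, code: str, position: int, message: str):
        self.code = code
        self.position = position
        super().__init__(f"invalid HLM code {code!r} at position {position}: {message}")


def parse_code(code: str) -> tuple[int, int, int]:
    """Parse an "H{1-4}L{0-3}M{0-3}" code, case-insensitively.

    Round-trips with :func:`format_code` for stageable results.  Malformed
    codes raise :class:`CodeParseError` pointing at the first offending
    position.
    """
    m = _CODE_RE.match(code)
    if m:
        return int(m.group(1)), int(m.group(2)), int(m.group(3))
    # locate the failure for the error message
    expected = [
        ("H", "letter 'H'"),
        ("[1-4]", "heart stage digit 1-4"),
        ("L", "letter 'L'"),
        ("[0-3]", "lung stage digit 0-3"),
        ("M", "letter 'M'"),
        ("[0-3]", "organ stage digit 0-3"),
    ]
    for i, (pat, what) in enumerate(expected):
        if i >= len(code) or not re.match(pat, code[i], re.IGNORECASE):
            raise CodeParseError(code, i, f"expected {what}")
    raise CodeParseError(code, 6, "unexpected trailing characters")


def _tri_entry(criterion: str, value: Tristate, note: str = "") -> ProvenanceEntry:
    return ProvenanceEntry(criterion, value.value, value is PRESENT, note)


def classify(record: PatientRecord, config: ReferenceConfig | None = None) -> StageResult:
    """Stage one patient: returns the H/L/M stages, code and provenance.

    Raises :class:`ValidationError` listing every violation when the record
    fails validation.
    """
    config = config or ReferenceConfig()
    violations = validate_record(record)
    if violations:
        raise ValidationError(violations)

    warnings: list[str] = []
    prov: list[ProvenanceEntry] = []

    # --- H ---
    findings = derive_cardiac_findings(record.cardiac, config)
    prov.append(_tri_entry("h.systolic_dysfunction", findings.systolic_dysfunction))
    prov.append(_tri_entry("h.diastolic_dysfunction", findings.diastolic_dysfunction))
    prov.append(_tri_entry("h.structural_damage", findings.structural_damage))
    prov.append(_tri_entry("h.remodeling", findings.remodeling))
    prov.append(
        _tri_entry(
            "h.severe_ef",
            findings.severe_ef,
            f"EF < {config.ef_severe_cutoff:g}% (strict)",
        )
    )
    prov.append(_tri_entry("h.biventricular", findings.biventricular))
    h = stage_h(findings)
    if h is HStage.NOT_STAGEABLE:
        warnings.append(
            "heart not stageable: no LV dysfunction evidence (the H ladder starts at H1)"
        )

    # --- L ---
    ph = classify_ph(record.hemodynamics, config)
    pf = derive_pulmonary_findings(record.pulmonary, ph, config)
    prov.append(
        ProvenanceEntry(
            "l.ph_type",
            ph.value,
            ph in (PHType.PRECAPILLARY, PHType.POSTCAPILLARY),
            f"PH iff mPAP > {config.mpap_rest_cutoff:g} mmHg at rest "
            f"(> {config.mpap_exercise_cutoff:g} on exercise); "
            f"PAWP <= {config.pawp_cutoff:g} -> precapillary",
        )
    )
    prov.append(_tri_entry("l.hemodynamic_congestion", pf.hemodynamic_congestion))
    prov.append(_tri_entry("l.clinical_congestion", pf.clinical_congestion))
    prov.append(_tri_entry("l.cardiac_lung", pf.cardiac_lung))
    l_stage = stage_l_from_findings(pf)
    if l_stage == 0:
        warnings.append("L0 (no pulmonary involvement) extends the published L1-L3 ladder")

    # --- M ---
    derived = derive_renal(record.renal, record.demographics, config)
    kidney = assess_kidney(derived, config)
    liver = assess_liver(record.hepatic, config)
    brain = assess_brain(record.neuro)
    statuses = [kidney, liver, brain]
    for s in statuses:
        prov.append(
            ProvenanceEntry(
                f"m.{s.organ.value}",
                s.malfunction.value,
                s.malfunction is PRESENT,
                "evidence: " + (", ".join(s.evidence) or "none")
                + ("; supportive: " + ", ".join(s.supportive) if s.supportive else ""),
            )
        )
    m_stage = stage_m(statuses)

    if kidney.malfunction is PRESENT and (
        findings.systolic_dysfunction is PRESENT
        or findings.diastolic_dysfunction is PRESENT
    ):
        warnings.append(
            "cardiac dysfunction with renal malfunction: consistent with a "
            "cardiorenal syndrome (descriptive annotation only)"
        )
    body_mass_index = compute_bmi(record.demographics.weight, record.demographics.height)
    if (
        config.cachexia_bmi_cutoff is not None
        and body_mass_index < config.cachexia_bmi_cutoff
    ):
        warnings.append(
            f"BMI {body_mass_index:.1f} kg/m² below the cachexia cutoff "
            f"({config.cachexia_bmi_cutoff:g}): severity marker of multi-organ failure"
        )

    comp = completeness(record)
    if comp == 0.0:
        warnings.append("no staging-relevant clinical fields observed")

    return StageResult(
        patient_id=record.patient_id,
        h_stage=h,
        l_stage=l_stage,
        m_stage=m_stage,
        malfunctioning_organs=malfunctioning_organs(statuses),
        code=format_code(h, l_stage, m_stage),
        provenance=tuple(prov),
        completeness=comp,
        warnings=tuple(warnings),
    )


def therapy_tier_note(result: StageResult) -> str:
    """Descriptive therapy-orientation note for reports (no recommendation logic).

    Initial-stage disease (H1L1M0) is conventionally managed with traditional
    therapy; organ malfunction alongside H2L2 motivates second-tier,
    organ-protective therapy; end-stage H4L3M3 shifts the goal to quality of
    life with palliative support.
    """
    if result.code == "H1L1M0":
        return "initial stage: traditional therapy orientation"
    if result.code == "H4L3M3":
        return "end stage: palliative/quality-of-life orientation"
    if result.h_stage is HStage.H2 and result.l_stage == 2 and result.m_stage >= 1:
        return "second-tier, organ-protective therapy orientation"
    return "intermediate stage: orientation per component stages"
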