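"""Pulmonary ("L") staging: hemodynamic classification and the L0–L3 ladder.

Hemodynamics first: pulmonary hypertension (PH) is a resting mean pulmonary
arterial pressure (mPAP) strictly above 25 mmHg — or, when only an exercise
measurement exists, above 30 mmHg.  Among PH patients the wedge pressure
(PAWP) splits the mechanism: ≤ 15 mmHg is precapillary, > 15 mmHg
postcapillary (left-sided congestion backing up into the lungs).

The ladder then grades involvement:

* L1 — hemodynamic congestion: elevated filling pressures (postcapillary PH,
  or bedside surrogates such as an abnormal Valsalva response) without
  clinical signs
* L2 — clinical congestion: cardiopulmonary/systemic signs and symptoms;
  pulmonary edema always classifies here at minimum
* L3 — cardiac lung: arterialization of the pulmonary vasculature

L0 (no pulmonary involvement) is an extension of the published ladder, which
starts at L1 and leaves the no-involvement case undefined; reports label it
as such.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    ABSENT,
    HemodynamicPanel,
    PHType,
    PRESENT,
    PulmonarySigns,
    ReferenceConfig,
    Tristate,
    UNKNOWN,
    tri_or,
)


@dataclass(frozen=True)
class PulmonaryFindings:
    ph_type: PHType
    hemodynamic_congestion: Tristate
    clinical_congestion: Tristate
    cardiac_lung: Tristate


def classify_ph(hemo: HemodynamicPanel, config: ReferenceConfig) -> PHType:
    """Classify pulmonary hypertension from right-heart pressures.

    Resting mPAP takes precedence; the exercise threshold is consulted only
    when no resting measurement exists.  PH with a missing wedge pressure has
    an unknown subtype.
    """
    if hemo.mpap_rest is not None:
        ph_present = hemo.mpap_rest > config.mpap_rest_cutoff
    elif hemo.mpap_exercise is not None:
        ph_present = hemo.mpap_exercise > config.mpap_exercise_cutoff
    else:
        return PHType.UNKNOWN
    if not ph_present:
        return PHType.NONE
    if hemo.pawp is None:
        return PHType.UNKNOWN
    if hemo.pawp <= config.pawp_cutoff:
        return PHType.PRECAPILLARY
    return PHType.POSTCAPILLARY


def derive_pulmonary_findings(
    signs: PulmonarySigns, ph: PHType, config: ReferenceConfig
) -> PulmonaryFindings:
    """Bundle hemodynamic- and clinical-congestion evidence for staging.

    Clinical congestion is the adjudicated sign flag, forced present by
    pulmonary edema, and (configurably) by pleural effusion.  Hemodynamic
    congestion is postcapillary PH — precapillary too under the default
    configuration, since both are graded pulmonary damage — or any
    elevated-filling-pressure bedside surrogate.
    """
    clinical_evidence = [signs.clinical_congestion_signs, signs.pulmonary_edema]
    if config.pleural_effusion_is_clinical:
        clinical_evidence.append(signs.pleural_effusion)
    clinical = tri_or(*clinical_evidence)

    if ph is PHType.POSTCAPILLARY or (
        ph is PHType.PRECAPILLARY and config.precapillary_counts_hemodynamic
    ):
        ph_tri = PRESENT
    elif ph is PHType.NONE or ph is PHType.PRECAPILLARY:
        ph_tri = ABSENT
    else:
        ph_tri = UNKNOWN
    hemodynamic = tri_or(
        ph_tri,
        signs.abnormal_valsalva,
        signs.orthostatic_bp_abnormal,
        signs.nitroglycerin_response_abnormal,
    )
    return PulmonaryFindings(
        ph_type=ph,
        hemodynamic_congestion=hemodynamic,
        clinical_congestion=clinical,
        cardiac_lung=signs.cardiac_lung,
    )


def stage_l(signs: PulmonarySigns, ph: PHType, config: ReferenceConfig) -> int:
    """Assign the lung stage 0–3; highest satisfied rule wins.

    Unknown evidence never satisfies a rule.
    """
    findings = derive_pulmonary_findings(signs, ph, config)
    return stage_l_from_findings(findings)


def stage_l_from_findings(findings: PulmonaryFindings) -> int:
    if findings.cardiac_lung is PRESENT:
        return 3
    if findings.clinical_congestion is PRESENT:
        return 2
    if findings.hemodynamic_congestion is PRESENT:
        return 1
    return 0
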