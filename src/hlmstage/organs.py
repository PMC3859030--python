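"""Malfunction-of-other-organs ("M") staging: kidney, liver, brain.

Each organ gets a tristate malfunction verdict with an evidence trail, then
the count of heart-failure-attributable malfunctioning organs maps to the
stage: 0 → M0, 1 → M1, 2 → M2, ≥ 3 → M3.

Detection is deliberately multi-parameter:

* kidney — a creatinine clearance below its sex-specific reference range, an
  estimated GFR below the malfunction cutoff, or elevated cystatin C.
  Creatinine alone is unreliable (muscle-mass confounding) and BUN is
  ambiguous (catabolism-driven), so neither triggers by itself; abnormal BUN
  is recorded as supportive evidence only.
* liver — single liver-function tests are aspecific, so at least two
  abnormal labs are required (bilirubin, ALT, AST, ALP, γ-GT, low albumin,
  abnormal INR — the INR is discarded as evidence in anticoagulated
  patients); any hemodynamic/structural sign (ascites, reduced portal flow,
  a non-collapsing inferior vena cava) suffices on its own.
* brain — cerebral hypoperfusion or depression.
"""

from __future__ import annotations

from dataclasses import dataclass

from .derived import DerivedRenal
from .model import (
    ABSENT,
    HepaticPanel,
    NeuroPanel,
    Organ,
    PRESENT,
    RangeFlag,
    ReferenceConfig,
    Tristate,
    UNKNOWN,
    tri_or,
)


@dataclass(frozen=True)
class OrganStatus:
    organ: Organ
    malfunction: Tristate
    evidence: tuple[str, ...] = ()  # criteria that fired
    supportive: tuple[str, ...] = ()  # abnormal but non-triggering findings
    attributable_to_hf: Tristate = UNKNOWN  # unknown attribution still counts

    def __post_init__(self) -> None:
        if self.malfunction is PRESENT and not self.evidence:
            raise ValueError(f"{self.organ.value}: malfunction without evidence")


def assess_kidney(derived: DerivedRenal, config: ReferenceConfig) -> OrganStatus:
    """Kidney verdict from the derived renal quantities.

    Unknown only when every renal input is missing; an abnormal serum
    creatinine with normal clearance does not trigger.
    """
    evidence: list[str] = []
    supportive: list[str] = []
    if derived.clcr_flag is RangeFlag.BELOW:
        evidence.append("creatinine_clearance_below_reference")
    if (
        derived.gfr_smdrd is not None
        and derived.gfr_smdrd < config.gfr_malfunction_cutoff
    ):
        evidence.append("smdrd_gfr_below_cutoff")
    if derived.cystatin_flag is RangeFlag.ABOVE:
        evidence.append("cystatin_c_elevated")
    if derived.bun_flag is RangeFlag.ABOVE:
        supportive.append("bun_elevated")
    if derived.scr_flag is not RangeFlag.WITHIN and derived.scr_flag is not RangeFlag.UNKNOWN:
        supportive.append("serum_creatinine_outside_reference")

    if evidence:
        malfunction = PRESENT
    elif (
        derived.clcr_flag is RangeFlag.UNKNOWN
        and derived.gfr_smdrd is None
        and derived.cystatin_flag is RangeFlag.UNKNOWN
    ):
        malfunction = UNKNOWN
    else:
        malfunction = ABSENT
    return OrganStatus(
        organ=Organ.KIDNEY,
        malfunction=malfunction,
        evidence=tuple(evidence),
        supportive=tuple(supportive),
    )


_LIVER_LABS = (
    ("total_bilirubin_elevated", "bilirubin_elevated"),
    ("alt_elevated", "alt_elevated"),
    ("ast_elevated", "ast_elevated"),
    ("alp_elevated", "alp_elevated"),
    ("ggt_elevated", "ggt_elevated"),
    ("albumin_decreased", "albumin_decreased"),
    ("inr_abnormal", "inr_abnormal"),
)
_LIVER_HEMO = (
    ("ascites", "ascites"),
    ("portal_flow_reduced", "portal_flow_reduced"),
    ("ivc_noncollapsing", "ivc_noncollapsing"),
)


def assess_liver(hepatic: HepaticPanel, config: ReferenceConfig) -> OrganStatus:
    """Liver verdict: lab-count rule OR any hemodynamic/structural sign.

    Unknown flags count as absent in the lab tally; the overall verdict is
    unknown only when every flag is unknown.
    """
    lab_hits: list[str] = []
    for attr, label in _LIVER_LABS:
        if attr == "inr_abnormal" and hepatic.on_anticoagulants:
            continue  # INR under anticoagulation is not liver evidence
        if getattr(hepatic, attr) is PRESENT:
            lab_hits.append(label)
    hemo_hits = [label for attr, label in _LIVER_HEMO if getattr(hepatic, attr) is PRESENT]

    evidence: list[str] = list(hemo_hits)
    supportive: list[str] = []
    if len(lab_hits) >= config.liver_min_abnormal_labs:
        evidence.extend(lab_hits)
    else:
        supportive.extend(lab_hits)

    considered = [getattr(hepatic, attr) for attr, _ in _LIVER_LABS + _LIVER_HEMO]
    if evidence:
        malfunction = PRESENT
    elif all(v is UNKNOWN for v in considered):
        malfunction = UNKNOWN
    else:
        malfunction = ABSENT
    return OrganStatus(
        organ=Organ.LIVER,
        malfunction=malfunction,
        evidence=tuple(evidence),
        supportive=tuple(supportive),
    )


def assess_brain(neuro: NeuroPanel) -> OrganStatus:
    """Brain verdict: cerebral hypoperfusion or depression."""
    verdict = tri_or(neuro.cerebral_hypoperfusion, neuro.depression)
    evidence = []
    if neuro.cerebral_hypoperfusion is PRESENT:
        evidence.append("cerebral_hypoperfusion")
    if neuro.depression is PRESENT:
        evidence.append("depression")
    return OrganStatus(organ=Organ.BRAIN, malfunction=verdict, evidence=tuple(evidence))


def stage_m(statuses: list[OrganStatus]) -> int:
    """Map the malfunctioning-organ count to M0–M3.

    An organ counts when malfunction is present and attribution to heart
    failure is not positively ruled out (unknown attribution counts —
    excluding it would systematically understage).  The mapping implements
    "count ≥ 3 → M3" so extending the organ set needs no logic change.
    """
    seen: set[Organ] = set()
    for s in statuses:
        if s.organ in seen:
            raise ValueError(f"duplicate organ entry: {s.organ.value}")
        seen.add(s.organ)
    count = sum(
        1
        for s in statuses
        if s.malfunction is PRESENT and s.attributable_to_hf is not ABSENT
    )
    return min(count, 3)


def malfunctioning_organs(statuses: list[OrganStatus]) -> frozenset[Organ]:
    return frozenset(
        s.organ
        for s in statuses
        if s.malfunction is PRESENT and s.attributable_to_hf is not ABSENT
    )
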