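"""Cardiac ("H") staging: map echocardiographic findings to H1–H4.

The ladder grades left-ventricular damage from isolated functional impairment
to biventricular failure:

* H1 — impaired systolic or diastolic LV function without structural damage
* H2 — systolic or diastolic dysfunction plus structural damage
  (hypertrophy or previous myocardial infarction)
* H3 — combined systolic and diastolic dysfunction (or severe EF < 35 %)
  with left-ventricular remodeling
* H4 — biventricular systolic and diastolic dysfunction

Rules are evaluated highest-first; an unknown criterion never satisfies a
rule, so incomplete data can only understage, never overstage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    ABSENT,
    CardiacPanel,
    HStage,
    PRESENT,
    PreviousMI,
    ReferenceConfig,
    Tristate,
    UNKNOWN,
    tri_and,
    tri_or,
)
from .derived import derive_lv_flags
from .model import RangeFlag


@dataclass(frozen=True)
class CardiacFindings:
    """Boolean criterion bundle the H rules consume, all tristate."""

    systolic_dysfunction: Tristate
    diastolic_dysfunction: Tristate
    structural_damage: Tristate  # hypertrophy OR previous MI
    remodeling: Tristate
    severe_ef: Tristate  # EF strictly below the severe cutoff
    biventricular: Tristate  # RV dysfunction AND any LV dysfunction


def derive_cardiac_findings(
    cardiac: CardiacPanel, config: ReferenceConfig
) -> CardiacFindings:
    """Derive the six H criteria from the cardiac panel.

    * structural damage: hypertrophy present OR previous MI (NSTEMI/STEMI)
    * severe EF: ejection fraction strictly below ``ef_severe_cutoff``
    * systolic dysfunction: the adjudicated flag; when the flag is unknown
      and an EF is available, optionally auto-derived as EF below
      ``ef_systolic_cutoff`` (50 % default, an extra-source convention)
    * remodeling: the adjudicated flag, or inferred present when either LV
      diameter exceeds its reference upper bound
    * biventricular: RV dysfunction AND (systolic or diastolic LV dysfunction)

    Unknown inputs propagate to unknown findings.
    """
    mi = cardiac.previous_mi
    mi_tri = (
        PRESENT
        if mi in (PreviousMI.NSTEMI, PreviousMI.STEMI)
        else ABSENT
        if mi is PreviousMI.NONE
        else UNKNOWN
    )
    structural = tri_or(cardiac.lv_hypertrophy, mi_tri)

    ef = cardiac.ejection_fraction
    if ef is None:
        severe_ef = UNKNOWN
    else:
        severe_ef = PRESENT if ef < config.ef_severe_cutoff else ABSENT

    systolic = cardiac.systolic_dysfunction
    if systolic is UNKNOWN and ef is not None and config.auto_systolic_from_ef:
        systolic = PRESENT if ef < config.ef_systolic_cutoff else ABSENT

    remodeling = cardiac.lv_remodeling
    if remodeling is not PRESENT:
        flags = derive_lv_flags(cardiac, config)
        if RangeFlag.ABOVE in (flags.lvdd_flag, flags.lvsd_flag):
            remodeling = PRESENT

    biventricular = tri_and(
        cardiac.rv_dysfunction, tri_or(systolic, cardiac.diastolic_dysfunction)
    )
    return CardiacFindings(
        systolic_dysfunction=systolic,
        diastolic_dysfunction=cardiac.diastolic_dysfunction,
        structural_damage=structural,
        remodeling=remodeling,
        severe_ef=severe_ef,
        biventricular=biventricular,
    )


def stage_h(findings: CardiacFindings) -> HStage:
    """Assign the cardiac stage; highest satisfied rule wins (H4 → H1).

    Severe EF counts as LV-dysfunction evidence for H1/H2, so an isolated
    EF < 35 % never falls through to "not stageable"; in H3 it may replace
    the systolic-plus-diastolic pair but remodeling remains mandatory.
    When no dysfunction evidence at all is present the heart is not
    stageable (the ladder starts at H1; there is no H0).
    """
    f = findings
    dysfunction = tri_or(f.systolic_dysfunction, f.diastolic_dysfunction, f.severe_ef)
    if f.biventricular is PRESENT:
        return HStage.H4
    if f.remodeling is PRESENT and (
        tri_and(f.systolic_dysfunction, f.diastolic_dysfunction) is PRESENT
        or f.severe_ef is PRESENT
    ):
        return HStage.H3
    if dysfunction is PRESENT and f.structural_damage is PRESENT:
        return HStage.H2
    if dysfunction is PRESENT:
        # structural damage absent or unknown: unknowns never upstage
        return HStage.H1
    return HStage.NOT_STAGEABLE
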