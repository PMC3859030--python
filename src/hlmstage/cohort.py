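"""Stage-conditional synthetic cohorts for exercising the staging engines.

No clinical dataset accompanies the staging proposal, so test cohorts are
generated: for a target (h, l, m) triple the generator samples physiology
that provably satisfies exactly the rules of that stage — values are drawn
*threshold-adjacent* (just inside or outside the configured cutoffs) rather
than population-realistic, which keeps boundary behaviour sharply exercised.

At zero missingness ``classify(generate_patient(t)) == t`` for every target
on the 4 × 4 × 4 grid (asserted at generation time).  Raising missingness
degrades records toward unknown, which can only lower stages — never raise
them — because unknown evidence never satisfies a rule.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .derived import (
    COCKCROFT_GAULT_FEMALE_FACTOR,
    SMDRD_AGE_EXPONENT,
    SMDRD_CONSTANT,
    SMDRD_FEMALE_FACTOR,
    SMDRD_SCR_EXPONENT,
    smdrd_gfr,
)
from .model import (
    ABSENT,
    CardiacPanel,
    Demographics,
    HemodynamicPanel,
    HemoSource,
    HepaticPanel,
    HStage,
    NeuroPanel,
    Organ,
    PatientRecord,
    PreviousMI,
    PRESENT,
    PulmonarySigns,
    ReferenceConfig,
    RenalPanel,
    Sex,
    Tristate,
    UNKNOWN,
)

Target = tuple[int, int, int]  # (h, l, m)

ALL_TARGETS: tuple[Target, ...] = tuple(
    (h, l, m) for h in (1, 2, 3, 4) for l in (0, 1, 2, 3) for m in (0, 1, 2, 3)
)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``stage_mix`` maps target (h, l, m) triples to weights (normalised
    internally); ``missingness`` is the per-field probability that a clinical
    input is dropped (numeric fields to missing, flags to unknown).
    """

    n: int
    stage_mix: dict[Target, float] = field(
        default_factory=lambda: {t: 1.0 for t in ALL_TARGETS}
    )
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"cohort size must be positive, got {self.n}")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        total = sum(self.stage_mix.values())
        if not total > 0:
            raise ValueError("stage_mix weights must sum to a positive value")
        for t in self.stage_mix:
            if t not in ALL_TARGETS:
                raise ValueError(f"unreachable target {t}")


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def _demographics(rng: np.random.Generator) -> Demographics:
    return Demographics(
        age=int(rng.integers(45, 81)),
        sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
        black_ethnicity=bool(rng.random() < 0.15),
        weight=round(_uniform(rng, 55.0, 95.0), 1),
        height=round(_uniform(rng, 1.55, 1.90), 2),
    )


def _cardiac(rng: np.random.Generator, h: int, config: ReferenceConfig) -> CardiacPanel:
    lvdd_n = config.lvdd_normal
    lvsd_n = config.lvsd_normal
    normal_dd = round(_uniform(rng, lvdd_n.lower, lvdd_n.upper), 1)
    normal_sd = round(_uniform(rng, lvsd_n.lower, lvsd_n.upper), 1)
    dilated_dd = round(_uniform(rng, lvdd_n.upper + 2.0, lvdd_n.upper + 15.0), 1)
    dilated_sd = round(_uniform(rng, lvsd_n.upper + 2.0, lvsd_n.upper + 15.0), 1)
    structural_mi = rng.random() < 0.5
    mi_kind = PreviousMI.STEMI if rng.random() < 0.5 else PreviousMI.NSTEMI

    if h == 1:
        # isolated diastolic (or systolic) impairment, structurally normal LV
        systolic_first = rng.random() < 0.3
        return CardiacPanel(
            ejection_fraction=round(_uniform(rng, 40.0, 49.0), 1)
            if systolic_first
            else round(_uniform(rng, 52.0, 65.0), 1),
            systolic_dysfunction=PRESENT if systolic_first else ABSENT,
            diastolic_dysfunction=ABSENT if systolic_first else PRESENT,
            lv_hypertrophy=ABSENT,
            previous_mi=PreviousMI.NONE,
            lv_end_diastolic_diameter=normal_dd,
            lv_end_systolic_diameter=normal_sd,
            lv_remodeling=ABSENT,
            rv_dysfunction=ABSENT,
        )
    if h == 2:
        return CardiacPanel(
            ejection_fraction=round(_uniform(rng, 36.0, 48.0), 1),
            systolic_dysfunction=PRESENT,
            diastolic_dysfunction=ABSENT,
            lv_hypertrophy=ABSENT if structural_mi else PRESENT,
            previous_mi=mi_kind if structural_mi else PreviousMI.NONE,
            lv_end_diastolic_diameter=normal_dd,
            lv_end_systolic_diameter=normal_sd,
            lv_remodeling=ABSENT,
            rv_dysfunction=ABSENT,
        )
    # H3/H4: combined dysfunction, severe EF, remodeled (dilated) ventricle
    return CardiacPanel(
        ejection_fraction=round(_uniform(rng, 18.0, 34.0), 1),
        systolic_dysfunction=PRESENT,
        diastolic_dysfunction=PRESENT,
        lv_hypertrophy=PRESENT if rng.random() < 0.5 else ABSENT,
        previous_mi=mi_kind if structural_mi else PreviousMI.NONE,
        lv_end_diastolic_diameter=dilated_dd,
        lv_end_systolic_diameter=dilated_sd,
        lv_remodeling=PRESENT,
        rv_dysfunction=PRESENT if h == 4 else ABSENT,
    )


def _hemodynamics(
    rng: np.random.Generator, l: int, config: ReferenceConfig
) -> HemodynamicPanel:
    if l == 0:
        return HemodynamicPanel(
            mpap_rest=round(_uniform(rng, 12.0, config.mpap_rest_cutoff - 1.0), 1),
            pawp=round(_uniform(rng, 4.0, config.pawp_cutoff - 3.0), 1),
            source=HemoSource.CATHETERIZATION,
        )
    # postcapillary PH: mPAP just above the resting cutoff, wedge above 15
    return HemodynamicPanel(
        mpap_rest=round(_uniform(rng, config.mpap_rest_cutoff + 1.0,
                                 config.mpap_rest_cutoff + 20.0), 1),
        pawp=round(_uniform(rng, config.pawp_cutoff + 0.5, config.pawp_cutoff + 10.0), 1),
        source=HemoSource.CATHETERIZATION,
    )


def _pulmonary(rng: np.random.Generator, l: int) -> PulmonarySigns:
    base = PulmonarySigns(
        clinical_congestion_signs=ABSENT,
        pulmonary_edema=ABSENT,
        pleural_effusion=ABSENT,
        cardiac_lung=ABSENT,
        abnormal_valsalva=ABSENT,
        orthostatic_bp_abnormal=ABSENT,
        nitroglycerin_response_abnormal=ABSENT,
    )
    if l <= 1:
        if l == 1 and rng.random() < 0.3:
            # bedside surrogate of high filling pressures (still L1)
            return dataclasses.replace(base, abnormal_valsalva=PRESENT)
        return base
    edema = rng.random() < 0.6
    congested = dataclasses.replace(
        base,
        clinical_congestion_signs=PRESENT,
        pulmonary_edema=PRESENT if edema else ABSENT,
        pleural_effusion=PRESENT if rng.random() < 0.5 else ABSENT,
    )
    if l == 3:
        congested = dataclasses.replace(congested, cardiac_lung=PRESENT)
    return congested


def _scr_for_clcr(target_clcr: float, demo: Demographics) -> float:
    """Serum creatinine that makes the Cockcroft-Gault estimate hit target_clcr."""
    factor = COCKCROFT_GAULT_FEMALE_FACTOR if demo.sex is Sex.FEMALE else 1.0
    return factor * (140.0 - demo.age) * demo.weight / (72.0 * target_clcr)


def _scr_gfr_floor(demo: Demographics, gfr_target: float) -> float:
    """Largest serum creatinine keeping the simplified-MDRD GFR above gfr_target."""
    scale = SMDRD_CONSTANT * demo.age**SMDRD_AGE_EXPONENT
    if demo.sex is Sex.FEMALE:
        scale *= SMDRD_FEMALE_FACTOR
    if demo.black_ethnicity:
        scale *= 1.21
    return (gfr_target / scale) ** (1.0 / SMDRD_SCR_EXPONENT)


def _renal(
    rng: np.random.Generator,
    demo: Demographics,
    malfunction: bool,
    config: ReferenceConfig,
) -> RenalPanel:
    ref = config.clcr_normal(demo.sex)
    if malfunction:
        target = _uniform(rng, 25.0, ref.lower - 15.0)
        scr = _scr_for_clcr(target, demo)
        return RenalPanel(
            serum_creatinine=round(scr, 2),
            bun=round(_uniform(rng, 25.0, 45.0), 1),
            cystatin_c=round(_uniform(rng, config.cystatin_upper + 0.2,
                                      config.cystatin_upper + 1.5), 2),
        )
    target = _uniform(rng, ref.lower + 10.0, ref.upper - 10.0)
    # keep the MDRD estimate clear of the malfunction cutoff as well
    scr = min(
        _scr_for_clcr(target, demo),
        _scr_gfr_floor(demo, config.gfr_malfunction_cutoff + 5.0),
    )
    scr = round(scr, 2)
    assert smdrd_gfr(scr, demo.age, demo.sex, demo.black_ethnicity) \
        >= config.gfr_malfunction_cutoff
    return RenalPanel(
        serum_creatinine=scr,
        bun=round(_uniform(rng, 8.0, 18.0), 1),
        cystatin_c=round(_uniform(rng, 0.60, config.cystatin_upper - 0.05), 2),
    )


def _hepatic(rng: np.random.Generator, malfunction: bool) -> HepaticPanel:
    if not malfunction:
        return HepaticPanel(
            total_bilirubin_elevated=ABSENT,
            alt_elevated=ABSENT,
            ast_elevated=ABSENT,
            alp_elevated=ABSENT,
            ggt_elevated=ABSENT,
            albumin_decreased=ABSENT,
            inr_abnormal=ABSENT,
            on_anticoagulants=bool(rng.random() < 1.0 / 3.0),
            ascites=ABSENT,
            portal_flow_reduced=ABSENT,
            ivc_noncollapsing=ABSENT,
        )
    # congestive hepatopathy: >= 2 abnormal labs, often with venous signs
    return HepaticPanel(
        total_bilirubin_elevated=PRESENT,
        alt_elevated=PRESENT if rng.random() < 0.4 else ABSENT,
        ast_elevated=PRESENT if rng.random() < 0.4 else ABSENT,
        alp_elevated=PRESENT if rng.random() < 0.3 else ABSENT,
        ggt_elevated=PRESENT if rng.random() < 0.5 else ABSENT,
        albumin_decreased=PRESENT,
        inr_abnormal=ABSENT,
        on_anticoagulants=bool(rng.random() < 1.0 / 3.0),
        ascites=PRESENT if rng.random() < 0.5 else ABSENT,
        portal_flow_reduced=PRESENT if rng.random() < 0.4 else ABSENT,
        ivc_noncollapsing=PRESENT if rng.random() < 0.4 else ABSENT,
    )


def _neuro(rng: np.random.Generator, malfunction: bool) -> NeuroPanel:
    if not malfunction:
        return NeuroPanel(cerebral_hypoperfusion=ABSENT, depression=ABSENT)
    hypo = rng.random() < 0.5
    return NeuroPanel(
        cerebral_hypoperfusion=PRESENT if hypo else ABSENT,
        depression=PRESENT if (not hypo or rng.random() < 0.5) else ABSENT,
    )


# numeric record fields eligible for dropping, and the tristate flag fields
_DROPPABLE_NUMERIC = {
    "cardiac": ("ejection_fraction", "lv_end_diastolic_diameter",
                "lv_end_systolic_diameter"),
    "hemodynamics": ("mpap_rest", "mpap_exercise", "pawp"),
    "renal": ("serum_creatinine", "bun", "cystatin_c", "measured_clcr"),
}


def _apply_missingness(
    record: PatientRecord, rng: np.random.Generator, p: float
) -> PatientRecord:
    if p <= 0:
        return record
    new_panels = {}
    for panel_name in ("cardiac", "hemodynamics", "pulmonary", "renal",
                       "hepatic", "neuro"):
        panel = getattr(record, panel_name)
        updates = {}
        for f in dataclasses.fields(panel):
            v = getattr(panel, f.name)
            if rng.random() >= p:
                continue
            if isinstance(v, Tristate):
                updates[f.name] = UNKNOWN
            elif f.name == "previous_mi":
                updates[f.name] = PreviousMI.UNKNOWN
            elif f.name in _DROPPABLE_NUMERIC.get(panel_name, ()):
                updates[f.name] = None
        if updates:
            panel = dataclasses.replace(panel, **updates)
        new_panels[panel_name] = panel
    return dataclasses.replace(record, **new_panels)


def generate_patient(
    target: Target,
    seed: int = 0,
    *,
    missingness: float = 0.0,
    config: Optional[ReferenceConfig] = None,
    patient_id: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> PatientRecord:
    """Generate one record that the classifier maps to ``target``.

    At ``missingness=0`` the round-trip is asserted internally; with
    missingness the record degrades toward unknown.  Identical (target,
    seed) pairs yield identical records.
    """
    h, l, m = target
    if h not in (1, 2, 3, 4) or l not in (0, 1, 2, 3) or m not in (0, 1, 2, 3):
        raise ValueError(f"target out of range: {target}")
    if rng is None:
        rng = np.random.default_rng([seed, h, l, m])
    config = config or ReferenceConfig()

    demo = _demographics(rng)
    organs = list(rng.permutation([o.value for o in Organ]))[:m]
    record = PatientRecord(
        patient_id=patient_id or f"T{h}{l}{m}S{seed}",
        demographics=demo,
        cardiac=_cardiac(rng, h, config),
        hemodynamics=_hemodynamics(rng, l, config),
        pulmonary=_pulmonary(rng, l),
        renal=_renal(rng, demo, Organ.KIDNEY.value in organs, config),
        hepatic=_hepatic(rng, Organ.LIVER.value in organs),
        neuro=_neuro(rng, Organ.BRAIN.value in organs),
    )
    if missingness == 0.0:
        from .classify import classify

        result = classify(record, config)
        got = (
            result.h_stage.value if result.h_stage is not HStage.NOT_STAGEABLE else 0,
            result.l_stage,
            result.m_stage,
        )
        assert got == target, f"generator inconsistency: built {got}, wanted {target}"
    else:
        record = _apply_missingness(record, rng, missingness)
    return record


def _stratified_counts(weights: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n among the weights."""
    total = sum(weights)
    quotas = [w / total * n for w in weights]
    counts = [math.floor(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(
    spec: CohortSpec, config: Optional[ReferenceConfig] = None
) -> list[PatientRecord]:
    """Generate a cohort with stage frequencies matching the mix exactly.

    Assignment is stratified (largest-remainder), not sampled, so at zero
    missingness the empirical code frequencies equal the requested mix up to
    integer rounding.  Per-patient randomness comes from substreams derived
    from (seed, index), so cohorts are reproducible and order-stable.
    """
    targets = sorted(spec.stage_mix)
    counts = _stratified_counts([spec.stage_mix[t] for t in targets], spec.n)
    records: list[PatientRecord] = []
    index = 0
    for target, count in zip(targets, counts):
        for _ in range(count):
            rng = np.random.default_rng([spec.seed, index])
            records.append(
                generate_patient(
                    target,
                    spec.seed,
                    missingness=spec.missingness,
                    config=config,
                    patient_id=f"P{index:05d}",
                    rng=rng,
                )
            )
            index += 1
    return records
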