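"""Domain types, units, and missing-data semantics for the HLM staging engine.

The staging engine works on a structured per-patient record.  Every clinical
flag is a *tristate* (:class:`Tristate`): ``PRESENT``, ``ABSENT`` or
``UNKNOWN``.  "Unknown" is a first-class value, distinct from a field that is
simply absent from an input file: rules are conservative, so an unknown
criterion never satisfies a stage rule, and unknowns are surfaced in the
completeness report instead of being imputed.

Units are fixed throughout: serum creatinine in mg/dL, pressures in mmHg,
weight in kg, height in m, ventricular diameters in mm.  A conversion helper
for creatinine reported in µmol/L lives at the I/O layer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional


class Tristate(enum.Enum):
    """Three-valued clinical flag: present / absent / unknown."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError(
            "Tristate is not a boolean; compare against Tristate members explicitly"
        )


PRESENT = Tristate.PRESENT
ABSENT = Tristate.ABSENT
UNKNOWN = Tristate.UNKNOWN


def tri_or(*values: Tristate) -> Tristate:
    """Kleene OR: present if any present, absent if all absent, else unknown."""
    if any(v is PRESENT for v in values):
        return PRESENT
    if all(v is ABSENT for v in values):
        return ABSENT
    return UNKNOWN


def tri_and(*values: Tristate) -> Tristate:
    """Kleene AND: absent if any absent, present if all present, else unknown."""
    if any(v is ABSENT for v in values):
        return ABSENT
    if all(v is PRESENT for v in values):
        return PRESENT
    return UNKNOWN


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


class PreviousMI(enum.Enum):
    """History of myocardial infarction (structural-damage evidence)."""

    NONE = "none"
    NSTEMI = "nstemi"
    STEMI = "stemi"
    UNKNOWN = "unknown"


class HemoSource(enum.Enum):
    CATHETERIZATION = "catheterization"
    ECHO_ESTIMATE = "echo_estimate"
    UNKNOWN = "unknown"


class PHType(enum.Enum):
    """Pulmonary-hypertension classification from right-heart hemodynamics."""

    NONE = "none"
    PRECAPILLARY = "precapillary"
    POSTCAPILLARY = "postcapillary"
    UNKNOWN = "unknown"


class Organ(enum.Enum):
    KIDNEY = "kidney"
    LIVER = "liver"
    BRAIN = "brain"


class RangeFlag(enum.Enum):
    """Position of a measurement relative to its reference interval.

    A four-valued refinement of the plain tristate: stage rules that care
    only about "abnormal" collapse BELOW/ABOVE, but the kidney rules need the
    direction (a creatinine clearance below its reference range is renal
    malfunction; one above it is not).
    """

    WITHIN = "within"
    BELOW = "below"
    ABOVE = "above"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Demographics:
    """Age (years), sex, ethnicity and body size used by the renal formulas."""

    age: int
    sex: Sex
    black_ethnicity: bool
    weight: float  # kg
    height: float  # m


@dataclass(frozen=True)
class CardiacPanel:
    ejection_fraction: Optional[float] = None  # % of LV end-diastolic volume
    systolic_dysfunction: Tristate = UNKNOWN
    diastolic_dysfunction: Tristate = UNKNOWN  # transmitral-flow adjudicated
    lv_hypertrophy: Tristate = UNKNOWN
    previous_mi: PreviousMI = PreviousMI.UNKNOWN
    lv_end_diastolic_diameter: Optional[float] = None  # mm
    lv_end_systolic_diameter: Optional[float] = None  # mm
    lv_remodeling: Tristate = UNKNOWN
    rv_dysfunction: Tristate = UNKNOWN


@dataclass(frozen=True)
class HemodynamicPanel:
    mpap_rest: Optional[float] = None  # mmHg
    mpap_exercise: Optional[float] = None  # mmHg
    pawp: Optional[float] = None  # mmHg
    source: HemoSource = HemoSource.UNKNOWN


@dataclass(frozen=True)
class PulmonarySigns:
    clinical_congestion_signs: Tristate = UNKNOWN
    pulmonary_edema: Tristate = UNKNOWN
    pleural_effusion: Tristate = UNKNOWN
    cardiac_lung: Tristate = UNKNOWN  # vascular arterialization, adjudicated
    abnormal_valsalva: Tristate = UNKNOWN
    orthostatic_bp_abnormal: Tristate = UNKNOWN
    nitroglycerin_response_abnormal: Tristate = UNKNOWN


@dataclass(frozen=True)
class RenalPanel:
    serum_creatinine: Optional[float] = None  # mg/dL
    bun: Optional[float] = None  # mg/dL
    cystatin_c: Optional[float] = None  # mg/L
    measured_clcr: Optional[float] = None  # mL/min


@dataclass(frozen=True)
class HepaticPanel:
    total_bilirubin_elevated: Tristate = UNKNOWN
    alt_elevated: Tristate = UNKNOWN
    ast_elevated: Tristate = UNKNOWN
    alp_elevated: Tristate = UNKNOWN
    ggt_elevated: Tristate = UNKNOWN
    albumin_decreased: Tristate = UNKNOWN
    inr_abnormal: Tristate = UNKNOWN
    on_anticoagulants: bool = False
    ascites: Tristate = UNKNOWN
    portal_flow_reduced: Tristate = UNKNOWN
    ivc_noncollapsing: Tristate = UNKNOWN


@dataclass(frozen=True)
class NeuroPanel:
    cerebral_hypoperfusion: Tristate = UNKNOWN
    depression: Tristate = UNKNOWN


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    demographics: Demographics
    cardiac: CardiacPanel = field(default_factory=CardiacPanel)
    hemodynamics: HemodynamicPanel = field(default_factory=HemodynamicPanel)
    pulmonary: PulmonarySigns = field(default_factory=PulmonarySigns)
    renal: RenalPanel = field(default_factory=RenalPanel)
    hepatic: HepaticPanel = field(default_factory=HepaticPanel)
    neuro: NeuroPanel = field(default_factory=NeuroPanel)


@dataclass(frozen=True)
class Interval:
    """Closed reference interval [lower, upper]; boundary values are within."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError(f"interval lower {self.lower} > upper {self.upper}")

    def flag(self, value: Optional[float]) -> RangeFlag:
        if value is None:
            return RangeFlag.UNKNOWN
        if value < self.lower:
            return RangeFlag.BELOW
        if value > self.upper:
            return RangeFlag.ABOVE
        return RangeFlag.WITHIN

    @staticmethod
    def from_mean_tol(mean: float, tol: float) -> "Interval":
        return Interval(mean - tol, mean + tol)


@dataclass(frozen=True)
class ReferenceConfig:
    """Every numeric threshold and reference interval the stage rules use.

    Defaults reproduce the published cutoffs of the staging proposal:
    pulmonary hypertension above 25 mmHg resting mPAP (30 mmHg on exercise),
    pre/postcapillary split at a wedge pressure of 15 mmHg, severe ejection
    fraction below 35 %, serum creatinine reference 0.7–1.3 mg/dL, creatinine
    clearance 57–115 mL/min (women) / 95–145 mL/min (men), LV end-diastolic
    diameter 50 ± 5 mm and end-systolic 31 ± 5 mm, liver malfunction
    requiring at least two abnormal laboratory tests.

    BUN and cystatin-C upper limits, the GFR malfunction cutoff and the
    "impaired systolic function" EF cutoff (50 %) have no value printed in the
    proposal; their defaults follow common laboratory practice and are marked
    extra-source in rule provenance.
    """

    mpap_rest_cutoff: float = 25.0  # mmHg; PH iff strictly above
    mpap_exercise_cutoff: float = 30.0  # mmHg
    pawp_cutoff: float = 15.0  # mmHg; <= cutoff -> precapillary
    ef_severe_cutoff: float = 35.0  # %; strictly below -> severe
    ef_systolic_cutoff: float = 50.0  # %; extra-source auto-derive default
    auto_systolic_from_ef: bool = True
    scr_normal: Interval = field(default_factory=lambda: Interval(0.7, 1.3))
    clcr_normal_female: Interval = field(default_factory=lambda: Interval(57.0, 115.0))
    clcr_normal_male: Interval = field(default_factory=lambda: Interval(95.0, 145.0))
    lvdd_normal: Interval = field(default_factory=lambda: Interval.from_mean_tol(50.0, 5.0))
    lvsd_normal: Interval = field(default_factory=lambda: Interval.from_mean_tol(31.0, 5.0))
    bun_upper: float = 20.0  # mg/dL, extra-source; supportive evidence only
    cystatin_upper: float = 1.0  # mg/L, extra-source
    gfr_malfunction_cutoff: float = 60.0  # mL/min/1.73m²
    liver_min_abnormal_labs: int = 2
    pleural_effusion_is_clinical: bool = True  # effusion counts as L2 evidence
    precapillary_counts_hemodynamic: bool = True  # precapillary PH -> L1
    count_cachexia_as_organ: bool = False
    cachexia_bmi_cutoff: Optional[float] = None  # kg/m²; user-supplied if counted

    def __post_init__(self) -> None:
        for name in (
            "mpap_rest_cutoff",
            "mpap_exercise_cutoff",
            "pawp_cutoff",
            "ef_severe_cutoff",
            "ef_systolic_cutoff",
            "bun_upper",
            "cystatin_upper",
            "gfr_malfunction_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.liver_min_abnormal_labs < 1:
            raise ValueError("liver_min_abnormal_labs must be >= 1")
        if self.count_cachexia_as_organ and self.cachexia_bmi_cutoff is None:
            raise ValueError(
                "cachexia_bmi_cutoff is required when count_cachexia_as_organ is set"
            )

    def clcr_normal(self, sex: Sex) -> Interval:
        return self.clcr_normal_female if sex is Sex.FEMALE else self.clcr_normal_male


class HStage(enum.Enum):
    """Cardiac stage: H1–H4, or not stageable when no dysfunction evidence."""

    H1 = 1
    H2 = 2
    H3 = 3
    H4 = 4
    NOT_STAGEABLE = "not_stageable"

    @property
    def label(self) -> str:
        return "?" if self is HStage.NOT_STAGEABLE else str(self.value)


@dataclass(frozen=True)
class ProvenanceEntry:
    """One evaluated criterion: its identifier, observed value, and whether it fired."""

    criterion: str
    value: str
    fired: bool
    note: str = ""


@dataclass(frozen=True)
class Violation:
    """A single validation failure: dotted field path plus human-readable reason."""

    path: str
    reason: str

    def __str__(self) -> str:
        return f"{self.path}: {self.reason}"


@dataclass(frozen=True)
class StageResult:
    patient_id: str
    h_stage: HStage
    l_stage: int  # 0–3
    m_stage: int  # 0–3
    malfunctioning_organs: frozenset[Organ]
    code: str  # e.g. "H2L1M0"; "H?..." when the heart is not stageable
    provenance: tuple[ProvenanceEntry, ...]
    completeness: float  # observed required fields / total required fields
    warnings: tuple[str, ...] = ()


class ValidationError(ValueError):
    """Raised when a record with violations is handed to the classifier."""

    def __init__(self, violations: Iterable[Violation]):
        self.violations = list(violations)
        super().__init__(
            "invalid patient record: " + "; ".join(str(v) for v in self.violations)
        )


def _check_positive(value: Optional[float], path: str, out: list[Violation]) -> None:
    if value is not None and not value > 0:
        out.append(Violation(path, f"must be strictly positive, got {value}"))


def _check_pressure(value: Optional[float], path: str, out: list[Violation]) -> None:
    if value is None:
        return
    if not (0.0 <= value <= 120.0):
        out.append(Violation(path, f"pressure must be in [0, 120] mmHg, got {value}"))


def validate_record(record: PatientRecord) -> list[Violation]:
    """Check every present field against its type invariant.

    Returns an empty list iff the record is valid; violations are data, not
    exceptions, so callers can collect them across a cohort.  The record is
    never mutated.
    """
    out: list[Violation] = []
    d = record.demographics
    if not record.patient_id:
        out.append(Violation("patient_id", "must be a non-empty string"))
    if d.age < 18:
        out.append(Violation("demographics.age", f"must be >= 18 years, got {d.age}"))
    if d.age >= 140:
        out.append(Violation("demographics.age", f"must be < 140 years, got {d.age}"))
    _check_positive(d.weight, "demographics.weight", out)
    _check_positive(d.height, "demographics.height", out)

    c = record.cardiac
    if c.ejection_fraction is not None and not (0.0 <= c.ejection_fraction <= 100.0):
        out.append(
            Violation(
                "cardiac.ejection_fraction",
                f"must be in [0, 100] %, got {c.ejection_fraction}",
            )
        )
    _check_positive(c.lv_end_diastolic_diameter, "cardiac.lv_end_diastolic_diameter", out)
    _check_positive(c.lv_end_systolic_diameter, "cardiac.lv_end_systolic_diameter", out)

    h = record.hemodynamics
    _check_pressure(h.mpap_rest, "hemodynamics.mpap_rest", out)
    _check_pressure(h.mpap_exercise, "hemodynamics.mpap_exercise", out)
    _check_pressure(h.pawp, "hemodynamics.pawp", out)

    r = record.renal
    _check_positive(r.serum_creatinine, "renal.serum_creatinine", out)
    _check_positive(r.bun, "renal.bun", out)
    _check_positive(r.cystatin_c, "renal.cystatin_c", out)
    _check_positive(r.measured_clcr, "renal.measured_clcr", out)

    for panel_name in ("demographics", "cardiac", "hemodynamics", "pulmonary",
                       "renal", "hepatic", "neuro"):
        panel = getattr(record, panel_name)
        for f in dc_fields(panel):
            v = getattr(panel, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                out.append(Violation(f"{panel_name}.{f.name}", "must be finite"))
    return out
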