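"""Formula-derived quantities: renal clearance estimates, BMI, reference flags.

Two estimating equations drive the kidney rules:

* Cockcroft-Gault creatinine clearance (mL/min)::

      ClCr = (140 - age) * weight / (72 * SCr)      [* 0.85 if female]

* simplified MDRD glomerular filtration rate (mL/min/1.73 m²)::

      GFR = 186 * SCr^-1.154 * age^-0.203           [* 0.742 if female]
                                                    [* 1.21  if black]

with serum creatinine (SCr) in mg/dL and age in years.  The 186 leading
constant belongs to the mg/dL convention; creatinine reported in µmol/L is
converted at the I/O layer (÷ 88.4).

Derived values are carried at full precision; any display rounding happens
only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    CardiacPanel,
    Demographics,
    RangeFlag,
    ReferenceConfig,
    RenalPanel,
    Sex,
)

#: µmol/L of creatinine per mg/dL.
CREATININE_UMOL_PER_MGDL = 88.4

COCKCROFT_GAULT_FEMALE_FACTOR = 0.85
SMDRD_FEMALE_FACTOR = 0.742
SMDRD_BLACK_FACTOR = 1.21
SMDRD_CONSTANT = 186.0
SMDRD_SCR_EXPONENT = -1.154
SMDRD_AGE_EXPONENT = -0.203


class DomainError(ValueError):
    """An input outside a formula's domain; names the offending parameter."""

    def __init__(self, parameter: str, message: str):
        self.parameter = parameter
        super().__init__(f"{parameter}: {message}")


def umol_to_mgdl(scr_umol: float) -> float:
    """Convert serum creatinine from µmol/L to mg/dL."""
    return scr_umol / CREATININE_UMOL_PER_MGDL


def cockcroft_gault(scr: float, age: float, weight: float, sex: Sex) -> float:
    """Cockcroft-Gault estimated creatinine clearance in mL/min.

    Parameters
    ----------
    scr : serum creatinine, mg/dL (> 0)
    age : years, in [18, 140)
    weight : body weight, kg (> 0)
    sex : biological sex; female result is scaled by 0.85

    The denominator groups 72 with the creatinine term (the standard form of
    the equation).
    """
    if not scr > 0:
        raise DomainError("scr", f"must be strictly positive, got {scr}")
    if not 18 <= age < 140:
        raise DomainError("age", f"must be in [18, 140), got {age}")
    if not weight > 0:
        raise DomainError("weight", f"must be strictly positive, got {weight}")
    value = (140.0 - age) * weight / (72.0 * scr)
    if sex is Sex.FEMALE:
        value *= COCKCROFT_GAULT_FEMALE_FACTOR
    return value


def smdrd_gfr(
    scr: float,
    age: float,
    sex: Sex,
    black_ethnicity: bool = False,
    *,
    check_ranges: bool = True,
) -> float:
    """Simplified-MDRD estimated GFR in mL/min/1.73 m².

    ``check_ranges=False`` disables the adult age-range check (diagnostics
    mode), allowing analytic probes such as age = 1 where the age power-law
    term is exactly 1.
    """
    if not scr > 0:
        raise DomainError("scr", f"must be strictly positive, got {scr}")
    if check_ranges and not age >= 18:
        raise DomainError("age", f"must be >= 18 years, got {age}")
    if not age > 0:
        raise DomainError("age", f"must be strictly positive, got {age}")
    value = SMDRD_CONSTANT * scr**SMDRD_SCR_EXPONENT * age**SMDRD_AGE_EXPONENT
    if sex is Sex.FEMALE:
        value *= SMDRD_FEMALE_FACTOR
    if black_ethnicity:
        value *= SMDRD_BLACK_FACTOR
    return value


def bmi(weight: float, height: float) -> float:
    """Body-mass index, kg/m²: weight / height²."""
    if not weight > 0:
        raise DomainError("weight", f"must be strictly positive, got {weight}")
    if not height > 0:
        raise DomainError("height", f"must be strictly positive, got {height}")
    return weight / height**2


@dataclass(frozen=True)
class DerivedRenal:
    """Renal quantities and reference flags the kidney rules consume.

    ``clcr_flag`` is evaluated against the measured clearance when one is
    available, otherwise against the Cockcroft-Gault estimate.  ``bun_flag``
    is supportive evidence only and never triggers malfunction by itself.
    """

    clcr_cg: Optional[float]  # Cockcroft-Gault estimate, mL/min
    gfr_smdrd: Optional[float]  # mL/min/1.73m²
    clcr_flag: RangeFlag
    scr_flag: RangeFlag
    bun_flag: RangeFlag
    cystatin_flag: RangeFlag


@dataclass(frozen=True)
class Anthropometry:
    bmi: float  # kg/m²


@dataclass(frozen=True)
class LVDiameterFlags:
    lvdd_flag: RangeFlag  # end-diastolic diameter vs reference
    lvsd_flag: RangeFlag  # end-systolic diameter vs reference


def derive_renal(
    renal: RenalPanel, demographics: Demographics, config: ReferenceConfig
) -> DerivedRenal:
    """Compute clearance estimates and flag each renal measurement.

    Reference intervals are closed: boundary values count as within.  Missing
    measurements flag unknown.  Clearance is flagged sex-specifically.
    """
    scr = renal.serum_creatinine
    clcr_cg: Optional[float] = None
    gfr: Optional[float] = None
    if scr is not None and scr > 0:
        clcr_cg = cockcroft_gault(
            scr, demographics.age, demographics.weight, demographics.sex
        )
        gfr = smdrd_gfr(scr, demographics.age, demographics.sex,
                        demographics.black_ethnicity)

    clcr_value = renal.measured_clcr if renal.measured_clcr is not None else clcr_cg
    clcr_flag = config.clcr_normal(demographics.sex).flag(clcr_value)
    scr_flag = config.scr_normal.flag(scr)

    # BUN and cystatin C have a single upper limit, not an interval: only
    # elevation is clinically meaningful for congestion/filtration.
    bun_flag = RangeFlag.UNKNOWN
    if renal.bun is not None:
        bun_flag = RangeFlag.ABOVE if renal.bun > config.bun_upper else RangeFlag.WITHIN
    cystatin_flag = RangeFlag.UNKNOWN
    if renal.cystatin_c is not None:
        cystatin_flag = (
            RangeFlag.ABOVE
            if renal.cystatin_c > config.cystatin_upper
            else RangeFlag.WITHIN
        )
    return DerivedRenal(
        clcr_cg=clcr_cg,
        gfr_smdrd=gfr,
        clcr_flag=clcr_flag,
        scr_flag=scr_flag,
        bun_flag=bun_flag,
        cystatin_flag=cystatin_flag,
    )


def derive_lv_flags(cardiac: CardiacPanel, config: ReferenceConfig) -> LVDiameterFlags:
    return LVDiameterFlags(
        lvdd_flag=config.lvdd_normal.flag(cardiac.lv_end_diastolic_diameter),
        lvsd_flag=config.lvsd_normal.flag(cardiac.lv_end_systolic_diameter),
    )


def flag_reference_ranges(
    renal: RenalPanel,
    demographics: Demographics,
    cardiac: CardiacPanel,
    config: ReferenceConfig,
) -> tuple[DerivedRenal, LVDiameterFlags]:
    """Flag every available measurement against its reference interval."""
    return derive_renal(renal, demographics, config), derive_lv_flags(cardiac, config)
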