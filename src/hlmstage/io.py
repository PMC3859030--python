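"""Tabular cohort input/output and threshold-configuration files.

Cohorts travel as delimited text (comma-separated, UTF-8, "." decimal
separator), one row per patient, header mandatory.  An empty cell means
missing; tristate columns additionally accept present/absent/unknown,
1/0, true/false and yes/no.  The full column dictionary is in
``docs/column_dictionary.md`` and in :data:`COLUMNS`.

Creatinine may be reported in µmol/L via the ``creatinine_unit`` column and
is converted to mg/dL (÷ 88.4) on read; everything downstream is mg/dL.

Threshold configuration round-trips through a flat YAML mapping mirroring
:class:`~hlmstage.model.ReferenceConfig`; unknown keys are rejected to
prevent silent typos.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import yaml

from .derived import umol_to_mgdl
from .model import (
    CardiacPanel,
    Demographics,
    HemodynamicPanel,
    HemoSource,
    HepaticPanel,
    Interval,
    NeuroPanel,
    PatientRecord,
    PreviousMI,
    PulmonarySigns,
    ReferenceConfig,
    RenalPanel,
    Sex,
    Tristate,
)


class SchemaError(ValueError):
    """Structural problem with a cohort file (columns, duplicate ids)."""


@dataclass(frozen=True)
class RowError:
    row: int  # 0-based data-row index
    patient_id: str
    message: str


@dataclass(frozen=True)
class ReadResult:
    records: list[PatientRecord]
    row_errors: list[RowError]


_TRISTATE_IN = {
    "present": Tristate.PRESENT, "1": Tristate.PRESENT, "true": Tristate.PRESENT,
    "yes": Tristate.PRESENT,
    "absent": Tristate.ABSENT, "0": Tristate.ABSENT, "false": Tristate.ABSENT,
    "no": Tristate.ABSENT,
    "unknown": Tristate.UNKNOWN, "": Tristate.UNKNOWN,
}
_BOOL_IN = {"1": True, "true": True, "yes": True,
            "0": False, "false": False, "no": False}

#: column name -> (panel attribute path, kind).  Kinds: str, int, float,
#: tristate, bool, sex, mi, source, unit.
COLUMNS: dict[str, tuple[str, str]] = {
    "patient_id": ("patient_id", "str"),
    "age": ("demographics.age", "int"),
    "sex": ("demographics.sex", "sex"),
    "black_ethnicity": ("demographics.black_ethnicity", "bool"),
    "weight_kg": ("demographics.weight", "float"),
    "height_m": ("demographics.height", "float"),
    "ejection_fraction": ("cardiac.ejection_fraction", "float"),
    "systolic_dysfunction": ("cardiac.systolic_dysfunction", "tristate"),
    "diastolic_dysfunction": ("cardiac.diastolic_dysfunction", "tristate"),
    "lv_hypertrophy": ("cardiac.lv_hypertrophy", "tristate"),
    "previous_mi": ("cardiac.previous_mi", "mi"),
    "lv_end_diastolic_diameter_mm": ("cardiac.lv_end_diastolic_diameter", "float"),
    "lv_end_systolic_diameter_mm": ("cardiac.lv_end_systolic_diameter", "float"),
    "lv_remodeling": ("cardiac.lv_remodeling", "tristate"),
    "rv_dysfunction": ("cardiac.rv_dysfunction", "tristate"),
    "mpap_rest_mmhg": ("hemodynamics.mpap_rest", "float"),
    "mpap_exercise_mmhg": ("hemodynamics.mpap_exercise", "float"),
    "pawp_mmhg": ("hemodynamics.pawp", "float"),
    "hemo_source": ("hemodynamics.source", "source"),
    "clinical_congestion_signs": ("pulmonary.clinical_congestion_signs", "tristate"),
    "pulmonary_edema": ("pulmonary.pulmonary_edema", "tristate"),
    "pleural_effusion": ("pulmonary.pleural_effusion", "tristate"),
    "cardiac_lung": ("pulmonary.cardiac_lung", "tristate"),
    "abnormal_valsalva": ("pulmonary.abnormal_valsalva", "tristate"),
    "orthostatic_bp_abnormal": ("pulmonary.orthostatic_bp_abnormal", "tristate"),
    "nitroglycerin_response_abnormal":
        ("pulmonary.nitroglycerin_response_abnormal", "tristate"),
    "serum_creatinine": ("renal.serum_creatinine", "float"),
    "creatinine_unit": ("", "unit"),
    "bun_mg_dl": ("renal.bun", "float"),
    "cystatin_c_mg_l": ("renal.cystatin_c", "float"),
    "measured_clcr_ml_min": ("renal.measured_clcr", "float"),
    "bilirubin_elevated": ("hepatic.total_bilirubin_elevated", "tristate"),
    "alt_elevated": ("hepatic.alt_elevated", "tristate"),
    "ast_elevated": ("hepatic.ast_elevated", "tristate"),
    "alp_elevated": ("hepatic.alp_elevated", "tristate"),
    "ggt_elevated": ("hepatic.ggt_elevated", "tristate"),
    "albumin_decreased": ("hepatic.albumin_decreased", "tristate"),
    "inr_abnormal": ("hepatic.inr_abnormal", "tristate"),
    "on_anticoagulants": ("hepatic.on_anticoagulants", "bool_optional"),
    "ascites": ("hepatic.ascites", "tristate"),
    "portal_flow_reduced": ("hepatic.portal_flow_reduced", "tristate"),
    "ivc_noncollapsing": ("hepatic.ivc_noncollapsing", "tristate"),
    "cerebral_hypoperfusion": ("neuro.cerebral_hypoperfusion", "tristate"),
    "depression": ("neuro.depression", "tristate"),
}

MANDATORY_COLUMNS = ("patient_id", "age", "sex", "black_ethnicity",
                     "weight_kg", "height_m")


def _parse_cell(raw: str, kind: str, column: str):
    raw = raw.strip()
    if kind == "str":
        return raw
    if kind == "tristate":
        key = raw.lower()
        if key not in _TRISTATE_IN:
            raise ValueError(f"{column}: cannot parse tristate value {raw!r}")
        return _TRISTATE_IN[key]
    if kind in ("float", "int"):
        if raw == "":
            return None
        try:
            return int(raw) if kind == "int" else float(raw)
        except ValueError:
            raise ValueError(f"{column}: cannot parse number {raw!r}") from None
    if kind == "bool":
        key = raw.lower()
        if key not in _BOOL_IN:
            raise ValueError(f"{column}: cannot parse boolean {raw!r}")
        return _BOOL_IN[key]
    if kind == "bool_optional":
        if raw == "":
            return False
        return _parse_cell(raw, "bool", column)
    if kind == "sex":
        key = raw.lower()
        if key in ("female", "f"):
            return Sex.FEMALE
        if key in ("male", "m"):
            return Sex.MALE
        raise ValueError(f"{column}: cannot parse sex {raw!r}")
    if kind == "mi":
        key = raw.lower()
        if key == "":
            return PreviousMI.UNKNOWN
        try:
            return PreviousMI(key)
        except ValueError:
            raise ValueError(f"{column}: cannot parse infarction history {raw!r}") from None
    if kind == "source":
        key = raw.lower()
        if key == "":
            return HemoSource.UNKNOWN
        try:
            return HemoSource(key)
        except ValueError:
            raise ValueError(f"{column}: cannot parse hemodynamics source {raw!r}") from None
    if kind == "unit":
        key = raw.lower().replace("µ", "u")
        if key in ("", "mg/dl", "mg_dl"):
            return "mg/dL"
        if key in ("umol/l", "umol_l"):
            return "umol/L"
        raise ValueError(f"{column}: unsupported creatinine unit {raw!r}")
    raise AssertionError(f"unhandled column kind {kind}")


def _record_from_row(row: "pd.Series") -> PatientRecord:
    values: dict[str, dict] = {
        "demographics": {}, "cardiac": {}, "hemodynamics": {},
        "pulmonary": {}, "renal": {}, "hepatic": {}, "neuro": {},
    }
    patient_id = ""
    unit = "mg/dL"
    for column, raw in row.items():
        if column not in COLUMNS:
            continue  # lax mode tolerated upstream
        path, kind = COLUMNS[column]
        parsed = _parse_cell(str(raw), kind, column)
        if kind == "unit":
            unit = parsed
            continue
        if path == "patient_id":
            patient_id = parsed
            continue
        panel, attr = path.split(".")
        values[panel][attr] = parsed
    if unit == "umol/L" and values["renal"].get("serum_creatinine") is not None:
        values["renal"]["serum_creatinine"] = umol_to_mgdl(
            values["renal"]["serum_creatinine"]
        )
    demo = values["demographics"]
    missing = [k for k in ("age", "sex", "weight", "height", "black_ethnicity")
               if demo.get(k) is None]
    if missing:
        raise ValueError(f"demographics incomplete: missing {', '.join(missing)}")
    return PatientRecord(
        patient_id=patient_id,
        demographics=Demographics(**demo),
        cardiac=CardiacPanel(**values["cardiac"]),
        hemodynamics=HemodynamicPanel(**values["hemodynamics"]),
        pulmonary=PulmonarySigns(**values["pulmonary"]),
        renal=RenalPanel(**values["renal"]),
        hepatic=HepaticPanel(**values["hepatic"]),
        neuro=NeuroPanel(**values["neuro"]),
    )


def read_cohort(
    path: Union[str, Path], *, delimiter: str = ",", lax: bool = False
) -> ReadResult:
    """Read a cohort table; collects row-level failures instead of failing fast.

    Raises :class:`SchemaError` for structural problems: missing mandatory
    columns, unknown columns (unless ``lax``), or duplicate patient ids.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty or has no header") from None
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    unknown = [c for c in frame.columns if c not in COLUMNS]
    if unknown and not lax:
        raise SchemaError(
            f"unknown columns: {', '.join(unknown)} (pass lax=True to ignore)"
        )
    ids = frame["patient_id"].str.strip()
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise SchemaError(f"duplicate patient ids: {', '.join(dupes)}")

    records: list[PatientRecord] = []
    errors: list[RowError] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        pid = str(row.get("patient_id", "")).strip()
        try:
            records.append(_record_from_row(row))
        except ValueError as exc:
            errors.append(RowError(row=i, patient_id=pid, message=str(exc)))
    return ReadResult(records=records, row_errors=errors)


_TRISTATE_OUT = {Tristate.PRESENT: "present", Tristate.ABSENT: "absent",
                 Tristate.UNKNOWN: "unknown"}


def _format_cell(value, kind: str) -> str:
    if kind == "unit":
        return "mg/dL"
    if value is None:
        return ""
    if kind == "tristate":
        return _TRISTATE_OUT[value]
    if kind in ("bool", "bool_optional"):
        return "true" if value else "false"
    if kind in ("sex", "mi", "source"):
        if kind == "mi" and value is PreviousMI.UNKNOWN:
            return ""
        if kind == "source" and value is HemoSource.UNKNOWN:
            return ""
        return value.value
    if kind == "float":
        return repr(float(value))
    return str(value)


def write_cohort(
    records: Sequence[PatientRecord], path: Union[str, Path], *, delimiter: str = ","
) -> None:
    """Write records as a cohort table; ``read_cohort`` round-trips it losslessly."""
    rows = []
    for rec in records:
        row = {}
        for column, (cpath, kind) in COLUMNS.items():
            if kind == "unit":
                row[column] = _format_cell(None, kind)
            elif cpath == "patient_id":
                row[column] = rec.patient_id
            else:
                panel, attr = cpath.split(".")
                row[column] = _format_cell(getattr(getattr(rec, panel), attr), kind)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


# --- threshold configuration files -------------------------------------------

_INTERVAL_FIELDS = ("scr_normal", "clcr_normal_female", "clcr_normal_male",
                    "lvdd_normal", "lvsd_normal")


def config_to_dict(config: ReferenceConfig) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, Interval):
            out[f.name] = [v.lower, v.upper]
        else:
            out[f.name] = v
    return out


def config_from_dict(data: dict) -> ReferenceConfig:
    known = {f.name for f in dataclasses.fields(ReferenceConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise SchemaError(f"unknown configuration keys: {', '.join(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _INTERVAL_FIELDS:
            if not (isinstance(value, (list, tuple)) and len(value) == 2):
                raise SchemaError(f"{key}: expected [lower, upper], got {value!r}")
            kwargs[key] = Interval(float(value[0]), float(value[1]))
        else:
            kwargs[key] = value
    return ReferenceConfig(**kwargs)


def load_config(path: Union[str, Path]) -> ReferenceConfig:
    """Load a YAML threshold configuration; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return ReferenceConfig()
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a flat key/value mapping")
    return config_from_dict(data)


def save_config(config: ReferenceConfig, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
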