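"""Delimited-text readers and writers for cohort files.

Two UTF-8, comma-delimited files joined on ``patient_id``:

``patients.csv``
    patient_id, age, sex, weight_kg, bmi, surgery_type, surgical_access,
    prior_abdominal_surgery, adverse_outcome

``scans.csv``
    patient_id, phase, pod, supine_detected, supine_content, supine_d1_mm,
    supine_d2_mm, supine_csa_cm2, rld_detected, rld_content, rld_d1_mm,
    rld_d2_mm, rld_csa_cm2

Booleans are ``true``/``false``; optional values are empty cells.  Reading a
file written by :func:`write_cohort` reproduces the records exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd

from .records import (
    Content,
    PatientRecord,
    Phase,
    PositionMeasurement,
    ScanRecord,
    SchemaError,
    Sex,
    SurgeryType,
    SurgicalAccess,
    ValidationError,
    check_referential_integrity,
)

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "weight_kg",
    "bmi",
    "surgery_type",
    "surgical_access",
    "prior_abdominal_surgery",
    "adverse_outcome",
]

SCAN_COLUMNS = [
    "patient_id",
    "phase",
    "pod",
    "supine_detected",
    "supine_content",
    "supine_d1_mm",
    "supine_d2_mm",
    "supine_csa_cm2",
    "rld_detected",
    "rld_content",
    "rld_d1_mm",
    "rld_d2_mm",
    "rld_csa_cm2",
]


def _load_table(path, required, label: str) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{label}: missing required column(s) {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", label, ", ".join(extra))
    return frame


def _fail(label: str, row: int, field: str, message: str):
    raise ValidationError(f"{label} row {row}, field {field!r}: {message}")


def _parse_bool(raw: str, label: str, row: int, field: str) -> bool:
    value = raw.strip().lower()
    if value == "true":
        return True
    if value == "false":
        return False
    _fail(label, row, field, f"expected true/false, got {raw!r}")


def _parse_enum(enum_cls, raw: str, label: str, row: int, field: str):
    try:
        return enum_cls(raw.strip())
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        _fail(label, row, field, f"expected one of [{allowed}], got {raw!r}")


def _parse_opt_float(raw: str, label: str, row: int, field: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        _fail(label, row, field, f"expected a number or empty, got {raw!r}")


def _parse_int(raw: str, label: str, row: int, field: str) -> int:
    try:
        return int(raw.strip())
    except ValueError:
        _fail(label, row, field, f"expected an integer, got {raw!r}")


def _revalidate(exc: ValidationError, label: str, row: int):
    raise ValidationError(f"{label} row {row}: {exc}") from exc


def read_patients(path) -> List[PatientRecord]:
    label = Path(path).name
    frame = _load_table(path, PATIENT_COLUMNS, label)
    patients: List[PatientRecord] = []
    for row, rec in enumerate(frame.to_dict("records")):
        try:
            patients.append(
                PatientRecord(
                    patient_id=rec["patient_id"].strip(),
                    age=_parse_int(rec["age"], label, row, "age"),
                    sex=_parse_enum(Sex, rec["sex"], label, row, "sex"),
                    weight_kg=_parse_opt_float(rec["weight_kg"], label, row, "weight_kg"),
                    bmi=_parse_opt_float(rec["bmi"], label, row, "bmi"),
                    surgery_type=_parse_enum(
                        SurgeryType, rec["surgery_type"], label, row, "surgery_type"
                    ),
                    surgical_access=_parse_enum(
                        SurgicalAccess, rec["surgical_access"], label, row, "surgical_access"
                    ),
                    prior_abdominal_surgery=_parse_bool(
                        rec["prior_abdominal_surgery"], label, row, "prior_abdominal_surgery"
                    ),
                    adverse_outcome=_parse_bool(
                        rec["adverse_outcome"], label, row, "adverse_outcome"
                    ),
                )
            )
        except ValidationError as exc:
            if " row " in str(exc):
                raise
            _revalidate(exc, label, row)
    return patients


def _parse_position(rec, prefix: str, label: str, row: int) -> PositionMeasurement:
    return PositionMeasurement(
        detected=_parse_bool(rec[f"{prefix}_detected"], label, row, f"{prefix}_detected"),
        content=_parse_enum(Content, rec[f"{prefix}_content"], label, row, f"{prefix}_content"),
        d1_mm=_parse_opt_float(rec[f"{prefix}_d1_mm"], label, row, f"{prefix}_d1_mm"),
        d2_mm=_parse_opt_float(rec[f"{prefix}_d2_mm"], label, row, f"{prefix}_d2_mm"),
        csa_traced_cm2=_parse_opt_float(
            rec[f"{prefix}_csa_cm2"], label, row, f"{prefix}_csa_cm2"
        ),
    )


def read_scans(path) -> List[ScanRecord]:
    label = Path(path).name
    frame = _load_table(path, SCAN_COLUMNS, label)
    scans: List[ScanRecord] = []
    for row, rec in enumerate(frame.to_dict("records")):
        try:
            phase = _parse_enum(Phase, rec["phase"], label, row, "phase")
            pod_raw = rec["pod"].strip()
            pod = None if pod_raw == "" else _parse_int(pod_raw, label, row, "pod")
            scans.append(
                ScanRecord(
                    patient_id=rec["patient_id"].strip(),
                    phase=phase,
                    pod=pod,
                    supine=_parse_position(rec, "supine", label, row),
                    rld=_parse_position(rec, "rld", label, row),
                )
            )
        except ValidationError as exc:
            if " row " in str(exc):
                raise
            _revalidate(exc, label, row)
    return scans


def read_cohort(patients_path, scans_path) -> Tuple[List[PatientRecord], List[ScanRecord]]:
    """Read and cross-validate a two-file cohort.

    Raises :class:`SchemaError` for missing columns, :class:`ValidationError`
    for invariant violations (naming file, row and field), and
    :class:`ReferentialError` when a scan names an unknown patient.
    """
    patients = read_patients(patients_path)
    scans = read_scans(scans_path)
    check_referential_integrity(patients, scans)
    return patients, scans


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_cohort(patients, scans, out_dir) -> Tuple[Path, Path]:
    """Write ``patients.csv`` and ``scans.csv`` into ``out_dir``.

    Optional values become empty cells; the output reads back to records equal
    to the inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients_path = out / "patients.csv"
    scans_path = out / "scans.csv"

    prows = [
        {
            "patient_id": p.patient_id,
            "age": p.age,
            "sex": p.sex.value,
            "weight_kg": _fmt(p.weight_kg),
            "bmi": _fmt(p.bmi),
            "surgery_type": p.surgery_type.value,
            "surgical_access": p.surgical_access.value,
            "prior_abdominal_surgery": _fmt(p.prior_abdominal_surgery),
            "adverse_outcome": _fmt(p.adverse_outcome),
        }
        for p in patients
    ]
    pd.DataFrame(prows, columns=PATIENT_COLUMNS).to_csv(patients_path, index=False)

    srows = []
    for s in scans:
        row = {"patient_id": s.patient_id, "phase": s.phase.value, "pod": _fmt(s.pod)}
        for prefix, m in (("supine", s.supine), ("rld", s.rld)):
            row[f"{prefix}_detected"] = _fmt(m.detected)
            row[f"{prefix}_content"] = m.content.value
            row[f"{prefix}_d1_mm"] = _fmt(m.d1_mm)
            row[f"{prefix}_d2_mm"] = _fmt(m.d2_mm)
            row[f"{prefix}_csa_cm2"] = _fmt(m.csa_traced_cm2)
        srows.append(row)
    pd.DataFrame(srows, columns=SCAN_COLUMNS).to_csv(scans_path, index=False)

    return patients_path, scans_path
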