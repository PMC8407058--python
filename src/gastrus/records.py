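"""Domain records for gastric-ultrasound cohorts.

A cohort is a list of :class:`PatientRecord` joined, on ``patient_id``, to a
list of :class:`ScanRecord`.  One scan is one bedside examination and carries
two :class:`PositionMeasurement` blocks, one per patient position (supine /
semi-recumbent and right lateral decubitus), because the gastric antrum is
imaged in both positions and the grading and volume models are position
specific.

All records are immutable and validate their invariants on construction, so
every downstream computation can assume well-formed inputs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional


class CohortError(ValueError):
    """Base class for cohort data errors."""


class SchemaError(CohortError):
    """A delimited-text file does not have the expected columns."""


class ValidationError(CohortError):
    """A record violates a type invariant."""


class ReferentialError(CohortError):
    """A scan refers to a patient that does not exist."""


class DomainError(CohortError):
    """An operation received an argument outside its mathematical domain."""


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class SurgeryType(str, enum.Enum):
    colorectal = "colorectal"
    small_bowel = "small_bowel"
    cholecystectomy = "cholecystectomy"
    appendectomy = "appendectomy"
    hernioplasty = "hernioplasty"
    other = "other"


#: Operations entailing a high risk of postoperative ileus (extensive bowel
#: manipulation); used to select the major-surgery subgroup.
MAJOR_SURGERY = frozenset({SurgeryType.colorectal, SurgeryType.small_bowel})


class SurgicalAccess(str, enum.Enum):
    open = "open"
    laparoscopic = "laparoscopic"
    other = "other"


class Phase(str, enum.Enum):
    preoperative = "preoperative"
    postoperative = "postoperative"


class Content(str, enum.Enum):
    """Qualitative sonographic pattern of the gastric lumen."""

    empty = "empty"
    liquid = "liquid"
    solid = "solid"
    mixed = "mixed"
    unknown = "unknown"


#: Contents that count as fluid-bearing for the antral grading system.
FLUID_CONTENTS = frozenset({Content.liquid, Content.mixed})
#: Contents that count as solid-bearing for the aspiration-risk rule.
SOLID_CONTENTS = frozenset({Content.solid, Content.mixed})


def _check_optional_measure(name: str, value: Optional[float]) -> None:
    if value is None:
        return
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True)
class PatientRecord:
    """Demographics, surgery descriptors and the composite adverse-outcome flag.

    ``adverse_outcome`` is true when the patient experienced nausea and/or
    vomiting, received antiemetic therapy, had delayed return of bowel
    function, and/or had a nasogastric tube placed.
    """

    patient_id: str
    age: int
    sex: Sex
    surgery_type: SurgeryType
    surgical_access: SurgicalAccess
    prior_abdominal_surgery: bool
    adverse_outcome: bool
    weight_kg: Optional[float] = None
    bmi: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be a non-empty string")
        if not isinstance(self.age, int) or isinstance(self.age, bool) or self.age < 0:
            raise ValidationError(
                f"patient {self.patient_id}: age must be an integer >= 0, got {self.age!r}"
            )
        for name, value in (("weight_kg", self.weight_kg), ("bmi", self.bmi)):
            if value is not None and (not math.isfinite(value) or value <= 0):
                raise ValidationError(
                    f"patient {self.patient_id}: {name} must be positive, got {value!r}"
                )


@dataclass(frozen=True)
class PositionMeasurement:
    """One position's findings: detection, content, diameters, traced area.

    ``d1_mm``/``d2_mm`` are the anteroposterior and craniocaudal antral
    diameters in millimetres; ``csa_traced_cm2`` is the cross-sectional area
    traced directly on the ultrasound machine.  When the antrum could not be
    detected the content is unknown and no measurement is recorded.
    """

    detected: bool
    content: Content = Content.unknown
    d1_mm: Optional[float] = None
    d2_mm: Optional[float] = None
    csa_traced_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.detected:
            if self.content is not Content.unknown:
                raise ValidationError(
                    f"undetected antrum cannot have content {self.content.value!r}"
                )
            if any(v is not None for v in (self.d1_mm, self.d2_mm, self.csa_traced_cm2)):
                raise ValidationError("undetected antrum cannot carry measurements")
        _check_optional_measure("d1_mm", self.d1_mm)
        _check_optional_measure("d2_mm", self.d2_mm)
        _check_optional_measure("csa_traced_cm2", self.csa_traced_cm2)


#: A measurement block for an undetected antrum (the common miss case).
NOT_DETECTED = PositionMeasurement(detected=False)


@dataclass(frozen=True)
class ScanRecord:
    """One ultrasound examination of one patient.

    ``pod`` is the 1-based postoperative day and is present exactly when the
    scan is postoperative.
    """

    patient_id: str
    phase: Phase
    supine: PositionMeasurement
    rld: PositionMeasurement
    pod: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be a non-empty string")
        if self.phase is Phase.preoperative:
            if self.pod is not None:
                raise ValidationError(
                    f"patient {self.patient_id}: preoperative scan cannot carry a pod"
                )
        else:
            if not isinstance(self.pod, int) or isinstance(self.pod, bool) or self.pod < 1:
                raise ValidationError(
                    f"patient {self.patient_id}: postoperative scan needs an integer pod >= 1"
                )

    def position(self, which: str) -> PositionMeasurement:
        """Return the supine or RLD measurement block by name."""
        if which == "supine":
            return self.supine
        if which == "rld":
            return self.rld
        raise DomainError(f"unknown position {which!r} (expected 'supine' or 'rld')")


def check_referential_integrity(patients, scans) -> None:
    """Raise unless every scan's patient_id names a unique, existing patient."""
    ids = [p.patient_id for p in patients]
    seen = set()
    for pid in ids:
        if pid in seen:
            raise ValidationError(f"duplicate patient_id {pid!r}")
        seen.add(pid)
    for i, scan in enumerate(scans):
        if scan.patient_id not in seen:
            raise ReferentialError(
                f"scan row {i}: patient_id {scan.patient_id!r} has no patient record"
            )
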