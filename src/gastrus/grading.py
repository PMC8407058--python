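"""Antral grading and the aspiration-risk decision rule.

The three-grade antral system summarizes where fluid is seen:

* Grade 0 - no fluid content in either position (supine and RLD);
* Grade 1 - fluid only in right lateral decubitus;
* Grade 2 - fluid in both positions.

The risk flowchart labels a scan high risk when it shows solid (or mixed)
content, Grade-2 fluid, or a predicted gastric volume above a weight-adjusted
threshold (default 1.5 mL/kg); a scan is low risk only when all three branches
can be evaluated and are negative; otherwise the assessment is indeterminate.
Patient-level risk aggregates postoperative scans: high if any scan is high,
indeterminate if every scan is indeterminate, low otherwise.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .antrum import (
    RISK_THRESHOLD_ML_PER_KG,
    VolumeEstimate,
    available_csa,
    estimate_volume,
)
from .records import (
    Content,
    DomainError,
    FLUID_CONTENTS,
    PatientRecord,
    Phase,
    ScanRecord,
    SOLID_CONTENTS,
)

logger = logging.getLogger(__name__)


class AntralGrade(str, enum.Enum):
    G0 = "G0"
    G1 = "G1"
    G2 = "G2"
    indeterminate = "indeterminate"


class Risk(str, enum.Enum):
    high = "high"
    low = "low"
    indeterminate = "indeterminate"


class FiredRule(str, enum.Enum):
    solid_content = "solid_content"
    grade2_fluid = "grade2_fluid"
    volume_over_threshold = "volume_over_threshold"
    below_threshold = "below_threshold"
    insufficient_data = "insufficient_data"


def _is_fluid(content: Content) -> bool:
    return content in FLUID_CONTENTS


def antral_grade(supine_content: Content, rld_content: Content) -> AntralGrade:
    """Three-grade antral classification from per-position content.

    ``unknown`` marks a position whose content could not be assessed.  When
    the supine content is unknown but the RLD shows fluid, the minimum grade
    consistent with the observation (G1) is reported rather than
    indeterminate, so that downstream volume assessment can still run; this
    conservative call is logged.  Fluid seen only in supine has no grade in
    the three-grade system and is reported indeterminate.
    """
    if not isinstance(supine_content, Content) or not isinstance(rld_content, Content):
        raise DomainError("contents must be Content enum members")

    sup_known = supine_content is not Content.unknown
    rld_known = rld_content is not Content.unknown

    if sup_known and rld_known:
        sup_fluid, rld_fluid = _is_fluid(supine_content), _is_fluid(rld_content)
        if sup_fluid and rld_fluid:
            return AntralGrade.G2
        if rld_fluid:
            return AntralGrade.G1
        if not sup_fluid:
            return AntralGrade.G0
        # fluid only in supine: outside the grading system
        return AntralGrade.indeterminate
    if not sup_known and rld_known and _is_fluid(rld_content):
        logger.info(
            "supine content unknown with fluid in RLD: reporting minimum consistent grade G1"
        )
        return AntralGrade.G1
    return AntralGrade.indeterminate


@dataclass(frozen=True)
class RiskAssessment:
    """Outcome of the risk flowchart for one scan (or one patient)."""

    grade: AntralGrade
    risk: Risk
    fired_rule: FiredRule
    volume: Optional[VolumeEstimate] = None

    def __post_init__(self) -> None:
        high_rules = {
            FiredRule.solid_content,
            FiredRule.grade2_fluid,
            FiredRule.volume_over_threshold,
        }
        if (self.risk is Risk.high) != (self.fired_rule in high_rules):
            raise DomainError("risk=high must pair with a high-risk rule")
        if (self.risk is Risk.indeterminate) != (
            self.fired_rule is FiredRule.insufficient_data
        ):
            raise DomainError("risk=indeterminate must pair with insufficient_data")


def classify_risk(
    scan: ScanRecord,
    patient: PatientRecord,
    threshold_ml_per_kg: float = RISK_THRESHOLD_ML_PER_KG,
) -> RiskAssessment:
    """Apply the aspiration-risk flowchart to one scan.

    Branch order: (1) solid or mixed content in any detected position;
    (2) Grade-2 fluid; (3) predicted gastric volume above
    ``threshold_ml_per_kg``.  The RLD CSA feeding branch 3 is the traced area
    when present, else the ellipse area from the RLD diameters.  Low risk
    requires every branch to be decidable and negative; missing data yields an
    indeterminate assessment, never an error.
    """
    if threshold_ml_per_kg <= 0:
        raise DomainError(f"threshold must be > 0, got {threshold_ml_per_kg!r}")

    grade = antral_grade(scan.supine.content, scan.rld.content)

    # branch 1: solid-bearing content in a detected position
    for m in (scan.supine, scan.rld):
        if m.detected and m.content in SOLID_CONTENTS:
            return RiskAssessment(grade=grade, risk=Risk.high, fired_rule=FiredRule.solid_content)

    # branch 2: Grade-2 fluid
    if grade is AntralGrade.G2:
        return RiskAssessment(grade=grade, risk=Risk.high, fired_rule=FiredRule.grade2_fluid)

    # branch 3: predicted volume per kg
    csa = available_csa(scan.rld)
    volume: Optional[VolumeEstimate] = None
    per_kg: Optional[float] = None
    if csa is not None and patient.weight_kg is not None:
        volume = estimate_volume(csa, patient.age, patient.weight_kg)
        per_kg = volume.volume_ml_per_kg
        if per_kg is not None and per_kg > threshold_ml_per_kg:
            return RiskAssessment(
                grade=grade,
                risk=Risk.high,
                fired_rule=FiredRule.volume_over_threshold,
                volume=volume,
            )

    # Grade 2 is excluded once the grade is known (G0/G1, including the
    # conservative unknown-supine G1 call) or either position is known
    # non-fluid.
    g2_excluded = grade in (AntralGrade.G0, AntralGrade.G1) or any(
        m.content is not Content.unknown and m.content not in FLUID_CONTENTS
        for m in (scan.supine, scan.rld)
    )

    if g2_excluded and per_kg is not None and per_kg <= threshold_ml_per_kg:
        return RiskAssessment(
            grade=grade, risk=Risk.low, fired_rule=FiredRule.below_threshold, volume=volume
        )

    logger.info(
        "patient %s: indeterminate risk (grade=%s, rld CSA %s, weight %s)",
        scan.patient_id,
        grade.value,
        "available" if csa is not None else "missing",
        "known" if patient.weight_kg is not None else "missing",
    )
    return RiskAssessment(
        grade=grade, risk=Risk.indeterminate, fired_rule=FiredRule.insufficient_data, volume=volume
    )


def assess_patient(
    patient: PatientRecord,
    scans: Sequence[ScanRecord],
    threshold_ml_per_kg: float = RISK_THRESHOLD_ML_PER_KG,
    phase: Optional[Phase] = Phase.postoperative,
) -> RiskAssessment:
    """Aggregate scan-level assessments into one per-patient assessment.

    Considers the patient's scans of the given phase (postoperative by
    default, ``None`` for all phases): high if any scan is high (that scan's
    assessment is returned), low if any scan is low and none high,
    indeterminate otherwise.
    """
    relevant = [
        s
        for s in scans
        if s.patient_id == patient.patient_id and (phase is None or s.phase is phase)
    ]
    assessments = [classify_risk(s, patient, threshold_ml_per_kg) for s in relevant]
    for a in assessments:
        if a.risk is Risk.high:
            return a
    for a in assessments:
        if a.risk is Risk.low:
            return a
    if assessments:
        return assessments[0]
    return RiskAssessment(
        grade=AntralGrade.indeterminate,
        risk=Risk.indeterminate,
        fired_rule=FiredRule.insufficient_data,
    )


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-patient risk predictions tallied against the adverse-outcome flag.

    ``prediction_rate_pct`` is the fraction of adverse-outcome patients with a
    (determinate) high-risk assessment, as a percentage — the rule's
    sensitivity.  Indeterminate assessments are tallied separately and do not
    enter the rate.
    """

    true_pos: int
    false_neg: int
    false_pos: int
    true_neg: int
    indeterminate: int
    prediction_rate_pct: Optional[float]


def prediction_confusion(
    assessments: Iterable[Tuple[str, RiskAssessment]],
    patients: Sequence[PatientRecord],
) -> ConfusionSummary:
    """Compare per-patient risk assessments with observed adverse outcomes."""
    by_id: Dict[str, PatientRecord] = {p.patient_id: p for p in patients}
    seen: set = set()
    tp = fn = fp = tn = ind = 0
    for pid, assessment in assessments:
        if pid not in by_id:
            raise DomainError(f"assessment for unknown patient_id {pid!r}")
        if pid in seen:
            raise DomainError(f"patient {pid!r} assessed more than once")
        seen.add(pid)
        adverse = by_id[pid].adverse_outcome
        if assessment.risk is Risk.indeterminate:
            ind += 1
        elif assessment.risk is Risk.high:
            tp += adverse
            fp += not adverse
        else:
            fn += adverse
            tn += not adverse
    if tp + fn == 0:
        logger.warning("no adverse-outcome patients with determinate risk: rate undefined")
        rate = None
    else:
        rate = 100.0 * tp / (tp + fn)
    return ConfusionSummary(
        true_pos=tp,
        false_neg=fn,
        false_pos=fp,
        true_neg=tn,
        indeterminate=ind,
        prediction_rate_pct=rate,
    )


def assess_cohort(
    patients: Sequence[PatientRecord],
    scans: Sequence[ScanRecord],
    threshold_ml_per_kg: float = RISK_THRESHOLD_ML_PER_KG,
) -> List[Tuple[str, RiskAssessment]]:
    """Per-patient aggregated assessments for a whole cohort (postoperative scans)."""
    by_patient: Dict[str, List[ScanRecord]] = {p.patient_id: [] for p in patients}
    for s in scans:
        by_patient.setdefault(s.patient_id, []).append(s)
    return [
        (p.patient_id, assess_patient(p, by_patient[p.patient_id], threshold_ml_per_kg))
        for p in patients
    ]
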