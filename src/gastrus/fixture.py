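"""Deterministic cohort fixture reproducing the printed cohort marginals.

The raw per-scan data behind the published cohort are not available, so this
module constructs, by explicit assignment (counting, not sampling), a
synthetic 41-patient / 94-scan cohort whose marginal counts equal the printed
ones:

* 28 preoperative and 66 postoperative scans;
* antrum detected in 62/94 scans in at least one position, 59/94 supine,
  57/94 RLD; 16/28 preoperative and 46/66 postoperative scans detected;
* patient-level detection 15/19 in laparoscopic and 7/22 in open access;
* antral grades: 34 G0, 5 G1, 16 G2, 39 not assessable;
* an 18-patient major-surgery subgroup containing 6 adverse-outcome patients
  of whom exactly one meets the high-risk criteria (Grade-2 fluid), for a
  prediction rate of 1/6;
* adverse patients scanned on postoperative days 1-4 with relative CSA
  rising exactly 1/6 per day (+50 % over 72 h).

Being deterministic, every acceptance-style check on it is exact regardless
of RNG details.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .io import write_cohort
from .records import (
    Content,
    NOT_DETECTED,
    PatientRecord,
    Phase,
    PositionMeasurement,
    ScanRecord,
    Sex,
    SurgeryType,
    SurgicalAccess,
)

_ECC = 1.08  # fixed diameter eccentricity used for all fixture measurements


def _meas(content: Content, csa: Optional[float]) -> PositionMeasurement:
    """Detected-position measurement whose traced and calculated CSA agree."""
    if csa is None:
        return PositionMeasurement(detected=True, content=content)
    d1_cm = math.sqrt(4.0 * csa * _ECC / math.pi)
    d2_cm = d1_cm / _ECC
    return PositionMeasurement(
        detected=True,
        content=content,
        d1_mm=d1_cm * 10.0,
        d2_mm=d2_cm * 10.0,
        csa_traced_cm2=csa,
    )


def _both(sup_content: Content, rld_content: Content, rld_csa: float) -> Tuple[
    PositionMeasurement, PositionMeasurement
]:
    return _meas(sup_content, 0.92 * rld_csa), _meas(rld_content, rld_csa)


def _g0(rld_csa: float):
    return _both(Content.empty, Content.empty, rld_csa)


def _g1(rld_csa: float):
    return _both(Content.empty, Content.liquid, rld_csa)


def _g2(rld_csa: float):
    return _both(Content.liquid, Content.liquid, rld_csa)


def _sup_only(sup_csa: float):
    return _meas(Content.empty, sup_csa), NOT_DETECTED


def _rld_only(content: Content, rld_csa: float):
    return NOT_DETECTED, _meas(content, rld_csa)


_FEMALE = {2, 4, 7, 10, 14, 17, 21, 24, 28, 31, 34, 37, 39}
_PRIOR = {3, 5, 8, 13, 16, 18, 20, 22, 25, 27, 30, 32, 35, 38, 40}

_AGES = {1: 58, 2: 62, 3: 66, 4: 65, 5: 68, 6: 70, 7: 46, 8: 50, 9: 54, 10: 48,
         11: 52, 12: 56}
_WEIGHTS = {1: 75.0, 2: 80.0, 3: 80.0, 4: 80.0, 5: 82.0, 6: 85.0, 7: 70.0,
            8: 72.0, 9: 75.0, 10: 68.0, 11: 74.0, 12: 76.0}


def _surgery(i: int) -> SurgeryType:
    if i <= 12:
        return SurgeryType.colorectal
    if i in (16, 17, 18, 19, 27, 28):
        return SurgeryType.small_bowel
    if i in (13, 14, 15, 20, 21, 22, 23):
        return SurgeryType.cholecystectomy
    if i in (24, 25, 26, 29, 30, 31, 32):
        return SurgeryType.appendectomy
    if i in (33, 34, 35, 36):
        return SurgeryType.hernioplasty
    return SurgeryType.other


def build_results_cohort() -> Tuple[List[PatientRecord], List[ScanRecord]]:
    """The deterministic cohort with the printed marginal counts."""
    patients: List[PatientRecord] = []
    for i in range(1, 42):
        patients.append(
            PatientRecord(
                patient_id=f"P{i:02d}",
                age=_AGES.get(i, 35 + (i * 7) % 45),
                sex=Sex.female if i in _FEMALE else Sex.male,
                weight_kg=_WEIGHTS.get(i, 60.0 + (i * 3) % 30),
                bmi=round((_WEIGHTS.get(i, 60.0 + (i * 3) % 30)) / 2.89, 1),
                surgery_type=_surgery(i),
                surgical_access=SurgicalAccess.laparoscopic if i <= 19 else SurgicalAccess.open,
                prior_abdominal_surgery=i in _PRIOR,
                adverse_outcome=i <= 6,
            )
        )

    scans: List[ScanRecord] = []

    def pre(pid: int, sup: PositionMeasurement, rld: PositionMeasurement) -> None:
        scans.append(ScanRecord(patient_id=f"P{pid:02d}", phase=Phase.preoperative,
                                supine=sup, rld=rld))

    def post(pid: int, pod: int, sup: PositionMeasurement, rld: PositionMeasurement) -> None:
        scans.append(ScanRecord(patient_id=f"P{pid:02d}", phase=Phase.postoperative,
                                pod=pod, supine=sup, rld=rld))

    def undetected_pre(pid: int) -> None:
        pre(pid, NOT_DETECTED, NOT_DETECTED)

    def undetected_post(pid: int, pod: int) -> None:
        post(pid, pod, NOT_DETECTED, NOT_DETECTED)

    # P01: the one adverse patient the flowchart flags (Grade-2 fluid),
    # antrum enlarged and rising 50 % over PODs 1-4.
    pre(1, *_g2(12.0))
    for pod in range(1, 5):
        post(1, pod, *_g2(12.0 * (5 + pod) / 6.0))

    # P02-P06: adverse, enlarged rising antrum, but empty contents and
    # predicted volume below 1.5 mL/kg on every scan -> missed by the rule.
    bases = {2: 6.0, 3: 6.6, 4: 7.2, 5: 7.8, 6: 8.4}
    for pid, base in bases.items():
        pre(pid, *_g0(5.0 + 0.1 * (pid - 2)))
        for pod in range(1, 5):
            post(pid, pod, *_g0(base * (5 + pod) / 6.0))

    # P07-P12: uneventful subgroup patients, low risk on their scans.
    for k, pid in enumerate((7, 8, 9)):
        pre(pid, *_g0(4.9 - 0.1 * k))
        post(pid, 1, *_g0(5.1 + 0.1 * k))
        post(pid, 2, *_g1(6.0 + 0.1 * k))
    pre(10, *_g0(4.7))
    post(10, 1, *_g1(6.2))
    post(10, 2, *_rld_only(Content.liquid, 6.4))
    pre(11, *_g0(4.9))
    post(11, 1, *_sup_only(4.8))
    post(11, 2, *_rld_only(Content.empty, 5.1))
    pre(12, *_g0(5.0))
    post(12, 1, *_rld_only(Content.empty, 5.2))
    post(12, 2, *_sup_only(4.9))

    # P13-P15 (laparoscopic) and P20 (open): detected, outside the subgroup.
    pre(13, *_g2(9.0)); post(13, 1, *_g2(10.0)); undetected_post(13, 2)
    pre(14, *_g2(8.5)); post(14, 1, *_g2(9.5)); undetected_post(14, 2)
    pre(15, *_g2(8.0)); post(15, 1, *_sup_only(7.4)); undetected_post(15, 2)
    pre(20, *_g2(8.2)); post(20, 1, *_sup_only(7.6)); undetected_post(20, 2)

    # P21-P26: open-access patients detected postoperatively only.
    post(21, 1, *_g2(9.2)); undetected_post(21, 2)
    for pid, csa in ((22, 9.4), (23, 9.6), (24, 9.8), (25, 10.2)):
        post(pid, 1, *_g2(csa))
    post(26, 1, *_sup_only(7.2))

    # Undetected patients: P16-P19 and P27-P30 scanned in both phases,
    # P31-P37 postoperatively only, P38-P41 preoperatively only.
    for pid in (16, 17, 18, 19, 27, 28, 29, 30):
        undetected_pre(pid)
        undetected_post(pid, 1)
    for pid in range(31, 38):
        undetected_post(pid, 1)
    for pid in range(38, 42):
        undetected_pre(pid)

    _verify(patients, scans)
    return patients, scans


def _verify(patients: List[PatientRecord], scans: List[ScanRecord]) -> None:
    """Independent counting check of every marginal the fixture promises."""
    assert len(patients) == 41 and len(scans) == 94
    pre = [s for s in scans if s.phase is Phase.preoperative]
    post = [s for s in scans if s.phase is Phase.postoperative]
    assert (len(pre), len(post)) == (28, 66)

    def either(s: ScanRecord) -> bool:
        return s.supine.detected or s.rld.detected

    assert sum(either(s) for s in scans) == 62
    assert sum(s.supine.detected for s in scans) == 59
    assert sum(s.rld.detected for s in scans) == 57
    assert sum(either(s) for s in pre) == 16
    assert sum(either(s) for s in post) == 46

    by_access: Dict[SurgicalAccess, List[PatientRecord]] = {}
    for p in patients:
        by_access.setdefault(p.surgical_access, []).append(p)
    det_ids = {s.patient_id for s in scans if either(s)}
    lap = by_access[SurgicalAccess.laparoscopic]
    opn = by_access[SurgicalAccess.open]
    assert (len(lap), sum(p.patient_id in det_ids for p in lap)) == (19, 15)
    assert (len(opn), sum(p.patient_id in det_ids for p in opn)) == (22, 7)

    fluid = {Content.liquid, Content.mixed}
    g0 = g1 = g2 = none = 0
    for s in scans:
        sk, rk = s.supine.content, s.rld.content
        if sk is not Content.unknown and rk is not Content.unknown:
            if sk in fluid and rk in fluid:
                g2 += 1
            elif rk in fluid:
                g1 += 1
            else:
                g0 += 1
        elif sk is Content.unknown and rk in fluid:
            g1 += 1
        else:
            none += 1
    assert (g0, g1, g2, none) == (34, 5, 16, 39)


def make_fixture_resultslike(out_dir) -> Tuple[Path, Path]:
    """Write the deterministic cohort as patients.csv / scans.csv."""
    patients, scans = build_results_cohort()
    return write_cohort(patients, scans, out_dir)
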