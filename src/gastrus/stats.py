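"""Cohort statistics: detection rates, 2x2 chi-squared, t-tests, descriptives.

Categorical comparisons use the uncorrected Pearson chi-squared statistic on
2x2 tables (no Yates continuity correction); numeric comparisons use the
pooled-variance two-sample Student t-test (Welch available as an option);
descriptives are median and interquartile range with linear-interpolation
quartiles, plus mean and n-1 standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .antrum import scan_csa
from .records import (
    DomainError,
    PatientRecord,
    Phase,
    ScanRecord,
    SurgicalAccess,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) in stratum 1 and (c, d) in stratum 2, columns =
    event / no-event (e.g. antrum detected / not detected)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise DomainError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise DomainError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value must be in [0, 1], got {self.p_value!r}")


def pearson_chi2_statistic(a: float, b: float, c: float, d: float) -> float:
    """Closed-form uncorrected Pearson statistic n(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def chi_squared_2x2(table: ContingencyTable2x2) -> TestResult:
    """Uncorrected Pearson chi-squared test of independence on a 2x2 table.

    A table with a zero margin carries no information about association; it
    yields statistic 0 and p = 1 with a warning.
    """
    denom = (table.a + table.b) * (table.c + table.d) * (table.a + table.c) * (table.b + table.d)
    if denom == 0:
        logger.warning("chi-squared on a table with a zero margin: statistic 0, p = 1")
        return TestResult(statistic=0.0, p_value=1.0, df=1)
    stat = pearson_chi2_statistic(table.a, table.b, table.c, table.d)
    return TestResult(statistic=stat, p_value=float(sps.chi2.sf(stat, df=1)), df=1)


def student_t_two_sample(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-tailed two-sample t-test, pooled variance by default.

    Both samples need >= 2 values.  Two constant, equal samples give t = 0,
    p = 1 (no evidence of a difference rather than an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DomainError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("samples must be finite")
    df = x.size + y.size - 2 if not welch else None
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(statistic=0.0, p_value=1.0, df=float(df or 0))
        return TestResult(statistic=float("inf"), p_value=0.0, df=float(df or 0))
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), df=float(res.df)
    )


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    mean: float
    sd: Optional[float]


def descriptive_summary(values: Sequence[float]) -> DescriptiveSummary:
    """Median/IQR (linear-interpolation quartiles), mean and n-1 SD.

    The SD of a single observation is undefined and reported as ``None``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise DomainError("need at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return DescriptiveSummary(
        n=int(arr.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(q3 - q1),
        mean=float(arr.mean()),
        sd=sd,
    )


@dataclass(frozen=True)
class DetectionRate:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def pct(self) -> float:
        return 100.0 * self.fraction


def _scan_detected(scan: ScanRecord, position: str) -> bool:
    if position == "either":
        return scan.supine.detected or scan.rld.detected
    return scan.position(position).detected


def detection_rate(
    scans: Sequence[ScanRecord],
    position: str = "either",
    *,
    patients: Optional[Sequence[PatientRecord]] = None,
    where: Optional[Callable[[ScanRecord, Optional[PatientRecord]], bool]] = None,
    unit: str = "scan",
) -> DetectionRate:
    """Antrum detection rate per scan or per patient.

    ``position`` is ``"supine"``, ``"rld"`` or ``"either"``.  ``where`` is an
    optional predicate over ``(scan, patient)`` (the patient is ``None``
    unless ``patients`` is supplied).  With ``unit="patient"`` the denominator
    is the number of distinct patients among the filtered scans and a patient
    counts as detected if any of their scans is.
    """
    if unit not in ("scan", "patient"):
        raise DomainError(f"unit must be 'scan' or 'patient', got {unit!r}")
    by_id: Dict[str, PatientRecord] = (
        {p.patient_id: p for p in patients} if patients is not None else {}
    )
    selected = [
        s for s in scans if where is None or where(s, by_id.get(s.patient_id))
    ]
    if not selected:
        raise DomainError("no scans left after filtering")
    if unit == "scan":
        num = sum(_scan_detected(s, position) for s in selected)
        return DetectionRate(numerator=num, denominator=len(selected))
    detected_by_patient: Dict[str, bool] = {}
    for s in selected:
        detected_by_patient[s.patient_id] = detected_by_patient.get(
            s.patient_id, False
        ) or _scan_detected(s, position)
    return DetectionRate(
        numerator=sum(detected_by_patient.values()),
        denominator=len(detected_by_patient),
    )


def _rate_row(label: str, r1_name: str, r1: DetectionRate, r2_name: str, r2: DetectionRate) -> dict:
    test = chi_squared_2x2(
        ContingencyTable2x2(
            a=r1.numerator,
            b=r1.denominator - r1.numerator,
            c=r2.numerator,
            d=r2.denominator - r2.numerator,
        )
    )
    return {
        "comparison": label,
        "group1": r1_name,
        "group1_rate": f"{r1.numerator}/{r1.denominator}",
        "group1_pct": round(r1.pct, 1),
        "group2": r2_name,
        "group2_rate": f"{r2.numerator}/{r2.denominator}",
        "group2_pct": round(r2.pct, 1),
        "statistic": test.statistic,
        "p_value": test.p_value,
    }


def standard_comparisons(
    patients: Sequence[PatientRecord], scans: Sequence[ScanRecord]
) -> pd.DataFrame:
    """The stratified detection-rate comparisons of a cohort analysis.

    Rows: supine vs RLD position (per scan), preoperative vs postoperative
    phase (per scan, either position), laparoscopic vs open access (per
    patient, either position).  Strata with no scans yield NA rows.
    """
    rows: List[dict] = []

    try:
        rows.append(
            _rate_row(
                "position",
                "supine",
                detection_rate(scans, "supine"),
                "rld",
                detection_rate(scans, "rld"),
            )
        )
    except DomainError:
        rows.append({"comparison": "position"})

    try:
        pre = detection_rate(scans, "either", where=lambda s, p: s.phase is Phase.preoperative)
        post = detection_rate(scans, "either", where=lambda s, p: s.phase is Phase.postoperative)
        rows.append(_rate_row("phase", "preoperative", pre, "postoperative", post))
    except DomainError:
        rows.append({"comparison": "phase"})

    try:
        lap = detection_rate(
            scans,
            "either",
            patients=patients,
            where=lambda s, p: p is not None and p.surgical_access is SurgicalAccess.laparoscopic,
            unit="patient",
        )
        opn = detection_rate(
            scans,
            "either",
            patients=patients,
            where=lambda s, p: p is not None and p.surgical_access is SurgicalAccess.open,
            unit="patient",
        )
        rows.append(_rate_row("access", "laparoscopic", lap, "open", opn))
    except DomainError:
        rows.append({"comparison": "access"})

    return pd.DataFrame(rows)


def csa_phase_comparison(
    scans: Sequence[ScanRecord], source: str = "calculated", position: str = "rld"
) -> pd.DataFrame:
    """Pre- vs postoperative CSA descriptives with a Student t-test."""
    pre = [
        v
        for s in scans
        if s.phase is Phase.preoperative and (v := scan_csa(s, source, position)) is not None
    ]
    post = [
        v
        for s in scans
        if s.phase is Phase.postoperative and (v := scan_csa(s, source, position)) is not None
    ]
    rows = []
    for phase, vals in (("preoperative", pre), ("postoperative", post)):
        if vals:
            d = descriptive_summary(vals)
            rows.append(
                {
                    "phase": phase,
                    "source": source,
                    "position": position,
                    "n": d.n,
                    "mean": d.mean,
                    "sd": d.sd,
                    "median": d.median,
                    "iqr": d.iqr,
                }
            )
        else:
            rows.append({"phase": phase, "source": source, "position": position, "n": 0})
    frame = pd.DataFrame(rows)
    if len(pre) >= 2 and len(post) >= 2:
        test = student_t_two_sample(pre, post)
        frame["t_statistic"] = test.statistic
        frame["p_value"] = test.p_value
    return frame
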