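"""Quantitative antral metrics: ellipse CSA and the Perlas volume model.

The antral cross-sectional area (CSA) is obtained either directly, by tracing
the antrum on the machine ("measured"), or indirectly from two perpendicular
diameters via the area of an ellipse ("calculated"):

    CSA [cm^2] = (AP diameter / 10) * (CC diameter / 10) * pi / 4

with diameters recorded in mm.  The predicted gastric volume uses the
age-adjusted linear model fitted on right-lateral-decubitus (RLD) CSA:

    Volume [mL] = 27.0 + 14.6 * CSA_RLD - 1.28 * age

The model can return negative values for small antra in older patients; a
negative prediction is clamped to 0 mL and flagged, since a gastric volume
cannot be negative.  Supine CSA is never substituted for RLD CSA: when the
RLD area is unavailable the volume is simply unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .records import DomainError, PositionMeasurement, ScanRecord

#: Coefficients of the predicted-gastric-volume model (mL, mL/cm^2, mL/year).
VOLUME_INTERCEPT_ML = 27.0
VOLUME_SLOPE_ML_PER_CM2 = 14.6
VOLUME_SLOPE_ML_PER_YEAR = 1.28

#: Predicted volume per body weight above which a subject is high risk (mL/kg).
RISK_THRESHOLD_ML_PER_KG = 1.5


@dataclass(frozen=True)
class VolumeEstimate:
    """A predicted gastric volume, optionally normalized by body weight."""

    volume_ml: float
    volume_ml_per_kg: Optional[float] = None
    clamped: bool = False


def _require_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise DomainError(f"{name} must be finite and >= 0, got {value!r}")


def csa_from_diameters(d1_mm: float, d2_mm: float) -> float:
    """Elliptical antral CSA in cm^2 from two perpendicular diameters in mm.

    Commutative in its arguments; zero if either diameter is zero.
    """
    _require_finite_nonneg("d1_mm", d1_mm)
    _require_finite_nonneg("d2_mm", d2_mm)
    return (d1_mm / 10.0) * (d2_mm / 10.0) * math.pi / 4.0


def predicted_gastric_volume(csa_rld_cm2: float, age_years: float) -> VolumeEstimate:
    """Predicted gastric volume (mL) from RLD CSA (cm^2) and age (years).

    The raw linear prediction is clamped at 0 mL; ``clamped`` records whether
    clamping occurred.  Weight normalization is left to
    :func:`volume_per_kg` / :func:`estimate_volume`.
    """
    _require_finite_nonneg("csa_rld_cm2", csa_rld_cm2)
    _require_finite_nonneg("age_years", age_years)
    raw = (
        VOLUME_INTERCEPT_ML
        + VOLUME_SLOPE_ML_PER_CM2 * csa_rld_cm2
        - VOLUME_SLOPE_ML_PER_YEAR * age_years
    )
    if raw < 0:
        return VolumeEstimate(volume_ml=0.0, clamped=True)
    return VolumeEstimate(volume_ml=raw, clamped=False)


def volume_per_kg(volume_ml: float, weight_kg: float) -> float:
    """Weight-normalized gastric volume in mL/kg (risk threshold is 1.5)."""
    _require_finite_nonneg("volume_ml", volume_ml)
    if weight_kg is None or not math.isfinite(weight_kg) or weight_kg <= 0:
        raise DomainError(
            f"weight_kg must be a positive number to normalize volume, got {weight_kg!r}; "
            "the mL/kg branch of the risk rule cannot be evaluated"
        )
    return volume_ml / weight_kg


def estimate_volume(
    csa_rld_cm2: float, age_years: float, weight_kg: Optional[float] = None
) -> VolumeEstimate:
    """Predicted volume with mL/kg filled in when weight is known."""
    est = predicted_gastric_volume(csa_rld_cm2, age_years)
    if weight_kg is None:
        return est
    return VolumeEstimate(
        volume_ml=est.volume_ml,
        volume_ml_per_kg=volume_per_kg(est.volume_ml, weight_kg),
        clamped=est.clamped,
    )


def available_csa(measurement: PositionMeasurement) -> Optional[float]:
    """Best available CSA for one position: traced area, else the ellipse
    area from the two diameters, else ``None``."""
    if measurement.csa_traced_cm2 is not None:
        return measurement.csa_traced_cm2
    if measurement.d1_mm is not None and measurement.d2_mm is not None:
        return csa_from_diameters(measurement.d1_mm, measurement.d2_mm)
    return None


def scan_csa(scan: ScanRecord, source: str = "calculated", position: str = "rld") -> Optional[float]:
    """CSA of one scan for an explicit source and position.

    ``source`` is ``"calculated"`` (ellipse from diameters) or ``"measured"``
    (machine-traced); ``None`` when the requested value was not recorded.
    """
    m = scan.position(position)
    if source == "measured":
        return m.csa_traced_cm2
    if source == "calculated":
        if m.d1_mm is None or m.d2_mm is None:
            return None
        return csa_from_diameters(m.d1_mm, m.d2_mm)
    raise DomainError(f"unknown CSA source {source!r} (expected 'calculated' or 'measured')")
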