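"""Comparison metrics between scan modes and compensating materials.

Covers the four figures of merit used to rank compensating materials:
dose-difference accuracy, sensitivity increase relative to a bare air gap,
the reflective/transmission sensitivity ratio, and scan-uniformity CV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import DoseResponseFit, sensitivity
from .errors import DomainError
from .scan_io import ROIStats

__all__ = [
    "AccuracyRecord",
    "UniformityRecord",
    "dose_difference_pct",
    "average_dose_difference",
    "sensitivity_increase_pct",
    "mode_sensitivity_ratio",
    "scan_uniformity",
]


@dataclass(frozen=True)
class AccuracyRecord:
    """One accuracy determination: delivered vs calibrated-measured dose."""

    material: str
    mode: str
    delivered_cgy: float
    measured_cgy: float
    dose_diff_pct: float


@dataclass(frozen=True)
class UniformityRecord:
    """Scan-uniformity CV for one material in one scan mode."""

    material: str
    mode: str
    cv: float


def dose_difference_pct(measured_cgy: float, delivered_cgy: float) -> float:
    """Absolute dose difference relative to the delivered dose, in percent."""
    if delivered_cgy <= 0:
        raise DomainError("delivered dose must be positive")
    return abs(measured_cgy - delivered_cgy) / delivered_cgy * 100.0


def average_dose_difference(records: list[AccuracyRecord], material: str) -> float:
    """Mean dose difference (%) for one material over all modes and doses."""
    diffs = [r.dose_diff_pct for r in records if r.material == material]
    if not diffs:
        raise DomainError(f"no accuracy records for material {material!r}")
    return float(np.mean(diffs))


def sensitivity_increase_pct(
    fit_material: DoseResponseFit, fit_air: DoseResponseFit, dose_gy: float
) -> float:
    """Percent sensitivity change of a material relative to air at one dose.

    (S_material - S_air) / S_air * 100; negative when the material couples
    light worse than a bare gap.
    """
    s_air = sensitivity(fit_air, dose_gy)
    if s_air == 0:
        raise DomainError("air sensitivity is zero; increase undefined")
    s_mat = sensitivity(fit_material, dose_gy)
    return (s_mat - s_air) / s_air * 100.0


def mode_sensitivity_ratio(
    fit_reflective: DoseResponseFit,
    fit_transmission: DoseResponseFit,
    doses_gy,
) -> float:
    """Mean reflective/transmission sensitivity ratio over a dose grid.

    Grid points where the transmission sensitivity vanishes are excluded
    with a warning.
    """
    d = np.asarray(doses_gy, dtype=float)
    if d.size == 0:
        raise DomainError("dose grid must not be empty")
    s_r = np.atleast_1d(sensitivity(fit_reflective, d))
    s_t = np.atleast_1d(sensitivity(fit_transmission, d))
    ok = s_t != 0
    if not np.all(ok):
        warnings.warn(
            "transmission sensitivity zero at some grid points; excluded",
            stacklevel=2,
        )
    if not np.any(ok):
        raise DomainError("no valid grid points for the sensitivity ratio")
    return float(np.mean(s_r[ok] / s_t[ok]))


def scan_uniformity(
    stats: ROIStats, material: str = "", mode: str = ""
) -> UniformityRecord:
    """Uniformity CV of an ROI (SD over mean of its pixel counts)."""
    if stats.mean <= 0:
        raise DomainError("uniformity CV undefined for non-positive ROI mean")
    return UniformityRecord(material=material, mode=mode, cv=stats.sd / stats.mean)
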