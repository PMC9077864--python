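"""Decomposition of the relative dose uncertainty (Devic-style budget).

For a calibrated dose D_fit = b*netOD + c*netOD^n (the calibration-curve
parameters named b and c here, as is conventional in the uncertainty
formulas), the relative uncertainty of a measured dose splits into

* experimental (scan-noise) part:
    sigma_Dexp(%) = |b + n*c*netOD^(n-1)| * sigma_netOD / D_fit * 100
* fit (parameter-uncertainty) part:
    sigma_Dfit(%) = sqrt(netOD^2 * sigma_b^2 + netOD^(2n) * sigma_c^2)
                    / D_fit * 100
* total: the quadrature sum of the two.

The fit part deliberately omits the exponent's uncertainty and the b-c
covariance — the standard published form; ``extended=True`` adds both for
comparison. Percentages are returned at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationFit, apply_calibration
from .errors import DomainError

__all__ = [
    "UncertaintyBudget",
    "experimental_uncertainty",
    "fit_uncertainty",
    "total_uncertainty",
]


@dataclass(frozen=True)
class UncertaintyBudget:
    """Relative dose uncertainty (%) split into its two components."""

    sigma_exp_pct: float
    sigma_fit_pct: float
    sigma_tot_pct: float
    at_netod: float
    at_dose_gy: float

    def __post_init__(self) -> None:
        quad = np.hypot(self.sigma_exp_pct, self.sigma_fit_pct)
        if quad > 0 and abs(self.sigma_tot_pct - quad) > 1e-9 * quad:
            raise DomainError("total uncertainty violates the quadrature identity")


def _dose_and_slope(fit: CalibrationFit, netod: float) -> tuple[float, float]:
    if netod <= 0:
        raise DomainError(
            "uncertainty undefined at netOD <= 0 (calibrated dose is 0)"
        )
    d_fit = apply_calibration(fit, netod)
    if d_fit <= 0:
        raise DomainError("calibrated dose must be positive")
    slope = fit.lin_coeff + fit.exponent * fit.pow_coeff * netod ** (
        fit.exponent - 1.0
    )
    return d_fit, slope


def experimental_uncertainty(
    fit: CalibrationFit, netod: float, sigma_netod: float
) -> float:
    """Relative experimental (scan-noise) dose uncertainty in percent."""
    if sigma_netod < 0:
        raise DomainError("sigma_netod must be >= 0")
    d_fit, slope = _dose_and_slope(fit, netod)
    return abs(slope) * sigma_netod / d_fit * 100.0


def fit_uncertainty(
    fit: CalibrationFit, netod: float, *, extended: bool = False
) -> float:
    """Relative fit (calibration-parameter) dose uncertainty in percent.

    Default form uses only sigma_b and sigma_c; ``extended=True`` also
    propagates the b-c covariance and the exponent's uncertainty.
    """
    d_fit, _ = _dose_and_slope(fit, netod)
    n = fit.exponent
    var = netod**2 * fit.sigma_lin**2 + netod ** (2.0 * n) * fit.sigma_pow**2
    if extended:
        var += 2.0 * netod ** (n + 1.0) * float(fit.covariance[0, 1])
        dn = fit.pow_coeff * netod**n * np.log(netod)
        var += dn**2 * fit.sigma_exponent**2
    var = max(var, 0.0)
    return float(np.sqrt(var)) / d_fit * 100.0


def total_uncertainty(
    fit: CalibrationFit,
    netod: float,
    sigma_netod: float,
    *,
    extended: bool = False,
) -> UncertaintyBudget:
    """Total relative dose uncertainty: the single-radical form, identical to
    the quadrature sum of the experimental and fit components."""
    s_exp = experimental_uncertainty(fit, netod, sigma_netod)
    s_fit = fit_uncertainty(fit, netod, extended=extended)
    d_fit, slope = _dose_and_slope(fit, netod)
    n = fit.exponent
    var = (
        netod**2 * fit.sigma_lin**2
        + netod ** (2.0 * n) * fit.sigma_pow**2
        + slope**2 * sigma_netod**2
    )
    if extended:
        var += 2.0 * netod ** (n + 1.0) * float(fit.covariance[0, 1])
        dn = fit.pow_coeff * netod**n * np.log(netod)
        var += dn**2 * fit.sigma_exponent**2
    s_tot = float(np.sqrt(max(var, 0.0))) / d_fit * 100.0
    return UncertaintyBudget(
        sigma_exp_pct=s_exp,
        sigma_fit_pct=s_fit,
        sigma_tot_pct=s_tot,
        at_netod=netod,
        at_dose_gy=d_fit,
    )
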