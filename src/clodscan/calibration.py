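"""Power-law dose-response and calibration fits, and analytic sensitivity.

Two fits share one functional family:

* dose-response:  netOD = a*D + b*D**n        (D in Gy)
* calibration:    D     = a*netOD + b*netOD**n

both through the origin by construction. Sensitivity is the analytic
derivative of the dose-response curve,

    S(D) = d netOD / dD = a + n*b*D**(n-1)

Fitting is unweighted nonlinear least squares by default (1/sigma^2
weighting behind ``weighted=True``); parameter SDs come from the covariance
of the fit and goodness of fit is the adjusted R^2 with p = 3 parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError

__all__ = [
    "DoseResponseFit",
    "CalibrationFit",
    "fit_dose_response",
    "fit_calibration",
    "sensitivity",
    "apply_calibration",
]

_N_BOUNDS = (0.2, 5.0)


def _power_law(x, a, b, n):
    return a * x + b * np.power(x, n)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted netOD = a*D + b*D^n with parameter uncertainties."""

    lin_coeff: float          # a, netOD/Gy
    pow_coeff: float          # b, netOD/Gy^n
    exponent: float           # n
    param_sds: np.ndarray     # SDs of (a, b, n)
    covariance: np.ndarray    # 3x3 parameter covariance
    adj_r2: float
    n_points: int
    dose_range_gy: tuple[float, float]
    n_at_bound: bool = False

    def predict(self, dose_gy):
        d = np.asarray(dose_gy, dtype=float)
        if np.any(d < 0):
            raise DomainError("dose must be >= 0")
        out = _power_law(d, self.lin_coeff, self.pow_coeff, self.exponent)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted D = a*netOD + b*netOD^n (the inverse, dose-from-density curve).

    In the uncertainty decomposition these parameters and their SDs appear as
    (b, sigma_b) for the linear and (c, sigma_c) for the power coefficient.
    """

    lin_coeff: float          # Gy/netOD
    pow_coeff: float          # Gy/netOD^n
    exponent: float
    sigma_lin: float
    sigma_pow: float
    sigma_exponent: float
    covariance: np.ndarray
    adj_r2: float
    n_points: int
    netod_range: tuple[float, float]
    n_at_bound: bool = False


def _initial_guess(x, y):
    """Heuristic start: slope from the two lowest positive x, residual power."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = x > 0
    xs = x[pos]
    ys = y[pos]
    order = np.argsort(xs)
    lo = order[: min(2, xs.size)]
    a0 = float(np.mean(ys[lo] / xs[lo])) if lo.size else 1.0
    n0 = 1.5
    i_hi = order[-1]
    resid = ys[i_hi] - a0 * xs[i_hi]
    b0 = float(resid / xs[i_hi] ** n0) if xs[i_hi] > 0 else 0.0
    return a0, b0, n0


def _fit_power_law(x, y, sigmas, weighted):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 4:
        raise DomainError("need at least 4 points for a 3-parameter fit")
    if np.unique(x[x > 0]).size < 3:
        raise DomainError("need at least 3 distinct positive abscissae")
    sigma = None
    if weighted:
        if sigmas is None:
            raise DomainError("weighted fit requires sigmas")
        sigma = np.asarray(sigmas, dtype=float)
        sigma = np.where(sigma > 0, sigma, np.nanmin(sigma[sigma > 0]))
    p0 = _initial_guess(x, y)
    p0 = (p0[0], p0[1], np.clip(p0[2], *_N_BOUNDS))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _power_law,
                x,
                y,
                p0=p0,
                sigma=sigma,
                bounds=([-np.inf, -np.inf, _N_BOUNDS[0]], [np.inf, np.inf, _N_BOUNDS[1]]),
                maxfev=20000,
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"power-law fit failed to converge: {exc}") from exc
    n_at_bound = bool(
        np.isclose(popt[2], _N_BOUNDS[0]) or np.isclose(popt[2], _N_BOUNDS[1])
    )
    if n_at_bound:
        warnings.warn("fitted exponent hit its bound", stacklevel=3)
    resid = y - _power_law(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n_pts = x.size
    adj_r2 = (
        1.0 - (1.0 - r2) * (n_pts - 1) / (n_pts - 4) if n_pts > 4 else r2
    )
    sds = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return popt, sds, pcov, adj_r2, n_pts, n_at_bound


def fit_dose_response(
    doses_gy, netods, sigmas=None, *, weighted: bool = False
) -> DoseResponseFit:
    """Fit netOD = a*D + b*D^n by nonlinear least squares.

    Points at D = 0 (netOD 0 by construction) are included; the curve passes
    through the origin exactly. ``weighted=True`` applies 1/sigma^2 weights.
    The fit is invariant to the ordering of the points.
    """
    popt, sds, pcov, adj_r2, n_pts, at_bound = _fit_power_law(
        doses_gy, netods, sigmas, weighted
    )
    d = np.asarray(doses_gy, dtype=float)
    return DoseResponseFit(
        lin_coeff=float(popt[0]),
        pow_coeff=float(popt[1]),
        exponent=float(popt[2]),
        param_sds=sds,
        covariance=pcov,
        adj_r2=float(adj_r2),
        n_points=n_pts,
        dose_range_gy=(float(d.min()), float(d.max())),
        n_at_bound=at_bound,
    )


def fit_calibration(
    netods, doses_gy, sigmas=None, *, weighted: bool = False
) -> CalibrationFit:
    """Fit the inverse curve D = a*netOD + b*netOD^n (dose as the dependent
    variable), used to convert measured netOD of an unknown exposure to Gy.

    Slightly negative netOD values (zero-dose scan noise) are clamped to the
    origin with a warning; values below -0.02 indicate a data problem and
    are rejected.
    """
    x = np.asarray(netods, dtype=float)
    if np.any(x < -0.02):
        raise DomainError("netOD below -0.02; check the scan pairing")
    if np.any(x < 0):
        warnings.warn(
            "clamping slightly negative netOD values to 0 for the fit",
            stacklevel=2,
        )
        x = np.clip(x, 0.0, None)
    popt, sds, pcov, adj_r2, n_pts, at_bound = _fit_power_law(
        x, doses_gy, sigmas, weighted
    )
    return CalibrationFit(
        lin_coeff=float(popt[0]),
        pow_coeff=float(popt[1]),
        exponent=float(popt[2]),
        sigma_lin=float(sds[0]),
        sigma_pow=float(sds[1]),
        sigma_exponent=float(sds[2]),
        covariance=pcov,
        adj_r2=float(adj_r2),
        n_points=n_pts,
        netod_range=(float(x.min()), float(x.max())),
        n_at_bound=at_bound,
    )


def sensitivity(fit: DoseResponseFit, dose_gy):
    """Analytic sensitivity S(D) = a + n*b*D^(n-1) in netOD/Gy.

    For n < 1 the derivative diverges at D = 0; that case returns +inf with
    a warning rather than raising.
    """
    d = np.asarray(dose_gy, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be >= 0")
    a, b, n = fit.lin_coeff, fit.pow_coeff, fit.exponent
    with np.errstate(divide="ignore"):
        out = a + n * b * np.power(d, n - 1.0)
    if n < 1 and np.any(d == 0):
        warnings.warn("sensitivity diverges at D = 0 for n < 1", stacklevel=2)
    return out if out.ndim else float(out)


def apply_calibration(fit: CalibrationFit, netod):
    """Convert measured netOD to dose (Gy) through the calibration curve.

    Values above the calibrated netOD range produce an extrapolation warning.
    """
    x = np.asarray(netod, dtype=float)
    if np.any(x < 0):
        raise DomainError("netOD must be >= 0")
    if np.any(x > fit.netod_range[1]):
        warnings.warn(
            "netOD above the calibrated range; extrapolating", stacklevel=2
        )
    out = _power_law(x, fit.lin_coeff, fit.pow_coeff, fit.exponent)
    return out if out.ndim else float(out)
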