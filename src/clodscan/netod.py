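"""Net optical density from pixel statistics, with propagated uncertainty.

netOD measures the radiation-induced darkening of the dosimeter:

    netOD = log10( (M_unexp - M_bkg) / (M_exp - M_bkg) )

where M_unexp, M_exp are the mean pixel values before and after irradiation
and M_bkg is the empty-bed value. With this (Devic-protocol) orientation a
darkening dosimeter yields netOD >= 0. The reversed orientation, with the
exposed value in the numerator, is occasionally seen in print and produces
negative values; it is available behind ``literal_sign=True`` for audit.

The uncertainty of a netOD value follows from first-order propagation of the
three pixel-value SDs:

    sigma_netOD = (1/ln 10) * sqrt( (sd_exp^2 + sd_bkg^2)/(M_exp - M_bkg)^2
                                  + (sd_unexp^2 + sd_bkg^2)/(M_unexp - M_bkg)^2 )
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SignalBelowBackgroundError
from .scan_io import ROIStats

__all__ = [
    "ODMeasurement",
    "compute_netod",
    "netod_sigma",
    "netod_sigma_mc",
]

_LN10 = np.log(10.0)


def compute_netod(
    m_unexp,
    m_exp,
    m_bkg=0.0,
    *,
    literal_sign: bool = False,
    strict: bool = False,
):
    """netOD of one measurement (scalars or broadcastable arrays).

    Raises :class:`SignalBelowBackgroundError` if either signal is at or
    below background. An exposed value brighter than the unexposed one
    (negative netOD) triggers a warning, or an error when ``strict=True``.
    """
    mu = np.asarray(m_unexp, dtype=float)
    me = np.asarray(m_exp, dtype=float)
    mb = np.asarray(m_bkg, dtype=float)
    if np.any(mu <= mb) or np.any(me <= mb):
        raise SignalBelowBackgroundError(
            "pixel value at or below background; cannot form netOD"
        )
    if np.any(me > mu):
        if strict:
            raise DomainError("exposed brighter than unexposed (negative netOD)")
        warnings.warn(
            "exposed pixel value exceeds unexposed; netOD will be negative",
            stacklevel=2,
        )
    out = np.log10((mu - mb) / (me - mb))
    if literal_sign:
        out = -out
    return out if out.ndim else float(out)


def netod_sigma(
    m_unexp, m_exp, m_bkg, sd_unexp, sd_exp, sd_bkg
):
    """First-order propagated SD of netOD from the three pixel-value SDs."""
    mu = np.asarray(m_unexp, dtype=float)
    me = np.asarray(m_exp, dtype=float)
    mb = np.asarray(m_bkg, dtype=float)
    if np.any(mu <= mb) or np.any(me <= mb):
        raise SignalBelowBackgroundError("signal at or below background")
    su = np.asarray(sd_unexp, dtype=float)
    se = np.asarray(sd_exp, dtype=float)
    sb = np.asarray(sd_bkg, dtype=float)
    if np.any(su < 0) or np.any(se < 0) or np.any(sb < 0):
        raise DomainError("SDs must be >= 0")
    out = (1.0 / _LN10) * np.sqrt(
        (se**2 + sb**2) / (me - mb) ** 2 + (su**2 + sb**2) / (mu - mb) ** 2
    )
    return out if out.ndim else float(out)


def netod_sigma_mc(
    m_unexp,
    m_exp,
    m_bkg,
    sd_unexp,
    sd_exp,
    sd_bkg,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo netOD SD: verification mode for :func:`netod_sigma`.

    Resamples the three pixel values from Gaussians and takes the SD of the
    recomputed netOD. Not the default propagation path.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    mu = rng.normal(m_unexp, sd_unexp, n_draws)
    me = rng.normal(m_exp, sd_exp, n_draws)
    mb = rng.normal(m_bkg, sd_bkg, n_draws)
    vals = np.log10((mu - mb) / (me - mb))
    return float(np.std(vals, ddof=1))


@dataclass(frozen=True)
class ODMeasurement:
    """One netOD determination: the pixel-value triple and derived quantities."""

    m_unexp: float
    m_exp: float
    m_bkg: float
    sd_unexp: float
    sd_exp: float
    sd_bkg: float
    netod: float
    sigma_netod: float

    @classmethod
    def from_roi_stats(
        cls,
        unexposed: ROIStats,
        exposed: ROIStats,
        background: ROIStats | None = None,
        *,
        literal_sign: bool = False,
        strict: bool = False,
    ) -> "ODMeasurement":
        """Build a measurement from unexposed/exposed/background ROI stats.

        When no empty-bed ROI is available the background defaults to zero
        counts with zero SD (a warning is emitted).
        """
        if background is None:
            warnings.warn(
                "no background ROI supplied; assuming M_bkg = 0", stacklevel=2
            )
            background = ROIStats(mean=0.0, sd=0.0, n_pixels=1, cv=float("nan"))
        netod = compute_netod(
            unexposed.mean,
            exposed.mean,
            background.mean,
            literal_sign=literal_sign,
            strict=strict,
        )
        sigma = netod_sigma(
            unexposed.mean,
            exposed.mean,
            background.mean,
            unexposed.sd,
            exposed.sd,
            background.sd,
        )
        return cls(
            m_unexp=unexposed.mean,
            m_exp=exposed.mean,
            m_bkg=background.mean,
            sd_unexp=unexposed.sd,
            sd_exp=exposed.sd,
            sd_bkg=background.sd,
            netod=netod,
            sigma_netod=sigma,
        )
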