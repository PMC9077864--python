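"""Synthetic flatbed-scanner images of curved contact-lens dosimeters (CLODs).

A CLOD is a curved radiochromic dosimeter worn on the eye. Scanned on a
flatbed scanner it darkens with dose like a Gafchromic film, but its curvature
leaves a thin air gap between the scanner glass and the active layer, so the
scan carries Newton's-ring interference fringes. Spreading an index-matching
compensating material (optical grease, soft silicones) in the gap suppresses
the fringes.

This module renders such scans from first principles so the whole analysis
chain (ROI statistics, netOD, calibration fits, uncertainty budgets, accuracy
and uniformity metrics) can be tested without physical scans:

* dose -> clean pixel value through the forward power-law response
  ``netOD = g * (a*D + b*D**n)`` (g is the reflective-mode gain),
* a sphere-on-flat gap profile ``t(r) = r**2 / (2*R)``,
* two-interface Fresnel reflectances -> fringe visibility,
* reflected-light ring modulation ``1 - V*cos(4*pi*n_gap*t/lambda)`` with the
  classic dark contact spot at t = 0,
* per-material additive Gaussian pixel noise on a 16-bit count scale.

Optical constants and lens geometry are simulator parameters with plausible
defaults; they are not measured properties of any physical device.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, LayoutError
from .scan_io import ScanImage

__all__ = [
    "LensGeometry",
    "MaterialSpec",
    "ScanConfig",
    "GroundTruthResponse",
    "MATERIAL_REFRACTIVE_INDEX",
    "MATERIAL_PIXEL_NOISE_SD",
    "default_material",
    "air_gap_profile",
    "fringe_visibility",
    "ring_modulation",
    "dark_ring_radius",
    "dose_to_clean_pixel",
    "render_scan",
]

#: Refractive indices of the compensating materials filling the glass-lens gap.
#: Plausible values for air, Dragon Skin 10 (DS), SORTA-Clear 40 (SC) and
#: BC-630 optical grease (OG); configurable, not measured.
MATERIAL_REFRACTIVE_INDEX: dict[str, float] = {
    "air": 1.0,
    "DS": 1.40,
    "SC": 1.41,
    "OG": 1.46,
}

#: Default per-material additive pixel-noise SD (16-bit counts), keyed by scan
#: mode. Scale anchored to reported ROI pixel-value SDs at 25 cGy.
MATERIAL_PIXEL_NOISE_SD: dict[str, dict[str, float]] = {
    "transmission": {"air": 766.3, "DS": 696.5, "SC": 695.0, "OG": 611.9},
    "reflective": {"air": 577.1, "DS": 495.9, "SC": 492.9, "OG": 373.3},
}

_MODES = ("transmission", "reflective")


@dataclass(frozen=True)
class LensGeometry:
    """Geometry of one rendered CLOD footprint.

    Parameters
    ----------
    base_curve_radius_mm
        Effective radius of curvature of the residual glass-lens gap. A
        contact lens has an anatomical base curve of ~8 mm, but pressed flat
        on the scanner glass the soft lens deforms elastically and the
        remaining wedge is far shallower; the default of 4000 mm puts about
        a dozen rings across a 6 mm-radius footprint at 0.3-0.7 mm spacing,
        the scale seen in real scans (an 8 mm gap radius would put every
        fringe below one 300-dpi pixel).
    contact_radius_mm
        Radial extent of the rendered footprint on the bed.
    center_mm
        Optional (x, y) position on the scan bed; when None the renderer
        lays footprints out automatically.
    """

    base_curve_radius_mm: float = 4000.0
    contact_radius_mm: float = 6.0
    center_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.base_curve_radius_mm <= 0:
            raise DomainError("base_curve_radius_mm must be positive")
        if self.contact_radius_mm <= 0:
            raise DomainError("contact_radius_mm must be positive")
        if self.contact_radius_mm > self.base_curve_radius_mm:
            raise DomainError(
                "contact_radius_mm cannot exceed base_curve_radius_mm"
            )


@dataclass(frozen=True)
class MaterialSpec:
    """A compensating material filling the glass-lens gap.

    ``response_gain`` is an optional multiplier on the true dose response
    (default 1.0: the material changes optical coupling, not the dosimeter
    chemistry); it lets simulations explore material-dependent sensitivity.
    """

    name: str
    refractive_index: float
    pixel_noise_sd: float
    response_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise DomainError("refractive_index must be >= 1")
        if self.pixel_noise_sd < 0:
            raise DomainError("pixel_noise_sd must be >= 0")
        if self.response_gain <= 0:
            raise DomainError("response_gain must be positive")


def default_material(name: str, mode: str = "transmission") -> MaterialSpec:
    """Return the built-in spec for ``name`` ('air', 'DS', 'SC' or 'OG').

    The noise SD depends on the scan mode (reflective scans are quieter).
    """
    if mode not in _MODES:
        raise DomainError(f"unknown scan mode {mode!r}")
    try:
        return MaterialSpec(
            name=name,
            refractive_index=MATERIAL_REFRACTIVE_INDEX[name],
            pixel_noise_sd=MATERIAL_PIXEL_NOISE_SD[mode][name],
        )
    except KeyError:
        raise DomainError(
            f"unknown material {name!r}; built-ins are air, DS, SC, OG"
        ) from None


@dataclass(frozen=True)
class ScanConfig:
    """Scanner acquisition settings for a rendered scan."""

    mode: str = "transmission"
    dpi: float = 300.0
    bit_depth: int = 16
    wavelength_nm: float = 630.0  # effective red-channel illumination
    seed: int = 0
    n_glass: float = 1.52
    n_lens: float = 1.50

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise DomainError(f"unknown scan mode {self.mode!r}")
        if self.dpi <= 0:
            raise DomainError("dpi must be positive")
        if self.bit_depth not in (8, 16):
            raise DomainError("bit_depth must be 8 or 16")
        if self.wavelength_nm <= 0:
            raise DomainError("wavelength_nm must be positive")


@dataclass(frozen=True)
class GroundTruthResponse:
    """True power-law dose response behind a simulation.

    netOD(D) = gain * (a*D + b*D**n) with D in Gy; ``mode_gain`` multiplies
    the response in reflective mode (default 2.5, the reflective/transmission
    sensitivity ratio of red-channel film scanning at low dose).
    """

    lin_coeff: float = 0.3   # a, netOD/Gy
    pow_coeff: float = 0.1   # b, netOD/Gy^n
    exponent: float = 1.8    # n
    mode_gain: float = 2.5

    def __post_init__(self) -> None:
        if self.lin_coeff < 0 or self.pow_coeff < 0:
            raise DomainError("response coefficients must be >= 0")
        if self.exponent <= 0:
            raise DomainError("exponent must be positive")
        if self.mode_gain <= 0:
            raise DomainError("mode_gain must be positive")

    def true_netod(
        self, dose_gy, mode: str = "transmission", response_gain: float = 1.0
    ):
        """True netOD at ``dose_gy`` (scalar or array) for a scan mode."""
        dose = np.asarray(dose_gy, dtype=float)
        if np.any(dose < 0):
            raise DomainError("dose must be >= 0")
        gain = self.mode_gain if mode == "reflective" else 1.0
        out = gain * response_gain * (
            self.lin_coeff * dose + self.pow_coeff * dose**self.exponent
        )
        return out if out.ndim else float(out)


def air_gap_profile(r_mm, geometry: LensGeometry):
    """Gap thickness t(r) in micrometres under a sphere-on-flat contact.

    Small-angle approximation t = r^2 / (2 R): exact contact at the apex,
    growing quadratically outward. ``r_mm`` may be scalar or array.
    """
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0) or np.any(r > geometry.contact_radius_mm):
        raise DomainError("r must lie in [0, contact_radius_mm]")
    t_mm = r**2 / (2.0 * geometry.base_curve_radius_mm)
    t_um = t_mm * 1000.0
    return t_um if t_um.ndim else float(t_um)


#: Normalization constant in the visibility formula. Chosen so an air gap
#: between glass (n=1.52) and lens (n=1.50) gives V ~ 0.45 (strong rings)
#: while index-matched media give V < 0.01.
_VISIBILITY_EPS = 0.1


def fringe_visibility(
    material: MaterialSpec, n_glass: float = 1.52, n_lens: float = 1.50
) -> float:
    """Fringe visibility V in [0, 1) of the thin-gap interference pattern.

    Normal-incidence Fresnel intensity reflectances of the glass/gap and
    gap/lens interfaces, R_i = ((n_i - n_gap)/(n_i + n_gap))^2, combined as

        V = 2 sqrt(R1 R2) / (R1 + R2 + eps)

    The eps term regularizes the two-beam visibility so that V -> 0 as both
    reflectances vanish (perfect index match) instead of staying near 1.
    V is symmetric in the two interfaces.
    """
    n_gap = material.refractive_index
    if min(n_gap, n_glass, n_lens) < 1.0:
        raise DomainError("refractive indices must be >= 1")
    r1 = ((n_glass - n_gap) / (n_glass + n_gap)) ** 2
    r2 = ((n_lens - n_gap) / (n_lens + n_gap)) ** 2
    return float(2.0 * np.sqrt(r1 * r2) / (r1 + r2 + _VISIBILITY_EPS))


def ring_modulation(t_um, n_gap: float, wavelength_nm: float, visibility: float):
    """Multiplicative Newton's-ring intensity factor for gap thickness t.

    Reflected-light law with the half-wave phase shift at the denser
    interface: factor = 1 - V cos(4 pi n_gap t / lambda). At t = 0 the factor
    is 1 - V (the classic dark contact spot); dark fringes sit at
    t_m = m lambda / (2 n_gap).
    """
    if not 0.0 <= visibility <= 1.0:
        raise DomainError("visibility must lie in [0, 1]")
    t = np.asarray(t_um, dtype=float)
    if np.any(t < 0):
        raise DomainError("gap thickness must be >= 0")
    phase = 4.0 * np.pi * n_gap * (t * 1000.0) / wavelength_nm
    out = 1.0 - visibility * np.cos(phase)
    return out if out.ndim else float(out)


def dark_ring_radius(
    m: int, wavelength_nm: float, geometry: LensGeometry, n_gap: float = 1.0
) -> float:
    """Radius (mm) of the m-th dark ring, r_m = sqrt(m lambda R / n_gap)."""
    if m < 1:
        raise DomainError("ring order m must be >= 1")
    lam_mm = wavelength_nm * 1e-6
    return float(
        np.sqrt(m * lam_mm * geometry.base_curve_radius_mm / n_gap)
    )


def dose_to_clean_pixel(
    dose_gy,
    truth: GroundTruthResponse,
    mode: str = "transmission",
    base_level: float = 40000.0,
    background_level: float = 1000.0,
    response_gain: float = 1.0,
):
    """Noise- and artifact-free pixel value of an exposed footprint.

    Inverts the netOD definition: with true netOD* = g (a D + b D^n),

        M_exp = M_bkg + (M_unexp - M_bkg) * 10**(-netOD*)

    so that measuring netOD from the rendered pixel recovers netOD* exactly.
    """
    if base_level <= background_level or background_level < 0:
        raise DomainError("require base_level > background_level >= 0")
    netod = truth.true_netod(dose_gy, mode=mode, response_gain=response_gain)
    out = background_level + (base_level - background_level) * 10.0 ** (
        -np.asarray(netod, dtype=float)
    )
    return out if out.ndim else float(out)


def _auto_layout(n: int, geometry: LensGeometry, margin_mm: float, extra_slots: int):
    slot = 2.0 * geometry.contact_radius_mm + 2.0 * margin_mm
    y = slot / 2.0
    centers = [((i + 0.5) * slot, y) for i in range(n)]
    width_mm = (n + extra_slots) * slot
    return centers, width_mm, slot


def render_scan(
    doses_gy,
    geometry: LensGeometry,
    material: MaterialSpec,
    config: ScanConfig,
    truth: GroundTruthResponse,
    *,
    base_level: float = 40000.0,
    background_level: float = 1000.0,
    margin_mm: float = 4.0,
    placement_jitter_mm: float = 0.05,
    gap_offset_sd_um: float = 0.5,
    centers_mm: list[tuple[float, float]] | None = None,
    background_slot: bool = True,
    disable_rings: bool = False,
    disable_noise: bool = False,
) -> tuple[ScanImage, dict]:
    """Render one scan holding one CLOD footprint per dose.

    The red channel carries the dose signal: clean pixel value times the
    Newton's-ring modulation over the footprint's radial gap profile. Green
    and blue carry the unmodulated base level. Additive Gaussian noise of SD
    ``material.pixel_noise_sd`` is applied everywhere, then counts are
    clipped to the bit depth and rounded. Rendering is deterministic for a
    fixed ``config.seed``.

    Two placement-reproducibility effects are simulated per footprint: the
    optical center is jittered around its nominal position by a Gaussian of
    SD ``placement_jitter_mm`` (repositioning repeatability of a mask-held
    dosimeter), and the whole gap profile is offset by |N(0,
    ``gap_offset_sd_um``)| micrometres (the lens seats differently and the
    compensating layer re-forms on every placement; a half-wavelength offset
    re-phases every fringe, which is why the ring artifact does not cancel
    between the unexposed and exposed scans of a real dosimeter). The
    manifest records the nominal centers used for ROI placement.

    Returns
    -------
    (ScanImage, manifest)
        The manifest lists per-footprint nominal centers (mm), doses, true
        netOD values, plus the seed and levels, for downstream assertions.
    """
    doses = [float(d) for d in np.atleast_1d(np.asarray(doses_gy, dtype=float))]
    if len(doses) == 0:
        raise DomainError("dose list must not be empty")
    if any(d < 0 for d in doses):
        raise DomainError("doses must be >= 0")

    if centers_mm is None:
        centers, width_mm, slot = _auto_layout(
            len(doses), geometry, margin_mm, extra_slots=1 if background_slot else 0
        )
        height_mm = slot
        bkg_center = ((len(doses) + 0.5) * slot, slot / 2.0) if background_slot else None
    else:
        if len(centers_mm) != len(doses):
            raise LayoutError("need one center per dose")
        centers = [(float(x), float(y)) for x, y in centers_mm]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(
                    centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
                )
                if d < 2.0 * geometry.contact_radius_mm:
                    raise LayoutError(f"footprints {i} and {j} overlap")
        width_mm = max(x for x, _ in centers) + geometry.contact_radius_mm + margin_mm
        height_mm = max(y for _, y in centers) + geometry.contact_radius_mm + margin_mm
        bkg_center = None

    pitch = 25.4 / config.dpi  # mm per pixel
    n_rows = int(np.ceil(height_mm / pitch))
    n_cols = int(np.ceil(width_mm / pitch))

    rng = np.random.default_rng(config.seed)
    img = np.full((n_rows, n_cols, 3), background_level, dtype=float)

    vis = 0.0 if disable_rings else fringe_visibility(
        material, n_glass=config.n_glass, n_lens=config.n_lens
    )

    # pixel-center coordinates in mm
    row_mm = (np.arange(n_rows) + 0.5) * pitch
    col_mm = (np.arange(n_cols) + 0.5) * pitch

    footprints = []
    for dose, (cx, cy) in zip(doses, centers):
        jx, jy = (
            rng.normal(0.0, placement_jitter_mm, size=2)
            if placement_jitter_mm > 0
            else (0.0, 0.0)
        )
        ox, oy = cx + jx, cy + jy
        t_offset = (
            abs(rng.normal(0.0, gap_offset_sd_um)) if gap_offset_sd_um > 0 else 0.0
        )
        half = geometry.contact_radius_mm
        r0 = max(0, int((oy - half) / pitch) - 1)
        r1 = min(n_rows, int((oy + half) / pitch) + 2)
        c0 = max(0, int((ox - half) / pitch) - 1)
        c1 = min(n_cols, int((ox + half) / pitch) + 2)
        yy = row_mm[r0:r1, None] - oy
        xx = col_mm[None, c0:c1] - ox
        rr = np.hypot(yy, xx)
        mask = rr <= geometry.contact_radius_mm

        clean = dose_to_clean_pixel(
            dose,
            truth,
            mode=config.mode,
            base_level=base_level,
            background_level=background_level,
            response_gain=material.response_gain,
        )
        gap = air_gap_profile(rr[mask], geometry) + t_offset
        factor = ring_modulation(
            gap, material.refractive_index, config.wavelength_nm, vis
        )
        block_red = img[r0:r1, c0:c1, 0]
        block_red[mask] = clean * factor
        for ch in (1, 2):
            block = img[r0:r1, c0:c1, ch]
            block[mask] = base_level

        footprints.append(
            {
                "dose_gy": dose,
                "center_mm": [cx, cy],
                "true_netod": truth.true_netod(
                    dose, mode=config.mode, response_gain=material.response_gain
                ),
            }
        )

    if not disable_noise and material.pixel_noise_sd > 0:
        img += rng.normal(0.0, material.pixel_noise_sd, size=img.shape)

    max_count = 2**config.bit_depth - 1
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(img), 0, max_count).astype(dtype)

    manifest = {
        "mode": config.mode,
        "material": material.name,
        "dpi": config.dpi,
        "bit_depth": config.bit_depth,
        "seed": config.seed,
        "wavelength_nm": config.wavelength_nm,
        "fringe_visibility": vis,
        "base_level": base_level,
        "background_level": background_level,
        "placement_jitter_mm": placement_jitter_mm,
        "gap_offset_sd_um": gap_offset_sd_um,
        "geometry": dataclasses.asdict(geometry),
        "truth": dataclasses.asdict(truth),
        "footprints": footprints,
        "background_center_mm": list(bkg_center) if bkg_center else None,
    }
    image = ScanImage(
        pixels=pixels,
        dpi=config.dpi,
        bit_depth=config.bit_depth,
        channels=("red", "green", "blue"),
    )
    return image, manifest
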