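"""Reading, writing and ROI statistics for flatbed-scanner TIFF images.

Conventions: row-major pixel arrays, origin at the top-left, 0-based indices;
physical coordinates in mm measured from the image origin; square pixels of
25.4/dpi mm. Counts are kept as stored — no rescaling on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import BoundsError, ConfigurationError, DomainError, FormatError

__all__ = [
    "ScanImage",
    "ROISpec",
    "ROIStats",
    "read_scan",
    "write_scan",
    "extract_channel",
    "roi_window",
    "roi_stats",
]

_CHANNELS_RGB = ("red", "green", "blue")


@dataclass(frozen=True)
class ScanImage:
    """A raster of scanner counts plus the metadata needed for analysis."""

    pixels: np.ndarray  # (H, W) or (H, W, C), unsigned integer counts
    dpi: float
    bit_depth: int
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise DomainError("dpi must be positive")
        if self.pixels.max(initial=0) > 2**self.bit_depth - 1:
            raise DomainError("pixel counts exceed the stated bit depth")

    @property
    def pixel_pitch_mm(self) -> float:
        return 25.4 / self.dpi

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass(frozen=True)
class ROISpec:
    """A square readout region given in physical units.

    The default side of 3.5 mm is the standard CLOD readout window
    (about 41 x 41 pixels at 300 dpi).
    """

    center_mm: tuple[float, float]  # (x, y)
    side_mm: float = 3.5

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise DomainError("ROI side must be positive")


@dataclass(frozen=True)
class ROIStats:
    """Mean, SD (sample, N-1), pixel count and CV of counts in an ROI."""

    mean: float
    sd: float
    n_pixels: int
    cv: float


def read_scan(path, dpi: float | None = None) -> ScanImage:
    """Read a 1- or 3-channel, 8/16-bit unsigned TIFF scan.

    dpi is taken from the TIFF resolution tags; pass ``dpi=`` to override or
    to supply it when the tags are absent.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tag_dpi = None
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        unit_val = (
            getattr(unit.value, "value", unit.value) if unit is not None else 2
        )
        # unit 1 = NONE: resolution is an aspect ratio, not a physical scale
        if xres is not None and unit_val in (2, 3):
            num, den = xres.value
            if den:
                tag_dpi = num / den
                if unit_val == 3:  # pixels per cm
                    tag_dpi *= 2.54
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(f"unsupported sample format {arr.dtype}")
    if arr.ndim == 2:
        channels: tuple[str, ...] = ("gray",)
    elif arr.ndim == 3 and arr.shape[2] == 3:
        channels = _CHANNELS_RGB
    else:
        raise FormatError("expected a single-channel or RGB image")
    use_dpi = dpi if dpi is not None else tag_dpi
    if use_dpi is None or use_dpi <= 0:
        raise ConfigurationError(
            f"{path} has no resolution tag; pass dpi= explicitly"
        )
    return ScanImage(pixels=arr, dpi=use_dpi, bit_depth=bit_depth, channels=channels)


def write_scan(image: ScanImage, path, manifest: dict | None = None) -> Path:
    """Write a scan as baseline TIFF with resolution tags; optional JSON sidecar.

    The sidecar (``<path>.json`` with the suffix replaced) records the
    generator manifest so analyses can locate footprints and ground truth.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        image.pixels,
        photometric="rgb" if image.n_channels == 3 else "minisblack",
        resolution=(image.dpi, image.dpi),
        resolutionunit="INCH",
    )
    if manifest is not None:
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path


def extract_channel(image: ScanImage, channel: str = "red") -> ScanImage:
    """Return the named channel as a single-channel image, counts preserved.

    A grayscale image is returned unchanged whatever channel is asked for.
    """
    if image.pixels.ndim == 2:
        return image
    try:
        idx = image.channels.index(channel)
    except ValueError:
        raise DomainError(
            f"unknown channel {channel!r}; have {image.channels}"
        ) from None
    return ScanImage(
        pixels=image.pixels[:, :, idx],
        dpi=image.dpi,
        bit_depth=image.bit_depth,
        channels=(channel,),
    )


def roi_window(
    spec: ROISpec,
    dpi: float,
    image_shape: tuple[int, int] | None = None,
    force_side_px: int | None = None,
) -> tuple[int, int, int, int]:
    """Convert a physical ROI to an integer pixel window (row0, col0, h, w).

    The side in pixels is ``round(side_mm * dpi / 25.4)`` (3.5 mm at 300 dpi
    gives 41); pass ``force_side_px=40`` to emulate readers that truncate to
    an even 40 x 40 block. The window is centered on the pixel containing the
    center coordinate, with half-open extents.
    """
    pitch = 25.4 / dpi
    side_px = force_side_px if force_side_px is not None else int(
        round(spec.side_mm * dpi / 25.4)
    )
    if side_px < 1:
        raise DomainError("ROI smaller than one pixel")
    cx, cy = spec.center_mm
    c_col = int(np.floor(cx / pitch))
    c_row = int(np.floor(cy / pitch))
    row0 = c_row - side_px // 2
    col0 = c_col - side_px // 2
    if image_shape is not None:
        h, w = image_shape[:2]
        if row0 < 0 or col0 < 0 or row0 + side_px > h or col0 + side_px > w:
            raise BoundsError("ROI window clipped by the image edge")
    return row0, col0, side_px, side_px


def roi_stats(image, window: tuple[int, int, int, int]) -> ROIStats:
    """ROI statistics: mean, sample SD (N-1 denominator) and CV = SD/mean.

    ``image`` may be a single-channel :class:`ScanImage` or a 2-D array.
    CV is NaN when the mean is zero.
    """
    arr = image.pixels if isinstance(image, ScanImage) else np.asarray(image)
    if arr.ndim != 2:
        raise DomainError("roi_stats needs a single-channel image")
    row0, col0, h, w = window
    if h < 1 or w < 1:
        raise DomainError("empty ROI window")
    if row0 < 0 or col0 < 0 or row0 + h > arr.shape[0] or col0 + w > arr.shape[1]:
        raise BoundsError("ROI window outside the image")
    block = arr[row0 : row0 + h, col0 : col0 + w].astype(float)
    n = block.size
    mean = float(block.mean())
    sd = float(block.std(ddof=1)) if n > 1 else 0.0
    cv = sd / mean if mean > 0 else float("nan")
    return ROIStats(mean=mean, sd=sd, n_pixels=n, cv=cv)
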