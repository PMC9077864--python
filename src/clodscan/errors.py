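"""Exception hierarchy for clodscan."""


class ClodscanError(Exception):
    """Base class for all clodscan errors."""


class DomainError(ClodscanError, ValueError):
    """An argument is outside the physically meaningful domain."""


class LayoutError(ClodscanError, ValueError):
    """Rendered footprints would overlap or fall off the scan bed."""


class FormatError(ClodscanError, ValueError):
    """An image file is not in a supported format."""


class ConfigurationError(ClodscanError, ValueError):
    """Required configuration (e.g. dpi, background scan) is missing."""


class BoundsError(ClodscanError, ValueError):
    """A region of interest extends beyond the image."""


class SignalBelowBackgroundError(DomainError):
    """Pixel value at or below the empty-bed background level."""


class FitError(ClodscanError, RuntimeError):
    """Nonlinear least squares failed to converge."""
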