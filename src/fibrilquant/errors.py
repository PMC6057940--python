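"""Exception types raised across the package.

Each error is named for the contract it enforces so batch callers can
catch and log specific failure modes per image.
"""


class FibrilquantError(Exception):
    """Base class for all package errors."""


class InvalidSceneSpecError(FibrilquantError, ValueError):
    """A synthetic scene specification violates its invariants."""


class ImageReadError(FibrilquantError, IOError):
    """A TIFF file could not be read."""


class MissingPixelSizeError(FibrilquantError, ValueError):
    """No pixel size was supplied and none could be recovered from metadata."""


class ChannelError(FibrilquantError, IndexError):
    """Requested channel does not exist in the source file."""


class AnisotropicPixelError(FibrilquantError, ValueError):
    """Pixel sizes differ between axes; the image metrics assume isotropic sampling."""


class InvalidMaskError(FibrilquantError, ValueError):
    """An ROI mask is degenerate for the requested operation (e.g. all-true)."""


class EmptyRoiError(FibrilquantError, ValueError):
    """The ROI contains no pixels."""


class DegenerateTextureError(FibrilquantError, ValueError):
    """GLCM marginals have zero variance (constant texture); correlation undefined."""


class NoPairsError(FibrilquantError, ValueError):
    """A GLCM offset admits no pixel pairs in the image/ROI."""


class NoOrientedSignalError(FibrilquantError, ValueError):
    """No valid oriented pixels remain after gating/ROI restriction."""


class ImageTooSmallError(FibrilquantError, ValueError):
    """Image smaller than the minimum size an operator supports."""


class BoundaryEstimateError(FibrilquantError, ValueError):
    """A dilution-assay fit is degenerate in a way the requested operation cannot handle."""
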