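"""Calibrated image containers and TIFF I/O.

The pipeline operates on single-channel grayscale intensity fields with an
explicit physical pixel size in micrometres. Pixel coordinates are 0-based
``(row, col)``; distances are centre-to-centre in physical units. Anisotropic
pixels are rejected: all downstream metrics (orientation, GLCM offsets,
interface distances) assume isotropic sampling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage

from .errors import (
    AnisotropicPixelError,
    ChannelError,
    ImageReadError,
    InvalidMaskError,
    MissingPixelSizeError,
)

__all__ = [
    "SHGImage",
    "ImageStack",
    "RoiMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "normalize_intensity",
    "interface_band",
]


@dataclass(frozen=True)
class SHGImage:
    """A calibrated grayscale intensity field.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of non-negative, finite intensities.
    pixel_size_um : float
        Physical edge length of one (square) pixel, in micrometres.
    bit_depth_source : int
        Bit depth of the source data (8 or 16); retained for round-trip I/O.
    name : str
        Identifier used in reports and error messages.
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth_source: int = 16
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("intensities must be finite and >= 0")
        if not (self.pixel_size_um > 0):
            raise MissingPixelSizeError("pixel_size_um must be a positive real")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "SHGImage":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class ImageStack:
    """An ordered z-stack of equally shaped, equally calibrated slices."""

    slices: tuple[SHGImage, ...]
    depth_step_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("stack must contain at least one slice")
        shapes = {s.shape for s in self.slices}
        sizes = {s.pixel_size_um for s in self.slices}
        if len(shapes) != 1 or len(sizes) != 1:
            raise ValueError("all slices must share shape and pixel size")
        if not (self.depth_step_um > 0):
            raise ValueError("depth_step_um must be positive")
        object.__setattr__(self, "slices", tuple(self.slices))

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    @property
    def pixel_size_um(self) -> float:
        return self.slices[0].pixel_size_um


@dataclass(frozen=True)
class RoiMask:
    """Boolean region-of-interest mask annotating an image of the same shape."""

    pixels: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise InvalidMaskError("mask must be a non-empty 2-D boolean array")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    """Recover μm/px from TIFF resolution tags, if present and isotropic."""
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        unit = page.tags.get("ResolutionUnit")
    except (KeyError, AttributeError):
        return None
    def _ratio(v):
        if isinstance(v, tuple):
            return v[0] / v[1] if v[1] else 0.0
        return float(v)
    rx, ry = _ratio(xres), _ratio(yres)
    if rx <= 0 or ry <= 0:
        return None
    # ResolutionUnit 3 = centimetre; 2 = inch. Pixels per unit -> um per pixel.
    scale = {2: 25_400.0, 3: 10_000.0}.get(getattr(unit, "value", None), None)
    if scale is None:
        return None
    sx, sy = scale / rx, scale / ry
    if abs(sx - sy) > 1e-6 * max(sx, sy):
        raise AnisotropicPixelError(
            f"TIFF tags imply anisotropic pixels ({sx:.4g} x {sy:.4g} um)"
        )
    return sx


def read_image(
    path,
    pixel_size_um: float | None = None,
    channel: int | None = None,
    depth_step_um: float = 1.0,
    name: str | None = None,
) -> SHGImage | ImageStack:
    """Read a single- or multi-page grayscale TIFF.

    ``pixel_size_um`` passed explicitly always wins over TIFF resolution
    tags; if neither is available a :class:`MissingPixelSizeError` is raised.
    Multi-page files are returned as an :class:`ImageStack` in page order.
    Multi-channel pages require ``channel``.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            tag_size = None
            if pixel_size_um is None:
                tag_size = _pixel_size_from_tags(tif)
    except (FileNotFoundError, tifffile.TiffFileError, ValueError) as exc:
        raise ImageReadError(f"cannot read TIFF {path!r}: {exc}") from exc

    size = pixel_size_um if pixel_size_um is not None else tag_size
    if size is None:
        raise MissingPixelSizeError(
            f"{path}: pixel size not in TIFF tags; pass pixel_size_um explicitly"
        )
    name = name if name is not None else str(path)

    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] not in (3, 4):
        # channel-last colour page
        if channel is None:
            raise ChannelError(f"{path}: multi-channel image requires channel index")
        if not 0 <= channel < data.shape[-1]:
            raise ChannelError(f"{path}: channel {channel} out of range")
        data = data[..., channel]
    elif channel is not None and data.ndim == 3:
        if not 0 <= channel < data.shape[0]:
            raise ChannelError(f"{path}: channel {channel} out of range")
        data = data[channel]
    elif channel not in (None, 0) and data.ndim == 2:
        raise ChannelError(f"{path}: channel {channel} out of range for 2-D image")

    bit = 8 if data.dtype.itemsize == 1 else 16
    if data.ndim == 2:
        return SHGImage(data.astype(float), size, bit, name)
    if data.ndim == 3:
        slices = tuple(
            SHGImage(plane.astype(float), size, bit, f"{name}[z={k}]")
            for k, plane in enumerate(data)
        )
        return ImageStack(slices, depth_step_um=depth_step_um)
    raise ImageReadError(f"{path}: unsupported dimensionality {data.ndim}")


def write_image(path, img: SHGImage | ImageStack) -> None:
    """Write an image or stack as 8/16-bit grayscale TIFF with resolution tags.

    Intensities are rounded and clipped to the integer range of
    ``bit_depth_source``; integer-valued inputs round-trip losslessly.
    """
    if isinstance(img, ImageStack):
        first = img.slices[0]
        data = np.stack([s.pixels for s in img.slices])
        bit = first.bit_depth_source
        size = first.pixel_size_um
    else:
        data = img.pixels
        bit = img.bit_depth_source
        size = img.pixel_size_um
    dtype = np.uint8 if bit == 8 else np.uint16
    lim = np.iinfo(dtype).max
    raw = np.clip(np.rint(data), 0, lim).astype(dtype)
    res = 10_000.0 / size  # pixels per centimetre
    tifffile.imwrite(
        str(path), raw, photometric="minisblack",
        resolution=(res, res), resolutionunit=3,
    )


def read_mask(path, label: str = "roi") -> RoiMask:
    """Read a binary ROI mask from TIFF/PNG; any nonzero pixel is inside."""
    try:
        data = tifffile.imread(str(path)) if str(path).lower().endswith((".tif", ".tiff")) else None
        if data is None:
            import imageio.v3 as iio

            data = iio.imread(str(path))
    except (FileNotFoundError, ValueError, OSError) as exc:
        raise ImageReadError(f"cannot read mask {path!r}: {exc}") from exc
    if data.ndim == 3:
        data = data[..., 0]
    return RoiMask(data != 0, label=label)


def write_mask(path, mask: RoiMask) -> None:
    tifffile.imwrite(str(path), mask.pixels.astype(np.uint8) * 255)


_PCT_RE = re.compile(r"^percentile\((\d+(?:\.\d+)?)\)$")


def normalize_intensity(img: SHGImage, method: str = "none") -> SHGImage:
    """Rescale intensities into [0, 1].

    ``"none"`` is the identity (coverage thresholds are defined on the raw
    scale). ``"max"`` divides by the maximum; an all-zero image is returned
    unchanged with a warning. ``"percentile(p)"`` divides by the p-th
    percentile and clips to [0, 1]; this is the default preconditioning
    before orientation/GLCM analysis (at p = 99.9) to limit the influence of
    hot pixels.
    """
    if method == "none":
        return img
    if method == "max":
        m = float(img.pixels.max())
        if m == 0:
            warnings.warn(f"{img.name or 'image'}: all-zero image, max-normalization skipped")
            return img
        return img.with_pixels(img.pixels / m)
    m = _PCT_RE.match(method)
    if m:
        p = float(m.group(1))
        ref = float(np.percentile(img.pixels, p))
        if ref == 0:
            warnings.warn(f"{img.name or 'image'}: zero percentile, normalization skipped")
            return img
        return img.with_pixels(np.clip(img.pixels / ref, 0.0, 1.0))
    raise ValueError(f"unknown normalization method {method!r}")


def interface_band(
    compartment_mask: RoiMask,
    distance_um: float = 200.0,
    pixel_size_um: float | None = None,
) -> RoiMask:
    """Build the analysis band adjoining a tissue compartment.

    Returns the pixels *outside* ``compartment_mask`` whose Euclidean
    centre-to-centre distance to the nearest inside pixel is at most
    ``distance_um``. The 200 μm default is the conventional width of the
    tumour–stromal interface band adjoining fibroblast-rich stroma.
    """
    if pixel_size_um is None or not pixel_size_um > 0:
        raise MissingPixelSizeError("interface_band requires a positive pixel_size_um")
    if distance_um < 0:
        raise ValueError("distance_um must be >= 0")
    inside = compartment_mask.pixels
    if inside.all() or not inside.any():
        raise InvalidMaskError(
            "compartment mask must contain both inside and outside pixels"
        )
    dist_px = ndimage.distance_transform_edt(~inside)
    band = (~inside) & (dist_px * pixel_size_um <= distance_um)
    return RoiMask(band, label=f"interface_band_{distance_um:g}um")
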