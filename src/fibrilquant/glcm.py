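"""Gray-level co-occurrence texture: Haralick correlation versus offset.

The organization readout is the correlation feature of the gray-level
co-occurrence matrix (GLCM) as a function of pixel offset distance,
averaged over the four principal directions. A slowly decaying correlation
curve indicates an organized, spatially correlated fiber network; a fast
decay indicates disorganized texture. Two scalar summaries of the curve
are reported: the area under the correlation–distance curve normalized by
the distance span (``auc``) and the distance at which correlation first
falls to half its value at the smallest offset (``half_decay_distance_px``,
linearly interpolated, +inf if never reached).

Offset convention (image axes, row down): 0° = +col, 45° = (−row, +col),
90° = −row, 135° = (−row, −col); diagonal offsets take a Chebyshev step of
``d`` pixels along both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateTextureError, NoPairsError
from .images import RoiMask, SHGImage

__all__ = [
    "GLCMConfig",
    "GLCMDecay",
    "quantize",
    "glcm",
    "glcm_correlation",
    "correlation_decay",
]

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMConfig:
    """GLCM parameters. Defaults follow common texture practice; the method
    itself does not prescribe them, so all are exposed here and echoed in
    outputs."""

    n_gray_levels: int = 64
    distances_px: tuple[int, ...] = tuple(range(1, 65))
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True

    def __post_init__(self) -> None:
        d = tuple(int(x) for x in self.distances_px)
        if not d or any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("distances_px must be non-empty, positive, strictly ascending")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        bad = set(self.angles_deg) - set(_OFFSETS)
        if bad:
            raise ValueError(f"unsupported angles {sorted(bad)}; allowed: 0, 45, 90, 135")
        object.__setattr__(self, "distances_px", d)
        object.__setattr__(self, "angles_deg", tuple(int(a) for a in self.angles_deg))


@dataclass(frozen=True)
class GLCMDecay:
    """Angle-averaged correlation per offset distance with decay summaries."""

    distances_px: tuple[int, ...]
    correlation: tuple[float, ...]
    auc: float
    half_decay_distance_px: float


def quantize(img: SHGImage | np.ndarray, n_gray_levels: int, roi: RoiMask | None = None) -> np.ndarray:
    """Uniformly bin intensities into ``n_gray_levels`` integer levels.

    Bin edges span [min, max] of the ROI intensities (whole image without a
    ROI); a constant image maps to level 0. Correlation is invariant to
    affine intensity maps, so per-image binning removes gain differences
    between acquisitions.
    """
    if n_gray_levels < 2:
        raise ValueError("n_gray_levels must be >= 2")
    px = img.pixels if isinstance(img, SHGImage) else np.asarray(img, dtype=float)
    sel = px[roi.pixels] if roi is not None else px
    lo, hi = float(sel.min()), float(sel.max())
    if hi == lo:
        return np.zeros(px.shape, dtype=np.intp)
    levels = np.floor((px - lo) / (hi - lo) * n_gray_levels).astype(np.intp)
    return np.clip(levels, 0, n_gray_levels - 1)


def glcm(
    levels: np.ndarray,
    distance_px: int,
    angle_deg: int,
    symmetric: bool = True,
    roi: RoiMask | None = None,
    n_gray_levels: int | None = None,
) -> np.ndarray:
    """Normalized co-occurrence matrix for one offset.

    ``P[i, j]`` is the fraction of pixel pairs ``(p, p + offset)`` with
    levels ``(i, j)``; pairs are restricted to ROI ∩ (ROI shifted). In
    symmetric mode both directions of the offset are accumulated, so
    ``P == P.T`` exactly.
    """
    levels = np.asarray(levels)
    if distance_px < 1:
        raise ValueError("distance_px must be >= 1")
    if angle_deg not in _OFFSETS:
        raise ValueError(f"unsupported angle {angle_deg}")
    n = int(n_gray_levels) if n_gray_levels is not None else int(levels.max()) + 1
    dr, dc = (o * distance_px for o in _OFFSETS[angle_deg])
    h, w = levels.shape

    def _slices(delta, extent):
        if delta >= 0:
            return slice(0, extent - delta), slice(delta, extent)
        return slice(-delta, extent), slice(0, extent + delta)

    rs, rd = _slices(dr, h)
    cs, cd = _slices(dc, w)
    if rs.stop <= rs.start or cs.stop <= cs.start:
        raise NoPairsError(f"offset ({dr},{dc}) exceeds image extent {levels.shape}")
    a = levels[rs, cs].ravel()
    b = levels[rd, cd].ravel()
    if roi is not None:
        keep = (roi.pixels[rs, cs] & roi.pixels[rd, cd]).ravel()
        a, b = a[keep], b[keep]
    if a.size == 0:
        raise NoPairsError(f"no ROI pixel pairs for offset ({dr},{dc})")
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n).astype(float)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glcm_correlation(P: np.ndarray) -> float:
    """Haralick correlation of a normalized GLCM; in [−1, 1] when defined.

    Raises :class:`DegenerateTextureError` when a marginal has zero
    variance (constant texture along the offset)."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    idx = np.arange(n, dtype=float)
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mi = float(idx @ pi)
    mj = float(idx @ pj)
    vi = float(((idx - mi) ** 2) @ pi)
    vj = float(((idx - mj) ** 2) @ pj)
    if vi <= 0 or vj <= 0:
        raise DegenerateTextureError("zero-variance marginal; correlation undefined")
    cov = float((idx - mi) @ P @ (idx - mj))
    return cov / np.sqrt(vi * vj)


def correlation_decay(
    img: SHGImage, config: GLCMConfig = GLCMConfig(), roi: RoiMask | None = None
) -> GLCMDecay:
    """Angle-averaged correlation at each configured distance, with summaries."""
    levels = quantize(img, config.n_gray_levels, roi=roi)
    corr = []
    for d in config.distances_px:
        vals = []
        for ang in config.angles_deg:
            try:
                P = glcm(levels, d, ang, config.symmetric, roi, config.n_gray_levels)
                vals.append(glcm_correlation(P))
            except DegenerateTextureError as exc:
                raise DegenerateTextureError(
                    f"{img.name or 'image'}: d={d}, angle={ang}: {exc}"
                ) from exc
        corr.append(float(np.mean(vals)))
    d = np.asarray(config.distances_px, dtype=float)
    c = np.asarray(corr)
    auc = float(c[0]) if len(c) == 1 else float(np.trapezoid(c, d) / (d[-1] - d[0]))
    return GLCMDecay(
        distances_px=config.distances_px,
        correlation=tuple(corr),
        auc=auc,
        half_decay_distance_px=_half_decay(d, c),
    )


def _half_decay(d: np.ndarray, c: np.ndarray) -> float:
    """First distance where correlation falls to half its initial value."""
    target = c[0] / 2.0
    if c[0] <= target:  # non-positive initial correlation: already at/below half
        return float(d[0])
    below = np.nonzero(c <= target)[0]
    if below.size == 0:
        return float("inf")
    k = below[0]
    if k == 0:
        return float(d[0])
    frac = (c[k - 1] - target) / (c[k - 1] - c[k])
    return float(d[k - 1] + frac * (d[k] - d[k - 1]))
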