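"""Structure-tensor fiber-orientation analysis.

Local fiber orientation is obtained from the eigenstructure of the
structure tensor, the Gaussian-windowed outer product of the image
gradient. Gradients are evaluated from a cubic B-spline representation of
the image (prefilter to interpolation coefficients, then analytic
derivative at pixel centres), which reproduces derivatives of polynomial
images up to degree 3 exactly at interior pixels.

Conventions
-----------
* ``theta_deg`` is the dominant *structure* orientation — the direction a
  fiber runs — in degrees counter-clockwise from the +column axis as seen
  on screen, reduced into the axial range (−90, 90]. It is perpendicular
  to the dominant gradient direction.
* ``coherency`` = (λ1 − λ2)/(λ1 + λ2) of the tensor eigenvalues ∈ [0, 1]:
  0 for isotropic texture, 1 for perfectly oriented texture. Pixels with
  low energy or low coherency ("isotropic" pixels) are excluded from the
  histogram via ``valid_mask``.
* The orientation histogram is axial; the peak alignment is the centre of
  its maximal bin (ties break toward the smaller angle) and the alignment
  frequency is the histogram mass within ±Δ of the peak, wrapping mod 180°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .axial import axial_distance_deg, wrap_axial_deg
from .errors import ImageTooSmallError, NoOrientedSignalError
from .images import RoiMask, SHGImage

__all__ = [
    "OrientationField",
    "OrientationHistogram",
    "bspline_gradient",
    "structure_tensor",
    "orientation_field",
    "orientation_histogram",
    "orientation_analysis",
    "compare_orientation_distributions",
]

# cubic B-spline value / first-derivative kernels at integer offsets
_B3 = np.array([1.0, 4.0, 1.0]) / 6.0
_DB3 = np.array([-0.5, 0.0, 0.5])  # out[k] = (c[k+1] - c[k-1]) / 2


@dataclass(frozen=True)
class OrientationField:
    theta_deg: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class OrientationHistogram:
    bin_edges_deg: np.ndarray
    frequency: np.ndarray
    peak_angle_deg: float
    alignment_frequency: float
    delta_deg: float
    n_valid_pixels: int

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])


def bspline_gradient(img: SHGImage | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous spatial derivatives from a cubic B-spline image model.

    Returns ``(fx, fy)``: the derivatives along +col and +row, evaluated at
    pixel centres with mirror-reflect boundary handling. Exact for
    polynomial intensities up to cubic order (interior pixels).
    """
    px = img.pixels if isinstance(img, SHGImage) else np.asarray(img, dtype=float)
    if px.ndim != 2 or min(px.shape) < 4:
        raise ImageTooSmallError("bspline_gradient requires at least a 4x4 image")
    c = ndimage.spline_filter(px, order=3, mode="mirror", output=float)
    fx = ndimage.correlate1d(c, _DB3, axis=1, mode="mirror")
    fx = ndimage.correlate1d(fx, _B3, axis=0, mode="mirror")
    fy = ndimage.correlate1d(c, _DB3, axis=0, mode="mirror")
    fy = ndimage.correlate1d(fy, _B3, axis=1, mode="mirror")
    return fx, fy


def structure_tensor(
    fx: np.ndarray, fy: np.ndarray, window_sigma_px: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-windowed tensor components (Jxx, Jxy, Jyy).

    Each component is the local average of the corresponding gradient
    product over a Gaussian window of s.d. ``window_sigma_px`` with
    mirror boundaries.
    """
    if not window_sigma_px > 0:
        raise ValueError("window_sigma_px must be positive")
    if fx.shape != fy.shape:
        raise ValueError("gradient fields must share a shape")
    sm = lambda a: ndimage.gaussian_filter(a, window_sigma_px, mode="mirror")
    return sm(fx * fx), sm(fx * fy), sm(fy * fy)


def orientation_field(
    Jxx: np.ndarray,
    Jxy: np.ndarray,
    Jyy: np.ndarray,
    energy_gate_percentile: float = 25.0,
    coherency_gate: float = 0.2,
    border_exclude_px: int = 0,
    roi: RoiMask | None = None,
) -> OrientationField:
    """Per-pixel orientation, coherency and validity gates from the tensor.

    The gradient fields follow image axes (row increasing downward), so the
    on-screen counter-clockwise structure orientation is
    ``90° − ½·atan2(2 Jxy, Jxx − Jyy)``, reduced into (−90, 90].
    Pixels are valid when their energy (tensor trace) reaches the
    ``energy_gate_percentile`` of ROI energies, their coherency reaches
    ``coherency_gate``, and they lie further than ``border_exclude_px``
    from the border (suppressing boundary artifacts of the windowed
    average). This energy/coherency gating is how "isotropic" pixels are
    excluded from the orientation statistics.
    """
    energy = Jxx + Jyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(
            energy > 0, np.sqrt((Jxx - Jyy) ** 2 + 4.0 * Jxy**2) / energy, 0.0
        )
    coherency = np.clip(coherency, 0.0, 1.0)
    theta = wrap_axial_deg(90.0 - 0.5 * np.degrees(np.arctan2(2.0 * Jxy, Jxx - Jyy)))

    sel = energy[roi.pixels] if roi is not None else energy
    gate = np.percentile(sel, energy_gate_percentile) if sel.size else np.inf
    valid = (energy >= gate) & (energy > 0) & (coherency >= coherency_gate)
    if roi is not None:
        valid &= roi.pixels
    b = int(border_exclude_px)
    if b > 0:
        h, w = valid.shape
        border = np.zeros_like(valid)
        border[b : h - b, b : w - b] = True
        valid &= border
    return OrientationField(theta, coherency, energy, valid)


def orientation_histogram(
    field: OrientationField,
    roi: RoiMask | None = None,
    bin_width_deg: float = 1.0,
    delta_deg: float = 10.0,
    weighting: str = "coherency",
) -> OrientationHistogram:
    """Axial orientation histogram with peak alignment and alignment frequency.

    ``bin_width_deg`` must divide 180 evenly; ``delta_deg`` ∈ (0, 90) is
    the half-width of the alignment window around the peak. With
    ``weighting="coherency"`` each pixel contributes its coherency, so
    strongly oriented texture dominates the histogram.
    """
    n_bins = 180.0 / bin_width_deg
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width_deg must divide 180 evenly")
    if not 0 < delta_deg < 90:
        raise ValueError("delta_deg must lie in (0, 90)")
    if weighting not in ("none", "coherency"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n_bins = int(round(n_bins))
    sel = field.valid_mask if roi is None else (field.valid_mask & roi.pixels)
    theta = field.theta_deg[sel]
    if theta.size == 0:
        raise NoOrientedSignalError("no oriented signal in valid_mask ∩ roi")
    w = field.coherency[sel] if weighting == "coherency" else None
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    hist, _ = np.histogram(theta, bins=edges, weights=w)
    total = hist.sum()
    if total <= 0:
        raise NoOrientedSignalError("zero total weight in orientation histogram")
    freq = hist / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_idx = int(np.argmax(freq))  # first max -> smaller angle on ties
    peak = float(centers[peak_idx])
    in_window = axial_distance_deg(centers, peak) <= delta_deg + 1e-9
    return OrientationHistogram(
        bin_edges_deg=edges,
        frequency=freq,
        peak_angle_deg=peak,
        alignment_frequency=float(freq[in_window].sum()),
        delta_deg=float(delta_deg),
        n_valid_pixels=int(theta.size),
    )


def orientation_analysis(
    img: SHGImage,
    window_sigma_px: float = 2.0,
    energy_gate_percentile: float = 25.0,
    coherency_gate: float = 0.2,
    bin_width_deg: float = 1.0,
    delta_deg: float = 10.0,
    weighting: str = "coherency",
    roi: RoiMask | None = None,
) -> tuple[OrientationField, OrientationHistogram]:
    """Full pipeline: B-spline gradient → structure tensor → histogram.

    Pixels within ``3 × window_sigma_px`` of the border are excluded from
    the valid mask.
    """
    fx, fy = bspline_gradient(img)
    Jxx, Jxy, Jyy = structure_tensor(fx, fy, window_sigma_px)
    field = orientation_field(
        Jxx,
        Jxy,
        Jyy,
        energy_gate_percentile=energy_gate_percentile,
        coherency_gate=coherency_gate,
        border_exclude_px=int(np.ceil(3.0 * window_sigma_px)),
        roi=roi,
    )
    hist = orientation_histogram(
        field, roi=roi, bin_width_deg=bin_width_deg, delta_deg=delta_deg, weighting=weighting
    )
    return field, hist


def compare_orientation_distributions(samples_a, samples_b) -> tuple[float, float]:
    """Mann–Whitney U comparison of two axial orientation samples.

    Axial angles have no natural linear order, so both samples are first
    expressed as absolute angular deviation (mod 180°) from their joint
    peak (the maximal 1° bin of the pooled histogram); the two-sided
    Mann–Whitney U test then compares how concentrated each sample is
    around that shared mode. Returns ``(U, p)``.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise NoOrientedSignalError("both samples must be non-empty")
    pooled = wrap_axial_deg(np.concatenate([a, b]))
    edges = np.linspace(-90.0, 90.0, 181)
    hist, _ = np.histogram(pooled, bins=edges)
    peak = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    da = axial_distance_deg(wrap_axial_deg(a), peak)
    db = axial_distance_deg(wrap_axial_deg(b), peak)
    res = stats.mannwhitneyu(da, db, alternative="two-sided", use_continuity=True)
    return float(res.statistic), float(res.pvalue)
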