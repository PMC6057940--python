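"""Helpers for axial (180°-periodic) angles.

Fiber orientation is axial: θ and θ+180° are the same direction. All
angles in the package live in the half-open interval (−90, 90] degrees,
and distances between angles are taken modulo 180°.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_axial_deg", "axial_distance_deg"]


def wrap_axial_deg(angle_deg):
    """Reduce angle(s) in degrees into the axial range (−90, 90]."""
    a = np.mod(np.asarray(angle_deg, dtype=float) + 90.0, 180.0) - 90.0
    a = np.where(a == -90.0, 90.0, a)
    return float(a) if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0 else a


def axial_distance_deg(a_deg, b_deg):
    """Smallest absolute angular difference modulo 180°, in [0, 90]."""
    d = np.abs(np.mod(np.asarray(a_deg, dtype=float) - b_deg, 180.0))
    d = np.minimum(d, 180.0 - d)
    return float(d) if np.ndim(d) == 0 else d
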