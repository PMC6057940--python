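"""Shared fixtures: small phantoms reused across test modules.

Phantoms here use a 320 × 320 μm field sampled at 1.25 μm/px (256 × 256)
unless a test needs the finer native sampling; session scope avoids
re-rendering the same scenes.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibrilquant import FiberSceneSpec, generate_fiber_scene


def small_spec(**kw) -> FiberSceneSpec:
    base = dict(height_px=256, width_px=256, pixel_size_um=1.25, n_fibers=150, seed=0)
    base.update(kw)
    return FiberSceneSpec(**base)


@pytest.fixture(scope="session")
def aligned_scene():
    """Strongly aligned phantom at 30 deg."""
    return generate_fiber_scene(small_spec(peak_angle_deg=30.0, kappa=8.0, seed=7))


@pytest.fixture(scope="session")
def noiseless_scene():
    """Phantom without photon/read noise: image equals its pre-noise field."""
    return generate_fiber_scene(
        small_spec(noise_gaussian_sd=0.0, noise_poisson_scale=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def isotropic_scene():
    return generate_fiber_scene(small_spec(kappa=0.0, n_fibers=500, seed=11))
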