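"""Structure-tensor orientation: recover peak alignment from a phantom.

A phantom is rendered with a known axial orientation distribution
(von Mises peak 40 deg, concentration kappa=8); the structure-tensor
pipeline recovers the peak alignment and the frequency of fiber
alignment from the image alone.
"""

from fibrilquant import (
    FiberSceneSpec,
    compare_orientation_distributions,
    generate_fiber_scene,
    normalize_intensity,
    orientation_analysis,
)

spec = FiberSceneSpec(height_px=256, width_px=256, pixel_size_um=1.25,
                      n_fibers=1500, fiber_length_um=30.0,
                      peak_angle_deg=40.0, kappa=8.0, seed=2)
scene = generate_fiber_scene(spec)
img = normalize_intensity(scene.image, "percentile(99.9)")
field, hist = orientation_analysis(img)

print(f"true peak angle        : {scene.true_peak_angle_deg:.1f} deg")
print(f"recovered peak angle   : {hist.peak_angle_deg:.1f} deg")
print(f"alignment frequency    : {hist.alignment_frequency:.3f} "
      f"(mass within +/-{hist.delta_deg:.0f} deg of the peak)")
print(f"oriented pixels used   : {hist.n_valid_pixels}")

# Compare the oriented-pixel distributions of an aligned and an isotropic
# field: the Mann-Whitney U test on deviations from the joint peak.
iso = generate_fiber_scene(FiberSceneSpec(
    height_px=256, width_px=256, pixel_size_um=1.25, n_fibers=1500,
    fiber_length_um=30.0, kappa=0.0, seed=2))
iso_field, _ = orientation_analysis(
    normalize_intensity(iso.image, "percentile(99.9)"))
u, p = compare_orientation_distributions(
    field.theta_deg[field.valid_mask][:5000],
    iso_field.theta_deg[iso_field.valid_mask][:5000],
)
print(f"\naligned vs isotropic orientation distributions: U = {u:.3g}, p = {p:.3g}")
print("(small p: the aligned sample is far more concentrated about the mode)")
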