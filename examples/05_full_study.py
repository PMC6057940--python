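"""Full study orchestration: two phantom groups through the whole pipeline.

Writes six phantoms to disk (three aligned, three isotropic), runs
coverage, GLCM decay and orientation on every image, and applies the
configured group tests to each metric. Outputs land in a temporary
directory as metrics.csv / comparisons.csv / run_manifest.json.
"""

import tempfile
from pathlib import Path

from fibrilquant import (
    FiberSceneSpec,
    GLCMConfig,
    ImageEntry,
    StudyConfig,
    generate_fiber_scene,
    run_study,
    write_scene,
)

with tempfile.TemporaryDirectory() as tmp:
    entries = []
    for k in range(3):
        for group, kappa in (("aligned", 50.0), ("isotropic", 0.0)):
            spec = FiberSceneSpec(height_px=128, width_px=128, pixel_size_um=1.25,
                                  n_fibers=120, fiber_length_um=30.0,
                                  peak_angle_deg=20.0, kappa=kappa, seed=k)
            path = Path(tmp) / f"{group}_{k}.tif"
            write_scene(generate_fiber_scene(spec), path)
            entries.append(ImageEntry(path=str(path), group=group, pixel_size_um=1.25))

    cfg = StudyConfig(
        images=tuple(entries),
        output_dir=str(Path(tmp) / "out"),
        threshold=500.0,
        glcm=GLCMConfig(distances_px=tuple(range(1, 9))),
        seed=0,
    )
    result = run_study(cfg)

    print(f"analyzed {len(result.metrics)} images "
          f"(threshold {result.threshold_used:g}, {result.n_failed} failures)\n")
    cols = ["group", "coverage_percent", "glcm_auc", "alignment_frequency"]
    print(result.metrics[cols].to_string(index=False, float_format="%.3f"))
    print("\ngroup comparisons (t test on scalars, Mann-Whitney on distributions):")
    cols = ["metric", "test", "statistic", "p_value"]
    print(result.comparisons[cols].to_string(index=False, float_format="%.4g"))
    print("\nalignment_frequency separates the groups; coverage does not "
          "(same fiber count), which is the expected pattern.")
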