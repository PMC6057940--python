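"""Batch orchestration: run every metric over an image manifest and compare groups.

A study is a YAML/JSON config naming images (path, group, optional ROI and
sample), the global coverage threshold policy, GLCM and orientation
parameters, and an output directory. ``run_study`` computes coverage, GLCM
decay summaries and orientation summaries per image (restricted to the
configured ROI or its interface band), aggregates them per group, runs the
configured comparison tests, and writes:

* ``metrics.csv`` — one row per image with every metric and its parameters
* ``comparisons.csv`` — one row per metric × group pair with test and p
* ``run_manifest.json`` — config echo, config hash, package version
* ``run.log`` — timestamped processing log (the only non-deterministic file)

Given identical config, inputs and seed, the CSV and manifest outputs are
byte-identical across reruns. Per-image failures are logged and skipped,
and reported in the returned summary (nonzero ``n_failed``), never silent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import binarize, coverage_fraction, pooled_otsu_threshold
from .errors import FibrilquantError
from .glcm import GLCMConfig, correlation_decay
from .groupstats import GroupComparison, compare_groups
from .images import (
    ImageStack,
    RoiMask,
    SHGImage,
    interface_band,
    normalize_intensity,
    read_image,
    read_mask,
)
from .orientation import compare_orientation_distributions, orientation_analysis

__all__ = ["ImageEntry", "StudyConfig", "StudyResult", "run_study", "load_study_config"]

log = logging.getLogger("fibrilquant")


@dataclass(frozen=True)
class ImageEntry:
    path: str
    group: str
    pixel_size_um: float | None = None
    roi: str | None = None
    sample: str | None = None
    channel: int | None = None


@dataclass(frozen=True)
class OrientationParams:
    window_sigma_px: float = 2.0
    bin_width_deg: float = 1.0
    delta_deg: float = 10.0
    energy_gate_percentile: float = 25.0
    coherency_gate: float = 0.2
    weighting: str = "coherency"


@dataclass(frozen=True)
class StudyConfig:
    images: tuple[ImageEntry, ...]
    output_dir: str
    threshold: float | None = None
    auto_threshold: str | None = None  # "otsu-pooled"
    normalization: str = "percentile(99.9)"  # applied before GLCM/orientation
    interface_band_um: float | None = None  # ROI = band around the compartment mask
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    orientation: OrientationParams = field(default_factory=OrientationParams)
    pooling: str = "per_sample_mean"  # or "per_area"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("study needs at least one image")
        if self.threshold is None and self.auto_threshold is None:
            raise ValueError("set a global threshold or auto_threshold: otsu-pooled")
        if self.auto_threshold not in (None, "otsu-pooled"):
            raise ValueError(f"unknown auto_threshold {self.auto_threshold!r}")
        if self.pooling not in ("per_sample_mean", "per_area"):
            raise ValueError(f"unknown pooling {self.pooling!r}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)  # analytic provenance only; not where it lands
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyResult:
    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    threshold_used: float
    n_failed: int
    output_dir: Path


_SCALAR_METRICS = ("coverage_percent", "glcm_auc", "glcm_half_decay_px",
                   "peak_angle_deg", "alignment_frequency")


def load_study_config(path) -> StudyConfig:
    """Load a study config from YAML (or JSON) on disk."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    images = tuple(ImageEntry(**e) for e in raw.pop("images"))
    glcm_raw = raw.pop("glcm", None)
    glcm_cfg = GLCMConfig(**_tupled(glcm_raw)) if glcm_raw else GLCMConfig()
    orient_raw = raw.pop("orientation", None)
    orient = OrientationParams(**orient_raw) if orient_raw else OrientationParams()
    return StudyConfig(images=images, glcm=glcm_cfg, orientation=orient, **raw)


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _load_entry(entry: ImageEntry, cfg: StudyConfig):
    img = read_image(entry.path, pixel_size_um=entry.pixel_size_um, channel=entry.channel)
    if isinstance(img, ImageStack):
        img = img.slices[0]  # stacks analyzed per-slice elsewhere; study uses slice 0
    roi = None
    if entry.roi:
        roi = read_mask(entry.roi)
        if cfg.interface_band_um is not None:
            roi = interface_band(roi, cfg.interface_band_um, img.pixel_size_um)
    return img, roi


def run_study(cfg: StudyConfig) -> StudyResult:
    """Execute the full pipeline over the manifest; see module docstring."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("fibrilquant %s study start; %d images; seed=%d; config=%s",
             __version__, len(cfg.images), cfg.seed, cfg.config_hash())

    loaded, failed = [], []
    for entry in cfg.images:
        try:
            img, roi = _load_entry(entry, cfg)
            loaded.append((entry, img, roi))
        except (FibrilquantError, OSError, ValueError) as exc:
            log.error("skipping %s: %s", entry.path, exc)
            failed.append((entry.path, str(exc)))

    if cfg.auto_threshold == "otsu-pooled":
        threshold = pooled_otsu_threshold(
            [img for _, img, _ in loaded], [roi for _, _, roi in loaded]
        )
        log.info("pooled Otsu threshold: %.6g", threshold)
    else:
        threshold = float(cfg.threshold)

    rows, theta_by_group = [], {}
    for entry, img, roi in loaded:
        try:
            rows.append(
                _analyze_one(entry, img, roi, threshold, cfg, theta_by_group)
            )
        except (FibrilquantError, ValueError) as exc:
            log.error("analysis failed for %s: %s", entry.path, exc)
            failed.append((entry.path, str(exc)))

    metrics = pd.DataFrame(rows)
    comparisons = _compare_all(metrics, theta_by_group, cfg)
    _write_outputs(out, cfg, metrics, comparisons, threshold, failed)
    log.info("study done: %d analyzed, %d failed", len(rows), len(failed))
    log.removeHandler(handler)
    handler.close()
    return StudyResult(metrics, comparisons, threshold, len(failed), out)


def _analyze_one(entry, img, roi, threshold, cfg, theta_by_group) -> dict:
    cov = coverage_fraction(binarize(img, threshold), roi, threshold_used=threshold)
    norm = normalize_intensity(img, cfg.normalization)
    decay = correlation_decay(norm, cfg.glcm, roi=roi)
    o = cfg.orientation
    field_, hist = orientation_analysis(
        norm,
        window_sigma_px=o.window_sigma_px,
        energy_gate_percentile=o.energy_gate_percentile,
        coherency_gate=o.coherency_gate,
        bin_width_deg=o.bin_width_deg,
        delta_deg=o.delta_deg,
        weighting=o.weighting,
        roi=roi,
    )
    sel = field_.valid_mask if roi is None else field_.valid_mask & roi.pixels
    theta_by_group.setdefault(entry.group, []).append(field_.theta_deg[sel])
    return {
        "image": entry.path,
        "group": entry.group,
        "sample": entry.sample or entry.path,
        "roi": entry.roi or "",
        "threshold": threshold,
        "coverage_percent": cov.coverage_percent,
        "glcm_auc": decay.auc,
        "glcm_half_decay_px": decay.half_decay_distance_px,
        "peak_angle_deg": hist.peak_angle_deg,
        "alignment_frequency": hist.alignment_frequency,
        "n_valid_pixels": hist.n_valid_pixels,
        "glcm_levels": cfg.glcm.n_gray_levels,
        "window_sigma_px": o.window_sigma_px,
        "delta_deg": o.delta_deg,
        "coherency_gate": o.coherency_gate,
        "energy_gate_percentile": o.energy_gate_percentile,
        "weighting": o.weighting,
        "normalization": cfg.normalization,
    }


def _pool_metric(metrics: pd.DataFrame, metric: str, cfg: StudyConfig) -> dict:
    """Per-group value arrays, averaging areas of one sample when configured."""
    if cfg.pooling == "per_sample_mean":
        pooled = metrics.groupby(["group", "sample"], sort=True)[metric].mean()
        return {g: pooled.xs(g).to_numpy() for g in pooled.index.get_level_values(0).unique()}
    return {g: sub[metric].to_numpy() for g, sub in metrics.groupby("group", sort=True)}


def _compare_all(metrics, theta_by_group, cfg) -> pd.DataFrame:
    rows = []
    if metrics.empty or metrics["group"].nunique() < 2:
        log.info("fewer than two groups: comparisons table left empty")
        return pd.DataFrame(
            columns=["metric", "test", "group_a", "group_b", "statistic", "p_value",
                     "mean_a", "sem_a", "n_a", "mean_b", "sem_b", "n_b"]
        )
    for metric in _SCALAR_METRICS:
        by_group = _pool_metric(metrics, metric, cfg)
        for ga, gb in itertools.combinations(sorted(by_group), 2):
            try:
                c = compare_groups({ga: by_group[ga], gb: by_group[gb]},
                                   "t_equal_var", metric=metric)
                rows.append(_row(c))
            except ValueError as exc:
                log.warning("t test skipped for %s (%s vs %s): %s", metric, ga, gb, exc)
    # distribution-level comparison of pooled orientation samples
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed % 2**32)))
    samples = {}
    for g in sorted(theta_by_group):
        pool = np.concatenate(theta_by_group[g])
        if pool.size > 5000:
            pool = rng.choice(pool, 5000, replace=False)
        samples[g] = pool
    for ga, gb in itertools.combinations(sorted(samples), 2):
        u, p = compare_orientation_distributions(samples[ga], samples[gb])
        rows.append({
            "metric": "orientation_distribution", "test": "mann_whitney",
            "group_a": ga, "group_b": gb, "statistic": u, "p_value": p,
            "mean_a": float("nan"), "sem_a": float("nan"), "n_a": samples[ga].size,
            "mean_b": float("nan"), "sem_b": float("nan"), "n_b": samples[gb].size,
        })
    return pd.DataFrame(rows)


def _row(c: GroupComparison) -> dict:
    return {
        "metric": c.metric, "test": c.test,
        "group_a": c.group_labels[0], "group_b": c.group_labels[1],
        "statistic": c.statistic, "p_value": c.p_value,
        "mean_a": c.group_means[0], "sem_a": c.group_sems[0], "n_a": c.group_ns[0],
        "mean_b": c.group_means[1], "sem_b": c.group_sems[1], "n_b": c.group_ns[1],
    }


def _write_outputs(out: Path, cfg, metrics, comparisons, threshold, failed) -> None:
    header = f"# fibrilquant {__version__} config={cfg.config_hash()}\n"
    for name, df in (("metrics.csv", metrics), ("comparisons.csv", comparisons)):
        with open(out / name, "w", encoding="utf-8", newline="") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "threshold_used": threshold,
        "n_images": len(cfg.images),
        "n_failed": len(failed),
        "failures": failed,
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
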