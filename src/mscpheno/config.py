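"""Pipeline configuration.

Every tunable of the segmentation/classification pipeline lives in a dataclass
here, with the package defaults, and can be overridden from a YAML file whose
top-level blocks mirror the pipeline stages (``preprocess:``, ``region_detect:``,
``marker_detect:``, ``segment:``, ``features:``, ``classify:``).

Intensities are always on the [0, 1] scale; lengths are in pixels unless a
field name says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class ImageSpec:
    """Raster geometry and physical scale of a micrograph.

    The default matches a 10x phase-contrast setup: 1280x1024 px at
    1.56 px/um.
    """

    width: int = 1280
    height: int = 1024
    pixels_per_micron: float = 1.56

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("image dimensions must be >= 64 px")
        if self.pixels_per_micron <= 0:
            raise ValueError("pixels_per_micron must be > 0")


@dataclass
class PreprocessParams:
    """Contrast stretch, unsharp masking and anisotropic median-diffusion."""

    contrast_saturation: float = 0.01  # fraction clipped per tail
    unsharp_radius: float = 2.0  # px, Gaussian sigma of the blur
    unsharp_amount: float = 0.8
    diffusion_iterations: int = 5
    diffusion_kappa: float = 0.1  # gradient scale on the [0,1] intensity axis
    diffusion_dt: float = 0.15

    def __post_init__(self) -> None:
        if not (0 <= self.contrast_saturation < 0.1):
            raise ValueError("contrast_saturation must be in [0, 0.1)")
        if self.unsharp_radius < 0.5:
            raise ValueError("unsharp_radius must be >= 0.5")
        if self.diffusion_iterations < 1:
            raise ValueError("diffusion_iterations must be >= 1")


@dataclass
class RegionFilterParams:
    """Size/intensity/shape thresholds and structuring elements for one
    density level."""

    edge_sensitivity: float = 1.0  # multiplier of the Otsu gradient threshold
    size_abs_min: float = 100.0  # px^2
    k_size: float = 2.0  # adaptive rule: area >= mean - k*std
    intensity_bright_quantile: float = 0.98
    intensity_dark_quantile: float = 0.02
    circularity_max: float = 0.70
    ellipticity_max: float = 0.70
    se_dilate: int = 2
    se_close: int = 3
    se_open: int = 2
    # the initial mask traces the outer halo boundary (~2-3 px outside the
    # cell body) and is then dilated by se_dilate; the erosion radius offsets
    # both so the candidate region sits at body scale
    se_erode: int = 5
    threshold_passes: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.circularity_max <= 1 and 0 < self.ellipticity_max <= 1):
            raise ValueError("shape cutoffs must be in (0, 1]")


@dataclass
class RegionDetectParams:
    af_threshold: float = 0.1
    low: RegionFilterParams = field(default_factory=RegionFilterParams)
    moderate: RegionFilterParams = field(
        default_factory=lambda: RegionFilterParams(
            edge_sensitivity=0.5,
            se_dilate=2,
            se_close=3,
            se_open=2,
            se_erode=5,
            threshold_passes=2,
        )
    )


@dataclass
class MarkerParams:
    """Dual-threshold H-minima marker detection."""

    h_threshold_A: float = 0.30  # deep-minimum depth (high threshold)
    h_threshold_B: float = 0.12  # shallow-minimum depth (low threshold)
    cluster_perimeter_min: float = 400.0  # px; larger ROIs are cluster candidates
    min_marker_area: float = 150.0  # px^2 (~62 um^2; below any MSC nuclear basin)
    min_centroid_distance: float = 15.0  # px (~10 um at 1.56 px/um)
    gaussian_sigma: float = 1.0
    median_radius: int = 1
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if not (0 < self.h_threshold_B < self.h_threshold_A <= 1):
            raise ValueError("require 0 < h_threshold_B < h_threshold_A <= 1")


@dataclass
class FeatureParams:
    glcm_levels: int = 32
    glcm_scheme: str = "angles24"  # or "angles8x3dist"
    elongation_cap: float = 100.0
    correlation_max: float = 0.8


@dataclass
class ClassifyParams:
    svm_C: float = 1.0
    lr_C: float = 1.0
    knn_k: int = 5
    smote_k: int = 5
    cv_folds: int = 5
    cv_seed: int = 17
    bootstrap_reps: int = 2000


@dataclass
class PipelineConfig:
    image: ImageSpec = field(default_factory=ImageSpec)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    region_detect: RegionDetectParams = field(default_factory=RegionDetectParams)
    marker_detect: MarkerParams = field(default_factory=MarkerParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)


def _update_dataclass(obj: Any, data: dict[str, Any]) -> Any:
    kwargs = {}
    for f in dataclasses.fields(obj):
        cur = getattr(obj, f.name)
        if f.name in data:
            val = data[f.name]
            if dataclasses.is_dataclass(cur) and isinstance(val, dict):
                kwargs[f.name] = _update_dataclass(cur, val)
            elif isinstance(cur, tuple) and isinstance(val, list):
                kwargs[f.name] = tuple(val)
            else:
                kwargs[f.name] = val
        else:
            kwargs[f.name] = cur
    return type(obj)(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a PipelineConfig, optionally overriding defaults from YAML."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return _update_dataclass(cfg, data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
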