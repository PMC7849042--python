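"""Candidate cell-region detection.

From the preprocessed image this stage produces, in order: Sobel edges, the
filled initial region mask, an area-fraction density estimate that selects a
low- or moderate-density parameter set, size/intensity/shape filtering of
connected components, and finally morphological refinement plus border
clearing to yield the candidate cell regions that marker detection operates
inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .config import RegionDetectParams, RegionFilterParams

# 8-connectivity for components everywhere in this stage
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ShapeScores:
    circularity: float
    ellipticity: float
    area: float
    perimeter: float


@dataclass
class DensityEstimate:
    area_fraction: float
    level: str  # "low" | "moderate"


@dataclass
class RegionDetectionResult:
    initial_mask: np.ndarray
    candidate_mask: np.ndarray
    density: DensityEstimate


def detect_edges(img: np.ndarray, sensitivity: float = 1.0) -> np.ndarray:
    """Sobel gradient magnitude thresholded at ``sensitivity * T_auto``.

    T_auto is the Otsu threshold of the gradient-magnitude histogram, so the
    low-density pass uses multiplier 1.0 and the moderate-density pass 0.5 on
    the same automatic scale.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    grad = filters.sobel(img)
    if np.ptp(grad) == 0:
        return np.zeros_like(img, dtype=bool)
    t_auto = filters.threshold_otsu(grad)
    return grad > sensitivity * t_auto


def connect_fill(edges: np.ndarray, se_dilate: int, se_close: int) -> np.ndarray:
    """Dilate -> close -> fill holes to turn edge fragments into solid regions."""
    out = morphology.dilation(edges, morphology.disk(se_dilate))
    out = morphology.closing(out, morphology.disk(se_close))
    # 4-connected background flood fill
    out = ndimage.binary_fill_holes(out)
    return out


def area_fraction(mask: np.ndarray) -> float:
    """Fraction of foreground pixels — the density proxy."""
    if mask.size == 0:
        raise ValueError("empty raster")
    return float(np.count_nonzero(mask)) / mask.size


def classify_density(af: float, threshold: float = 0.1) -> str:
    """Low density below the threshold, moderate at or above it."""
    return "low" if af < threshold else "moderate"


def shape_scores(component: np.ndarray) -> ShapeScores:
    """Circularity 4*pi*A/P^2 (clipped at 1) and ellipticity (M1-M2)/M1 of the
    moment-equivalent ellipse for a single-component boolean mask."""
    lab = component.astype(np.uint8)
    props = measure.regionprops(lab)[0]
    area = float(props.area)
    perim = float(props.perimeter)
    circ = min(4.0 * np.pi * area / perim**2, 1.0) if perim > 0 else 1.0
    m1 = float(props.axis_major_length)
    m2 = float(props.axis_minor_length)
    ell = (m1 - m2) / m1 if m1 > 0 else 0.0
    return ShapeScores(circularity=circ, ellipticity=ell, area=area, perimeter=perim)


def _component_passes(
    comp_mask: np.ndarray,
    pre_img: np.ndarray,
    area: float,
    size_min: float,
    bright_thr: float,
    dark_thr: float,
    params: RegionFilterParams,
) -> bool:
    if area < size_min:
        return False
    vals = pre_img[comp_mask]
    if not (np.any(vals > bright_thr) or np.any(vals < dark_thr)):
        return False
    s = shape_scores(comp_mask)
    if s.circularity > params.circularity_max:
        return False
    if s.ellipticity > params.ellipticity_max:
        return False
    return True


def filter_candidate_objects(
    mask: np.ndarray,
    pre_img: np.ndarray,
    params: RegionFilterParams,
    level: str = "low",
) -> np.ndarray:
    """Remove components failing the size, intensity, or shape criteria.

    Size: area below max(absolute floor, mean - k*std of the image's component
    areas). Intensity: a cell must contain at least one pixel brighter than
    the bright quantile (phase halo) or darker than the dark quantile
    (nucleus); components spanning only substrate-like intensities are
    dropped. Shape: overly circular (debris) or overly elliptical
    (fibers/strands) components are dropped. Moderate-density images run the
    pass twice because the lower edge threshold admits more false objects.
    """
    if mask.shape != pre_img.shape:
        raise ValueError("mask and image shapes differ")
    passes = params.threshold_passes if level == "moderate" else 1
    bright_thr = np.quantile(pre_img, params.intensity_bright_quantile)
    dark_thr = np.quantile(pre_img, params.intensity_dark_quantile)
    out = mask.copy()
    for _ in range(passes):
        labels, n = ndimage.label(out, structure=_STRUCT8)
        if n == 0:
            return out
        areas = ndimage.sum_labels(out, labels, index=np.arange(1, n + 1))
        size_min = max(params.size_abs_min, areas.mean() - params.k_size * areas.std())
        keep = np.zeros(n + 1, dtype=bool)
        for i in range(1, n + 1):
            comp = labels == i
            keep[i] = _component_passes(
                comp, pre_img, float(areas[i - 1]), size_min, bright_thr, dark_thr, params
            )
        out = keep[labels]
    return out


def refine_and_clear_border(mask: np.ndarray, se_open: int, se_erode: int) -> np.ndarray:
    """Opening, erosion, then removal of border-touching components (truncated
    cells are never analysed)."""
    out = morphology.opening(mask, morphology.disk(se_open))
    if se_erode > 0:
        out = morphology.erosion(out, morphology.disk(se_erode))
    out = segmentation.clear_border(out)
    return out


def detect_regions(
    pre_img: np.ndarray, params: RegionDetectParams | None = None
) -> RegionDetectionResult:
    """Full region-detection stage with density-adaptive branching.

    The initial mask is always built with the low-density (sensitivity 1.0)
    edge pass; its area fraction decides the density level. Moderate-density
    images are then re-detected with the reduced sensitivity threshold and the
    moderate structuring elements before filtering.
    """
    p = params or RegionDetectParams()
    edges = detect_edges(pre_img, p.low.edge_sensitivity)
    initial = connect_fill(edges, p.low.se_dilate, p.low.se_close)
    af = area_fraction(initial)
    level = classify_density(af, p.af_threshold)
    if level == "moderate":
        fp = p.moderate
        edges = detect_edges(pre_img, fp.edge_sensitivity)
        work = connect_fill(edges, fp.se_dilate, fp.se_close)
    else:
        fp = p.low
        work = initial
    filtered = filter_candidate_objects(work, pre_img, fp, level)
    candidate = refine_and_clear_border(filtered, fp.se_open, fp.se_erode)
    return RegionDetectionResult(
        initial_mask=initial,
        candidate_mask=candidate,
        density=DensityEstimate(area_fraction=af, level=level),
    )
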