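"""Instance segmentation: combine candidate regions and markers.

A region with no marker is dropped (not a cell), a region with one marker is
a single cell, and a region with two or more markers is a cluster that the
marker-controlled watershed splits into exactly one cell per marker. The
watershed floods the marker-processed intensity relief (cells are darkest
inside), constrained to the region, leaving one-pixel ridge lines unlabelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .config import PipelineConfig
from .marker_detect import MarkerSet, detect_markers
from .preprocess import preprocess_image, to_grayscale
from .region_detect import DensityEstimate, detect_regions

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class LabelMap:
    """Instance segmentation with provenance bookkeeping."""

    labels: np.ndarray
    provenance: dict[int, str] = field(default_factory=dict)  # "single"|"from_cluster"
    cluster_id: dict[int, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.provenance)

    def cell_ids(self) -> list[int]:
        return sorted(self.provenance)


@dataclass
class SegmentationResult:
    label_map: LabelMap
    density: DensityEstimate
    gray: np.ndarray
    preprocessed: np.ndarray
    reconstructed: np.ndarray  # marker-processed rendition (Imarker-like)
    candidate_mask: np.ndarray
    markers: MarkerSet


def triage_regions(
    cell_region: np.ndarray, markers: MarkerSet
) -> tuple[LabelMap, list[tuple[np.ndarray, np.ndarray]]]:
    """Split regions by marker count.

    Returns the single-cell label map plus, for each multi-marker region, a
    (region mask, marker label raster) pair queued for watershed.
    """
    rois, n = ndimage.label(cell_region, structure=_STRUCT8)
    counts: dict[int, list[int]] = {r: [] for r in range(1, n + 1)}
    for m, r in markers.roi_assignment.items():
        counts.setdefault(r, []).append(m)
    singles = np.zeros_like(rois)
    provenance: dict[int, str] = {}
    next_label = 1
    clusters: list[tuple[np.ndarray, np.ndarray]] = []
    for r in range(1, n + 1):
        ms = counts.get(r, [])
        if len(ms) == 0:
            continue
        region = rois == r
        if len(ms) == 1:
            singles[region] = next_label
            provenance[next_label] = "single"
            next_label += 1
        else:
            marker_raster = np.where(np.isin(markers.labels, ms), markers.labels, 0)
            clusters.append((region, marker_raster))
    return LabelMap(labels=singles, provenance=provenance), clusters


def watershed_cluster(
    region: np.ndarray, marker_raster: np.ndarray, relief: np.ndarray
) -> np.ndarray:
    """Marker-controlled watershed of one cluster region.

    Produces exactly one catchment label per marker, tiling the region except
    for the one-pixel ridge lines (left as 0).
    """
    marker_ids = np.unique(marker_raster)
    marker_ids = marker_ids[marker_ids > 0]
    if marker_ids.size < 2:
        raise ValueError("watershed_cluster requires >= 2 markers")
    if (marker_raster > 0).sum() != ((marker_raster > 0) & region).sum():
        raise ValueError("marker outside region violates the stage contract")
    return watershed(relief, markers=marker_raster, mask=region, watershed_line=True)


def _merge_clusters(
    base: LabelMap, clusters: list[tuple[np.ndarray, np.ndarray]], relief: np.ndarray
) -> LabelMap:
    labels = base.labels.copy()
    provenance = dict(base.provenance)
    cluster_id = dict(base.cluster_id)
    next_label = max(provenance, default=0) + 1
    for ci, (region, marker_raster) in enumerate(clusters, start=1):
        ws = watershed_cluster(region, marker_raster, relief)
        # renumber fragments in raster-scan order of their markers
        marker_ids = sorted(
            np.unique(marker_raster[marker_raster > 0]),
            key=lambda m: tuple(np.argwhere(marker_raster == m)[0]),
        )
        for m in marker_ids:
            frag = ws == m
            labels[frag] = next_label
            provenance[next_label] = "from_cluster"
            cluster_id[next_label] = ci
            next_label += 1
    return LabelMap(labels=labels, provenance=provenance, cluster_id=cluster_id)


def segment_image(
    img: np.ndarray, config: PipelineConfig | None = None
) -> SegmentationResult:
    """Run the full segmentation pipeline on one micrograph raster."""
    cfg = config or PipelineConfig()
    gray = to_grayscale(img)
    pre = preprocess_image(gray, cfg.preprocess)
    regions = detect_regions(pre, cfg.region_detect)
    markers, marker_img, _ = detect_markers(
        pre, regions.candidate_mask, cfg.marker_detect
    )
    singles, clusters = triage_regions(regions.candidate_mask, markers)
    label_map = _merge_clusters(singles, clusters, marker_img)
    return SegmentationResult(
        label_map=label_map,
        density=regions.density,
        gray=gray,
        preprocessed=pre,
        reconstructed=marker_img,
        candidate_mask=regions.candidate_mask,
        markers=markers,
    )
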