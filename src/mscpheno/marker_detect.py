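"""Marker detection inside candidate cell regions.

Phase-contrast cells are darkest in their interior (one prominent regional
minimum per cell, typically the nucleus), so markers are extracted as deep
regional minima of a smoothed, contrast-equalised rendition of the
preprocessed image. Two H-minima depths are combined: a high depth A that
under-detects but is precise, and a low depth B that recovers cells A misses
and fills in extra seeds inside large cluster regions. Over-segmentation is
then pruned by centroid distance and area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

from .config import MarkerParams

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class MarkerSet:
    """Labelled marker components and their region-of-interest assignment."""

    labels: np.ndarray  # int raster, 0 = background
    roi_assignment: dict[int, int] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.roi_assignment)

    def markers_in_roi(self, roi: int) -> list[int]:
        return [m for m, r in self.roi_assignment.items() if r == roi]


def _relabel(binary: np.ndarray, rois: np.ndarray) -> MarkerSet:
    """Label a marker binary, clip each marker to its ROI, assign by overlap."""
    binary = binary & (rois > 0)
    labels, n = ndimage.label(binary, structure=_STRUCT8)
    out = np.zeros_like(labels)
    assignment: dict[int, int] = {}
    next_label = 1
    for i in range(1, n + 1):
        comp = labels == i
        roi_vals, counts = np.unique(rois[comp], return_counts=True)
        # markers may straddle two ROIs after dilation: split per ROI
        for rv, _ in sorted(zip(roi_vals, counts), key=lambda t: -t[1]):
            if rv == 0:
                continue
            piece = comp & (rois == rv)
            if not piece.any():
                continue
            out[piece] = next_label
            assignment[next_label] = int(rv)
            next_label += 1
    return MarkerSet(labels=out, roi_assignment=assignment)


def prepare_marker_image(
    pre_img: np.ndarray, cell_region: np.ndarray, params: MarkerParams | None = None
) -> np.ndarray:
    """Produce the marker-detection rendition of the preprocessed image.

    Gaussian then median filtering suppress spurious local minima, CLAHE
    deepens the genuine ones, and a grayscale reconstruction by erosion with
    the region complement forced bright levels out every minimum lying outside
    the candidate cell regions.
    """
    p = params or MarkerParams()
    if pre_img.shape != cell_region.shape:
        raise ValueError("image and region shapes differ")
    out = ndimage.gaussian_filter(pre_img, sigma=p.gaussian_sigma)
    out = ndimage.median_filter(out, size=2 * p.median_radius + 1, mode="nearest")
    if np.ptp(out) > 0:
        kernel = (
            max(out.shape[0] // p.clahe_tiles[0], 2),
            max(out.shape[1] // p.clahe_tiles[1], 2),
        )
        out = exposure.equalize_adapthist(out, kernel_size=kernel, clip_limit=p.clahe_clip)
    seed = np.where(cell_region, out, 1.0)
    out = morphology.reconstruction(seed, np.minimum(seed, out), method="erosion")
    return np.clip(out, 0.0, 1.0)


def hminima_markers(
    img: np.ndarray,
    h: float,
    rois: np.ndarray,
    pass_type: str = "A",
    params: MarkerParams | None = None,
) -> MarkerSet:
    """Regional minima deeper than ``h`` inside ROIs, as labelled markers.

    The A (deep) pass cleans with a binary opening and a minimum-area removal;
    the B (shallow) pass dilates and closes its minima to make them usable as
    watershed seeds.
    """
    if not (0 < h < 1):
        raise ValueError("h must be in (0, 1)")
    p = params or MarkerParams()
    # extended minima: regional minima of the H-minima transform, i.e. the
    # full basin plateau of every minimum deeper than h
    suppressed = morphology.reconstruction(img + h, img, method="erosion")
    minima = morphology.local_minima(suppressed, connectivity=2)
    minima = minima.astype(bool) & (rois > 0)
    if pass_type == "A":
        keep = morphology.opening(minima, morphology.disk(1))
        keep = morphology.remove_small_objects(
            keep, max_size=int(p.min_marker_area) - 1, connectivity=2
        )
    elif pass_type == "B":
        keep = morphology.dilation(minima, morphology.disk(1))
        keep = morphology.closing(keep, morphology.disk(1))
    else:
        raise ValueError("pass_type must be 'A' or 'B'")
    return _relabel(keep, rois)


def _roi_perimeters(rois: np.ndarray) -> dict[int, float]:
    from skimage import measure

    out = {}
    for prop in measure.regionprops(rois):
        out[int(prop.label)] = float(prop.perimeter)
    return out


def combine_markers(
    markers_a: MarkerSet,
    markers_b: MarkerSet,
    rois: np.ndarray,
    cluster_perimeter_min: float = 400.0,
) -> MarkerSet:
    """Merge the two H-minima passes per ROI.

    Small ROIs with at least one deep (A) marker keep only those. ROIs with no
    deep marker fall back to the shallow (B) markers. Large-perimeter ROIs are
    potential clusters, so both passes are unioned (overlapping markers merge
    into one component).
    """
    perims = _roi_perimeters(rois)
    combined = np.zeros_like(rois, dtype=bool)
    for roi, perim in perims.items():
        a_ids = markers_a.markers_in_roi(roi)
        if perim >= cluster_perimeter_min:
            for m in a_ids:
                combined |= (markers_a.labels == m)
            for m in markers_b.markers_in_roi(roi):
                combined |= (markers_b.labels == m)
        elif a_ids:
            for m in a_ids:
                combined |= (markers_a.labels == m)
        else:
            for m in markers_b.markers_in_roi(roi):
                combined |= (markers_b.labels == m)
    return _relabel(combined, rois)


def prune_markers(
    markers: MarkerSet,
    min_centroid_distance: float = 15.0,
    min_marker_area: float = 20.0,
) -> MarkerSet:
    """Remove over-segmentation: within each ROI, greedily drop the
    smaller-area member of any marker pair closer than the centroid-distance
    threshold, then clean up with a closing and a minimum-area rule."""
    labels = markers.labels.copy()
    assignment = dict(markers.roi_assignment)
    rois_of: dict[int, list[int]] = {}
    for m, r in assignment.items():
        rois_of.setdefault(r, []).append(m)
    centroids = {}
    areas = {}
    for m in assignment:
        comp = labels == m
        ys, xs = np.nonzero(comp)
        centroids[m] = (ys.mean(), xs.mean())
        areas[m] = ys.size
    removed: set[int] = set()
    for roi, members in rois_of.items():
        alive = sorted(members)
        while True:
            worst = None
            for i, a in enumerate(alive):
                for b in alive[i + 1 :]:
                    d = np.hypot(
                        centroids[a][0] - centroids[b][0],
                        centroids[a][1] - centroids[b][1],
                    )
                    if d < min_centroid_distance:
                        if worst is None or d < worst[0]:
                            worst = (d, a, b)
            if worst is None:
                break
            _, a, b = worst
            if areas[a] < areas[b]:
                drop = a
            elif areas[b] < areas[a]:
                drop = b
            else:  # equal areas: deterministic tie-break on the larger label
                drop = max(a, b)
            removed.add(drop)
            alive.remove(drop)
    for m in removed:
        labels[labels == m] = 0
    # cleanup: per-ROI closing (dilation followed by erosion) and area floor
    roi_raster = np.zeros_like(labels)
    for m, r in assignment.items():
        if m not in removed:
            roi_raster[labels == m] = r
    binary = labels > 0
    binary = morphology.closing(binary, morphology.disk(1))
    out = _relabel(binary, _expand_rois(roi_raster, binary))
    # drop markers below the area floor
    final_labels = out.labels.copy()
    final_assignment = dict(out.roi_assignment)
    for m in list(final_assignment):
        if np.count_nonzero(final_labels == m) < min_marker_area:
            final_labels[final_labels == m] = 0
            del final_assignment[m]
    return MarkerSet(labels=final_labels, roi_assignment=final_assignment)


def _expand_rois(roi_raster: np.ndarray, binary: np.ndarray) -> np.ndarray:
    """Grow ROI identity onto closing-added pixels by nearest assignment."""
    if not (binary & (roi_raster == 0)).any():
        return roi_raster
    _, (iy, ix) = ndimage.distance_transform_edt(
        roi_raster == 0, return_indices=True
    )
    grown = roi_raster[iy, ix]
    out = roi_raster.copy()
    fill = binary & (roi_raster == 0)
    out[fill] = grown[fill]
    return out


def detect_markers(
    pre_img: np.ndarray,
    cell_region: np.ndarray,
    params: MarkerParams | None = None,
) -> tuple[MarkerSet, np.ndarray, np.ndarray]:
    """Full marker stage. Returns (markers, marker_image, roi label map)."""
    p = params or MarkerParams()
    rois, _ = ndimage.label(cell_region, structure=_STRUCT8)
    marker_img = prepare_marker_image(pre_img, cell_region, p)
    if not cell_region.any():
        return MarkerSet(labels=np.zeros_like(rois)), marker_img, rois
    a = hminima_markers(marker_img, p.h_threshold_A, rois, "A", p)
    b = hminima_markers(marker_img, p.h_threshold_B, rois, "B", p)
    combined = combine_markers(a, b, rois, p.cluster_perimeter_min)
    pruned = prune_markers(combined, p.min_centroid_distance, p.min_marker_area)
    # the closing in prune may leak a ring outside the region: clip back so
    # every marker lies wholly inside its assigned candidate region
    clipped = pruned.labels * cell_region
    assignment = {
        m: r for m, r in pruned.roi_assignment.items() if (clipped == m).any()
    }
    clipped[~np.isin(clipped, list(assignment) or [0])] = 0
    return MarkerSet(labels=clipped, roi_assignment=assignment), marker_img, rois
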