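"""Per-cell morphometric and textural features, measure selection and
correlation pruning.

Thirty named features are extracted per cell: 6 size, 6 shape, 9 first-order
intensity statistics and 9 gray-level co-occurrence (GLCM) statistics. The
intensity features are computed on three renditions of the micrograph — the
raw grayscale, the preprocessed image, and the morphological-reconstruction
output used for marker detection — giving 3 raw measures per first-order
feature. Each GLCM feature is additionally computed at 24 orientations,
giving 72 raw measures. For classification, exactly one measure per feature
is chosen on the training set by empirical ROC AUC, and features whose
selected measures are pairwise correlated above 0.8 are pruned in
descending-AUC order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure

from .config import FeatureParams

SIZE_FEATURES = ("area", "perimeter", "minor_axis", "major_axis", "width", "height")
SHAPE_FEATURES = (
    "elongation",
    "compactness",
    "circularity",
    "ellipticity",
    "solidity",
    "extent",
)
FIRST_ORDER_FEATURES = (
    "std",
    "variance",
    "intensity_profile",
    "skewness",
    "mean_intensity",
    "balance",
    "kurtosis",
    "median",
    "mode",
)
SECOND_ORDER_FEATURES = (
    "glcm_correlation",
    "glcm_inertia",
    "glcm_cluster_prominence",
    "glcm_energy",
    "glcm_entropy",
    "glcm_cluster_shade",
    "glcm_max_probability",
    "glcm_dissimilarity",
    "glcm_homogeneity",
)
ALL_FEATURES = SIZE_FEATURES + SHAPE_FEATURES + FIRST_ORDER_FEATURES + SECOND_ORDER_FEATURES

VARIANTS = ("gray", "preprocessed", "reconstructed")


def glcm_offsets(scheme: str = "angles24") -> list[tuple[str, tuple[int, int]]]:
    """Orientation set for the co-occurrence matrices.

    ``angles24``: 24 angles at 15-degree steps, pixel distance 1 (integer
    offsets obtained by rounding; neighbouring angles can share an offset).
    ``angles8x3dist``: 8 angles at 45-degree steps, distances 1..3.
    """
    out = []
    if scheme == "angles24":
        for k in range(24):
            theta = math.radians(15 * k)
            dr = -round(math.sin(theta))
            dc = round(math.cos(theta))
            out.append((f"a{15 * k:03d}", (dr, dc)))
    elif scheme == "angles8x3dist":
        for d in (1, 2, 3):
            for k in range(8):
                theta = math.radians(45 * k)
                dr = -round(d * math.sin(theta))
                dc = round(d * math.cos(theta))
                out.append((f"d{d}a{45 * k:03d}", (dr, dc)))
    else:
        raise ValueError(f"unknown GLCM scheme {scheme!r}")
    return out


@dataclass
class CellRecord:
    image_id: str
    cell_id: int
    raw_measures: dict[str, dict[str, float]]  # feature -> measure key -> value
    phenotype: str = "unknown"
    day: int | None = None
    selected: dict[str, float] = field(default_factory=dict)


@dataclass
class FeatureSelection:
    chosen: dict[str, str]  # feature -> measure key
    auc: dict[str, float]
    retained: list[str]  # descending AUC after correlation pruning

    def vector(self, record: CellRecord) -> np.ndarray:
        return np.array(
            [record.raw_measures[f][self.chosen[f]] for f in self.retained]
        )

    def to_dict(self) -> dict:
        return {"chosen": self.chosen, "auc": self.auc, "retained": self.retained}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSelection":
        return cls(chosen=dict(d["chosen"]), auc=dict(d["auc"]), retained=list(d["retained"]))


# ---------------------------------------------------------------- size/shape


def _props(mask: np.ndarray) -> measure._regionprops.RegionProperties:
    return measure.regionprops(mask.astype(np.uint8))[0]


def size_features(mask: np.ndarray, pixels_per_micron: float = 1.56) -> dict[str, float]:
    """Area (um^2), perimeter, moment-ellipse axes, bounding-box width/height (um)."""
    p = _props(mask)
    s = pixels_per_micron
    minr, minc, maxr, maxc = p.bbox
    return {
        "area": p.area / s**2,
        "perimeter": p.perimeter / s,
        "minor_axis": p.axis_minor_length / s,
        "major_axis": p.axis_major_length / s,
        "width": (maxc - minc) / s,
        "height": (maxr - minr) / s,
    }


def shape_features(mask: np.ndarray, elongation_cap: float = 100.0) -> dict[str, float]:
    p = _props(mask)
    area = float(p.area)
    perim = float(p.perimeter)
    m1 = float(p.axis_major_length)
    m2 = float(p.axis_minor_length)
    circ = min(4.0 * np.pi * area / perim**2, 1.0) if perim > 0 else 1.0
    return {
        "elongation": min(m1 / m2, elongation_cap) if m2 > 0 else elongation_cap,
        "compactness": perim**2 / (4.0 * np.pi * area),
        "circularity": circ,
        "ellipticity": (m1 - m2) / m1 if m1 > 0 else 0.0,
        "solidity": float(p.solidity),
        "extent": float(p.extent),
    }


# ---------------------------------------------------------------- first order


def first_order_features(mask: np.ndarray, image: np.ndarray) -> dict[str, float]:
    """Nine intensity statistics over the masked pixels.

    'intensity_profile' is the interdecile range (q90 - q10) and 'balance' is
    the mean-median skew (mean - median)/std (0 for a constant region); the
    mode is taken over intensities discretised to 8-bit steps.
    """
    vals = image[mask.astype(bool)].astype(np.float64)
    mean = vals.mean()
    median = float(np.median(vals))
    std = vals.std()
    q10, q90 = np.quantile(vals, [0.10, 0.90])
    quant = np.round(vals * 255).astype(int)
    mode = float(np.bincount(quant).argmax()) / 255.0
    if std == 0:
        skew = kurt = balance = 0.0
    else:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals, fisher=False))
        balance = (mean - median) / std
    return {
        "std": float(std),
        "variance": float(vals.var()),
        "intensity_profile": float(q90 - q10),
        "skewness": skew,
        "mean_intensity": float(mean),
        "balance": float(balance),
        "kurtosis": kurt,
        "median": median,
        "mode": mode,
    }


# ---------------------------------------------------------------- second order


def quantize(image: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Quantize masked intensities to ``levels`` gray levels over the mask's
    own intensity range. Returns -1 outside the mask."""
    out = np.full(image.shape, -1, dtype=np.int32)
    vals = image[mask.astype(bool)]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int32)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros(image.shape, dtype=np.int32)
    out[mask.astype(bool)] = q[mask.astype(bool)]
    return out


def glcm_matrix(
    quantized: np.ndarray, offset: tuple[int, int], levels: int
) -> np.ndarray:
    """Symmetric, normalised co-occurrence matrix over pixel pairs that are
    both inside the mask (quantized >= 0) at the given (drow, dcol) offset."""
    dr, dc = offset
    h, w = quantized.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = quantized[r0s:r0e, c0s:c0e]
    b = quantized[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        return np.zeros((levels, levels))
    pairs = a[valid] * levels + b[valid]
    counts = np.bincount(pairs, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T  # symmetric
    return counts / counts.sum()


def glcm_statistics(p: np.ndarray) -> dict[str, float]:
    """The nine Haralick-family statistics of a normalised GLCM."""
    levels = p.shape[0]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = (i * px).sum()
    sig_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    # symmetric matrix: the j marginal equals the i marginal
    mu_y, sig_y = mu_x, sig_x
    if sig_x > 0:
        corr = float((((ii - mu_x) * (jj - mu_y) * p).sum()) / (sig_x * sig_y))
    else:
        corr = 1.0
    dev = ii + jj - mu_x - mu_y
    nz = p[p > 0]
    return {
        "glcm_correlation": corr,
        "glcm_inertia": float(((ii - jj) ** 2 * p).sum()),
        "glcm_cluster_prominence": float((dev**4 * p).sum()),
        "glcm_energy": float((p**2).sum()),
        "glcm_entropy": float(-(nz * np.log2(nz)).sum()),
        "glcm_cluster_shade": float((dev**3 * p).sum()),
        "glcm_max_probability": float(p.max()),
        "glcm_dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "glcm_homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
    }


def glcm_features(
    mask: np.ndarray,
    image: np.ndarray,
    offset: tuple[int, int],
    levels: int = 32,
) -> dict[str, float]:
    q = quantize(image, mask, levels)
    p = glcm_matrix(q, offset, levels)
    if p.sum() == 0:
        warnings.warn("cell has no valid pixel pairs at this offset", stacklevel=2)
        return {k: 0.0 for k in SECOND_ORDER_FEATURES}
    return glcm_statistics(p)


# ---------------------------------------------------------------- extraction


def extract_cell_record(
    mask: np.ndarray,
    variants: dict[str, np.ndarray],
    image_id: str,
    cell_id: int,
    pixels_per_micron: float = 1.56,
    params: FeatureParams | None = None,
    phenotype: str = "unknown",
    day: int | None = None,
) -> CellRecord:
    """Extract all raw measures of the 30 features for one cell mask.

    ``variants`` must map the three rendition names ('gray', 'preprocessed',
    'reconstructed') to same-shaped rasters.
    """
    fp = params or FeatureParams()
    if set(variants) != set(VARIANTS):
        raise ValueError(f"variants must be exactly {VARIANTS}")
    raw: dict[str, dict[str, float]] = {}
    for name, value in size_features(mask, pixels_per_micron).items():
        raw[name] = {"geom": value}
    for name, value in shape_features(mask, fp.elongation_cap).items():
        raw[name] = {"geom": value}
    for variant in VARIANTS:
        fo = first_order_features(mask, variants[variant])
        for name, value in fo.items():
            raw.setdefault(name, {})[variant] = value
    offsets = glcm_offsets(fp.glcm_scheme)
    for variant in VARIANTS:
        q = quantize(variants[variant], mask, fp.glcm_levels)
        for key, offset in offsets:
            p = glcm_matrix(q, offset, fp.glcm_levels)
            if p.sum() == 0:
                st = {k: 0.0 for k in SECOND_ORDER_FEATURES}
            else:
                st = glcm_statistics(p)
            for name, value in st.items():
                raw.setdefault(name, {})[f"{variant}:{key}"] = value
    return CellRecord(
        image_id=image_id,
        cell_id=cell_id,
        raw_measures=raw,
        phenotype=phenotype,
        day=day,
    )


def extract_records(
    label_map: np.ndarray,
    variants: dict[str, np.ndarray],
    image_id: str,
    pixels_per_micron: float = 1.56,
    params: FeatureParams | None = None,
    phenotypes: dict[int, str] | None = None,
    day: int | None = None,
) -> list[CellRecord]:
    records = []
    for cid in sorted(set(np.unique(label_map)) - {0}):
        mask = label_map == cid
        if mask.sum() < 5:
            continue
        records.append(
            extract_cell_record(
                mask,
                variants,
                image_id,
                int(cid),
                pixels_per_micron,
                params,
                phenotype=(phenotypes or {}).get(int(cid), "unknown"),
                day=day,
            )
        )
    return records


# ---------------------------------------------------------------- selection


def _empirical_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney empirical ROC AUC of values against binary labels,
    folded as max(AUC, 1-AUC) so either direction of separation counts."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required to compute AUC")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (len(pos) * len(neg))
    return float(max(auc, 1.0 - auc))


def select_best_measure(records: list[CellRecord]) -> FeatureSelection:
    """Per feature, choose the raw measure with the highest folded AUC for
    separating RS from SR on the training records (ties to scan order)."""
    labels = np.array([1 if r.phenotype == "SR" else 0 for r in records])
    if len(set(labels)) < 2:
        raise ValueError("training records must contain both phenotypes")
    chosen: dict[str, str] = {}
    aucs: dict[str, float] = {}
    for feature in ALL_FEATURES:
        best_key, best_auc = None, -1.0
        for key in records[0].raw_measures[feature]:
            vals = np.array([r.raw_measures[feature][key] for r in records])
            auc = _empirical_auc(vals, labels)
            if auc > best_auc:
                best_key, best_auc = key, auc
        chosen[feature] = best_key
        aucs[feature] = best_auc
    order = sorted(ALL_FEATURES, key=lambda f: -aucs[f])
    return FeatureSelection(chosen=chosen, auc=aucs, retained=order)


def correlation_filter(
    selection: FeatureSelection,
    records: list[CellRecord],
    max_corr: float = 0.8,
) -> FeatureSelection:
    """Greedy prune in descending-AUC order: drop any feature whose selected
    measure correlates (|Pearson r| > max_corr) with an already-kept one."""
    order = sorted(selection.chosen, key=lambda f: -selection.auc[f])
    values = {
        f: np.array([r.raw_measures[f][selection.chosen[f]] for r in records])
        for f in order
    }
    kept: list[str] = []
    for f in order:
        ok = True
        for g in kept:
            x, y = values[f], values[g]
            if x.std() == 0 or y.std() == 0:
                r = 1.0 if (x.std() == 0 and y.std() == 0) else 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) > max_corr:
                ok = False
                break
        if ok:
            kept.append(f)
    return FeatureSelection(chosen=dict(selection.chosen), auc=dict(selection.auc), retained=kept)
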