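"""Reading and writing images, instance label maps and cell tables.

Conventions: intensities are mapped to float [0, 1] at load time; label maps
are 16-bit single-channel rasters with 0 = background; cell tables are UTF-8
CSV with a header row. Coordinates are row-major, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

PHENOTYPES = ("RS", "SR", "unknown")


class FormatError(ValueError):
    """Unsupported sample format or malformed file."""


class ConsistencyError(ValueError):
    """Ground-truth label map and cell table disagree."""


@dataclass
class CellTableRow:
    image_id: str
    cell_id: int
    phenotype: str = "unknown"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8/16-bit PNG or TIFF and map intensities to float [0, 1].

    RGB images come back as (H, W, 3); grayscale as (H, W).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"unreadable image file: {path}") from exc
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise FormatError(f"unsupported sample format {arr.dtype} in {path}")
    img = arr.astype(np.float64) / scale
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if img.ndim not in (2, 3):
        raise FormatError(f"unsupported image dimensionality {arr.ndim}")
    return np.clip(img, 0.0, 1.0)


def write_image(img: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Write a [0, 1] float raster as an 8- or 16-bit PNG/TIFF."""
    if bit_depth == 16:
        out = np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)
    elif bit_depth == 8:
        out = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
    else:
        raise FormatError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), out)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an instance label map as a 16-bit single-channel image."""
    if labels.min() < 0 or labels.max() > 65535:
        raise FormatError("labels must fit in uint16")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def load_label_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError("label map must be single-channel")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError("label map must be an integer raster")
    return arr.astype(np.int32)


def load_truth(
    labelmap_path: str | Path, table_path: str | Path
) -> tuple[np.ndarray, list[CellTableRow]]:
    """Load a ground-truth instance map plus its cell table.

    Every nonzero label in the map must have exactly one table row and vice
    versa; violations raise :class:`ConsistencyError`.
    """
    labels = load_label_map(labelmap_path)
    table = pd.read_csv(table_path)
    required = {"image_id", "cell_id", "phenotype"}
    if not required.issubset(table.columns):
        raise FormatError(f"cell table must have columns {sorted(required)}")
    if table.duplicated(subset=["image_id", "cell_id"]).any():
        raise ConsistencyError("duplicate (image_id, cell_id) rows in cell table")
    rows = [
        CellTableRow(
            image_id=str(r.image_id),
            cell_id=int(r.cell_id),
            phenotype=str(r.phenotype),
            score=float(r.score) if "score" in table.columns and pd.notna(getattr(r, "score", None)) else None,
        )
        for r in table.itertuples()
    ]
    map_labels = set(np.unique(labels)) - {0}
    table_labels = {r.cell_id for r in rows}
    if map_labels != table_labels:
        missing = sorted(map_labels - table_labels)
        extra = sorted(table_labels - map_labels)
        raise ConsistencyError(
            f"label map / table mismatch: labels without rows {missing}, "
            f"rows without labels {extra}"
        )
    return labels, rows


def write_cell_table(records: Iterable[dict], path: str | Path) -> None:
    """Write per-cell records (geometry, features, prediction) as CSV.

    An empty record list produces a header-only file with the identity
    columns.
    """
    records = list(records)
    if records:
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.DataFrame(columns=["image_id", "cell_id", "phenotype"])
    df.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
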