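"""Seeded synthetic phase-contrast-like micrographs with exact truth.

The generator does not simulate phase optics; it reproduces the intensity
ordering the segmentation pipeline exploits — bright halo rim > substrate >
cell body > nuclear minimum — on a mid-gray textured background. Cells are
smoothed super-ellipses: rapidly self-replicating (RS) cells are drawn
spindle-shaped (elongation >= 2.5, prominent halo), slowly replicating (SR)
cells flattened and rhomboid (elongation <= 1.8, larger area, weaker halo).
Each cell carries exactly one dark nuclear pit so marker counts are
well-defined, and the truth mask is the exact set of body pixels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import morphology

from . import io as mio

BACKGROUND = 0.5
BODY_LEVEL = 0.40
SUPERELLIPSE_N = 2.2


@dataclass
class FixtureCellSpec:
    phenotype: str  # "RS" | "SR"
    center: tuple[float, float]  # (row, col)
    orientation: float  # radians
    major_axis: float  # full length, px
    minor_axis: float
    halo_gain: float
    nucleus_depth: float
    membership: int = 0  # 0 = single, else cluster id
    # ruffled-boundary modulation: real MSC outlines are irregular, which is
    # what keeps their circularity well below that of round debris
    wobble_amp: float = 0.12
    wobble_lobes: int = 6
    wobble_phase: float = 0.0


@dataclass
class FixtureImage:
    image_id: str
    seed: int
    n_cells: int
    area_fraction_request: float | None
    cells: list[FixtureCellSpec] = field(default_factory=list)


@dataclass
class FixtureManifest:
    seed: int
    preset: str | None
    images: list[FixtureImage] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "preset": self.preset,
                "images": [asdict(im) for im in self.images],
            },
            indent=2,
        )


def _body_mask(spec: FixtureCellSpec, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dy = rr - spec.center[0]
    dx = cc - spec.center[1]
    u = np.cos(spec.orientation) * dx + np.sin(spec.orientation) * dy
    v = -np.sin(spec.orientation) * dx + np.cos(spec.orientation) * dy
    a = spec.major_axis / 2.0
    b = spec.minor_axis / 2.0
    n = SUPERELLIPSE_N
    rho = (np.abs(u / a) ** n + np.abs(v / b) ** n) ** (1.0 / n)
    phi = np.arctan2(v / b, u / a)
    radius = 1.0 + spec.wobble_amp * np.sin(spec.wobble_lobes * phi + spec.wobble_phase)
    return rho <= radius


def render_cell(
    spec: FixtureCellSpec, canvas: np.ndarray, margin: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one cell onto ``canvas`` and return (canvas, truth body mask).

    The body is set darker than background, a 2-px halo rim brighter by
    ``halo_gain``, and one Gaussian nuclear pit of depth ``nucleus_depth`` is
    sunk at the cell centre.
    """
    shape = canvas.shape
    body = _body_mask(spec, shape)
    if not body.any():
        raise ValueError("cell body is empty")
    rows, cols = np.nonzero(body)
    if (
        rows.min() < margin
        or cols.min() < margin
        or rows.max() >= shape[0] - margin
        or cols.max() >= shape[1] - margin
    ):
        raise ValueError("cell placement violates the border margin")
    halo = morphology.dilation(body, morphology.disk(2)) & ~body
    canvas[body] = BODY_LEVEL
    canvas[halo] = BACKGROUND + spec.halo_gain
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    sigma = max(spec.minor_axis * 0.18, 2.0)
    pit = spec.nucleus_depth * np.exp(
        -((rr - spec.center[0]) ** 2 + (cc - spec.center[1]) ** 2) / (2 * sigma**2)
    )
    canvas[body] -= pit[body]
    return canvas, body


DEFAULT_ELONGATION = {"RS": (2.5, 4.0), "SR": (1.15, 1.8)}


def _sample_cell(
    rng: np.random.Generator,
    phenotype: str,
    center: tuple[float, float],
    orientation: float | None = None,
    membership: int = 0,
    elongation: dict[str, tuple[float, float]] | None = None,
) -> FixtureCellSpec:
    theta = rng.uniform(0, np.pi) if orientation is None else orientation
    elong_lo, elong_hi = (elongation or DEFAULT_ELONGATION)[phenotype]
    elong = rng.uniform(elong_lo, elong_hi)
    if phenotype == "RS":
        major = rng.uniform(60, 85)
        halo_gain = rng.uniform(0.30, 0.38)
        wobble_amp = rng.uniform(0.16, 0.26)
        wobble_lobes = int(rng.integers(4, 7))
    else:
        # rhomboid cells are drawn more ruffled: elongation alone does not
        # carry their irregularity, so the boundary modulation does
        major = rng.uniform(55, 75)
        halo_gain = rng.uniform(0.18, 0.26)
        wobble_amp = rng.uniform(0.22, 0.32)
        wobble_lobes = int(rng.integers(5, 9))
    return FixtureCellSpec(
        phenotype=phenotype,
        center=center,
        orientation=float(theta),
        major_axis=float(major),
        minor_axis=float(major / elong),
        halo_gain=float(halo_gain),
        nucleus_depth=float(rng.uniform(0.22, 0.30)),
        membership=membership,
        wobble_amp=float(wobble_amp),
        wobble_lobes=wobble_lobes,
        wobble_phase=float(rng.uniform(0, 2 * np.pi)),
    )


def _artifact(canvas: np.ndarray, rng: np.random.Generator, kind: str, margin: int) -> None:
    """Debris the region filter should remove: near-circular blobs and thin
    bright fibers (both with uniform, substrate-like interiors)."""
    h, w = canvas.shape
    if kind == "disk":
        r = rng.uniform(8, 14)
        cy = rng.uniform(margin + r + 3, h - margin - r - 3)
        cx = rng.uniform(margin + r + 3, w - margin - r - 3)
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        blob = (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
        canvas[blob] = BACKGROUND + 0.12
    else:  # fiber
        length = rng.uniform(60, 100)
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(margin + length / 2 + 3, h - margin - length / 2 - 3)
        cx = rng.uniform(margin + length / 2 + 3, w - margin - length / 2 - 3)
        t = np.linspace(-length / 2, length / 2, int(length * 2))
        ys = np.clip(np.round(cy + t * np.sin(theta)).astype(int), 0, h - 1)
        xs = np.clip(np.round(cx + t * np.cos(theta)).astype(int), 0, w - 1)
        fiber = np.zeros_like(canvas, dtype=bool)
        fiber[ys, xs] = True
        fiber = morphology.dilation(fiber, morphology.disk(1))
        canvas[fiber] = BACKGROUND + 0.15


def generate_image(
    n_single: int = 5,
    clusters: list[int] | None = None,
    density_target: float | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    rs_fraction: float = 0.65,
    n_artifacts: int = 0,
    image_id: str = "img",
    max_tries: int = 200,
    gap: int = 8,
    elongation: dict[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, FixtureImage]:
    """Generate one synthetic micrograph.

    Returns (image, truth label map, manifest entry). Cells never touch the
    border; singles never touch each other; cells within a declared cluster
    overlap slightly along their flanks. If ``density_target`` is given,
    extra single cells are added until the dilated cell footprint (a proxy
    for the initial region mask) reaches that area fraction.

    Difficulty is tunable: ``noise_sd`` sets background noise, ``gap`` the
    minimum single-cell separation in px, and ``elongation`` optionally
    overrides the per-phenotype elongation sampling ranges (defaults:
    RS 2.5-4.0, SR 1.15-1.8).
    """
    rng = np.random.default_rng(seed)
    clusters = list(clusters or [])
    canvas = np.full(shape, BACKGROUND, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)
    occupancy = np.zeros(shape, dtype=bool)
    margin = 14
    specs: list[FixtureCellSpec] = []
    next_label = 1

    def try_place_single(membership: int = 0) -> bool:
        nonlocal next_label
        for _ in range(max_tries):
            center = (
                rng.uniform(margin + 45, shape[0] - margin - 45),
                rng.uniform(margin + 45, shape[1] - margin - 45),
            )
            phenotype = "RS" if rng.random() < rs_fraction else "SR"
            spec = _sample_cell(rng, phenotype, center, membership=membership, elongation=elongation)
            body = _body_mask(spec, shape)
            rows, cols = np.nonzero(body)
            if rows.size == 0:
                continue
            if (
                rows.min() < margin
                or cols.min() < margin
                or rows.max() >= shape[0] - margin
                or cols.max() >= shape[1] - margin
            ):
                continue
            footprint = morphology.dilation(body, morphology.disk(gap))
            if (footprint & occupancy).any():
                continue
            render_cell(spec, canvas)
            labels[body] = next_label
            occupancy[:] |= footprint
            specs.append(spec)
            next_label += 1
            return True
        return False

    def try_place_cluster(size: int, cluster_id: int) -> bool:
        nonlocal next_label
        for _ in range(max_tries):
            theta = rng.uniform(0, np.pi)
            start = (
                rng.uniform(margin + 60, shape[0] - margin - 60),
                rng.uniform(margin + 60, shape[1] - margin - 60),
            )
            members: list[FixtureCellSpec] = []
            ok = True
            offset = 0.0
            prev_b = None
            for i in range(size):
                phenotype = "RS" if rng.random() < rs_fraction else "SR"
                spec = _sample_cell(
                    rng, phenotype, start, orientation=theta, membership=cluster_id, elongation=elongation
                )
                b = spec.minor_axis / 2.0
                if prev_b is not None:
                    offset += (prev_b + b) * 0.92
                prev_b = b
                # stack members side-by-side along the minor-axis direction
                center = (
                    start[0] + offset * np.cos(theta),
                    start[1] - offset * np.sin(theta),
                )
                spec.center = (float(center[0]), float(center[1]))
                members.append(spec)
            bodies = []
            for spec in members:
                body = _body_mask(spec, shape)
                rows, cols = np.nonzero(body)
                if (
                    rows.size == 0
                    or rows.min() < margin
                    or cols.min() < margin
                    or rows.max() >= shape[0] - margin
                    or cols.max() >= shape[1] - margin
                ):
                    ok = False
                    break
                bodies.append(body)
            if not ok:
                continue
            union = np.logical_or.reduce(bodies)
            footprint = morphology.dilation(union, morphology.disk(gap))
            if (footprint & occupancy).any():
                continue
            for spec, body in zip(members, bodies):
                render_cell(spec, canvas)
                labels[body & (labels == 0)] = next_label
                specs.append(spec)
                next_label += 1
            occupancy[:] |= footprint
            return True
        return False

    placed_all = True
    for _ in range(n_single):
        placed_all &= try_place_single()
    for ci, size in enumerate(clusters, start=1):
        placed_all &= try_place_cluster(size, ci)
    if not placed_all:
        raise RuntimeError("infeasible packing: could not place all requested cells")
    if density_target is not None:
        # proxy for the initial-region footprint: body+halo dilated as the
        # region stage's connect/fill step would inflate it
        def measured() -> float:
            foot = morphology.dilation(labels > 0, morphology.disk(5))
            return float(foot.sum()) / labels.size

        guard = 0
        while measured() < density_target and guard < 200:
            if not try_place_single():
                break
            guard += 1
    for _ in range(n_artifacts):
        _artifact(canvas, rng, "disk" if rng.random() < 0.5 else "fiber", margin)
    # gentle smoothing of the drawn edges, then background texture
    canvas = ndimage.gaussian_filter(canvas, sigma=0.8)
    yy, xx = np.meshgrid(
        np.linspace(0, 2 * np.pi, shape[0]), np.linspace(0, 2 * np.pi, shape[1]), indexing="ij"
    )
    phase = rng.uniform(0, 2 * np.pi, size=2)
    shading = 0.01 * np.sin(yy + phase[0]) * np.cos(xx + phase[1])
    canvas = canvas + shading
    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, size=shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    entry = FixtureImage(
        image_id=image_id,
        seed=seed,
        n_cells=len(specs),
        area_fraction_request=density_target,
        cells=specs,
    )
    return canvas, labels, entry


PRESETS = {
    # early expansion: sparse, mostly isolated cells (area fraction < 0.1)
    "day2": {"n_single": 5, "clusters": [], "noise_sd": 0.01, "n_artifacts": 1},
    # mid-log expansion: more cells and touching clusters (area fraction >= 0.1)
    "day4": {
        "n_single": 6,
        "clusters": [2, 3],
        "noise_sd": 0.01,
        "n_artifacts": 1,
        "density_target": 0.15,
    },
}


def generate_dataset(
    preset: str = "day2",
    n_images: int = 5,
    seed: int = 0,
    out_dir: str | Path | None = None,
    shape: tuple[int, int] = (512, 512),
    rs_fraction: float = 0.65,
    overrides: dict | None = None,
) -> tuple[FixtureManifest, list[tuple[np.ndarray, np.ndarray, dict[int, str]]]]:
    """Generate a dataset of fixture images with truth.

    Returns the manifest and a list of (image, label map, phenotype-by-label)
    triples; when ``out_dir`` is given, also writes PNG images, 16-bit label
    maps, per-image cell tables and the manifest JSON in the package's truth
    format.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    params = dict(PRESETS[preset])
    params.update(overrides or {})
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_images)]
    manifest = FixtureManifest(seed=seed, preset=preset)
    data = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(child_seeds):
        image_id = f"{preset}_{i:03d}"
        img, labels, entry = generate_image(
            seed=s,
            shape=shape,
            rs_fraction=rs_fraction,
            image_id=image_id,
            **params,
        )
        phenotypes = {}
        label_ids = sorted(set(np.unique(labels)) - {0})
        for lid, spec in zip(label_ids, entry.cells):
            phenotypes[int(lid)] = spec.phenotype
        manifest.images.append(entry)
        data.append((img, labels, phenotypes))
        if out is not None:
            mio.write_image(img, out / f"{image_id}.png", bit_depth=16)
            mio.write_label_map(labels, out / f"{image_id}_labels.png")
            mio.write_cell_table(
                [
                    {"image_id": image_id, "cell_id": lid, "phenotype": phenotypes[lid]}
                    for lid in label_ids
                ],
                out / f"{image_id}_cells.csv",
            )
    if out is not None:
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest, data
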