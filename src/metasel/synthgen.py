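"""Synthetic metaphase-spread generator with per-object ground truth.

Renders dark, transversely banded chromosome bodies (straight and bent),
fused crossing clusters, and small/large debris blobs on a light
background, so the whole segmentation/classification pipeline can be
exercised and scored without real microscopy data.

Bodies are drawn as a stadium around a centerline: a vertical segment for
straight objects, a circular arc whose tangent turns by ``bend_deg`` for
bent ones.  Banding is a sinusoidal intensity modulation along arclength;
it changes gray levels only, never the binary mask.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .imaging import SegmentedObject

__all__ = [
    "SynthSpec",
    "GroundTruthRecord",
    "render_chromosome",
    "render_spread",
    "write_spread",
    "generate_batch",
    "read_ground_truth",
    "match_objects",
]

BACKGROUND = 230
BODY_MEAN = 90
_CENTERLINE_STEP = 0.5
_PLACEMENT_RETRIES = 1000
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic spread.  ``seed`` fixes the full output."""

    image_size: tuple[int, int] = (512, 512)
    n_straight: int = 10
    n_bent: int = 4
    n_overlap_clusters: int = 2
    n_debris: int = 3
    chrom_width_px: float = 8.0
    chrom_len_range_px: tuple[float, float] = (45.0, 75.0)
    bend_angle_range_deg: tuple[float, float] = (40.0, 70.0)
    band_contrast: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_straight, self.n_bent, self.n_overlap_clusters, self.n_debris) < 0:
            raise ValueError("counts must be >= 0")
        if self.chrom_width_px < 2:
            raise ValueError("chrom_width_px must be >= 2")
        lo, hi = self.chrom_len_range_px
        if not 0 < lo <= hi:
            raise ValueError("invalid chrom_len_range_px")
        if lo <= self.chrom_width_px:
            raise ValueError("chromosome length must exceed width")
        if not 0.0 <= self.band_contrast <= 1.0:
            raise ValueError("band_contrast must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruthRecord:
    """One rendered connected component and its intended class."""

    object_id: int
    true_class: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # r0, c0, r1, c1 (exclusive)


def _centerline(length_px: float, bend_deg: float) -> np.ndarray:
    """(N, 2) array of (row, col) points; a vertical run or a circular arc."""
    n = max(int(np.ceil(length_px / _CENTERLINE_STEP)) + 1, 2)
    s = np.linspace(0.0, length_px, n)
    if abs(bend_deg) < 1e-9:
        return np.column_stack([s, np.zeros_like(s)])
    theta = np.deg2rad(bend_deg)
    radius = length_px / abs(theta)
    t = s / radius
    rows = radius * np.sin(t)
    cols = np.sign(theta) * radius * (1.0 - np.cos(t))
    return np.column_stack([rows, cols])


def _stamp(path: np.ndarray, width_px: float, band_contrast: float,
           band_period: float) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a stadium of ``width_px`` around a centerline.

    Returns (gray tile uint8, bool mask), tight-cropped with the
    background at BACKGROUND.
    """
    half = width_px / 2.0
    margin = int(np.ceil(half)) + 1
    shifted = path - path.min(axis=0) + margin
    h = int(np.ceil(shifted[:, 0].max())) + margin + 1
    w = int(np.ceil(shifted[:, 1].max())) + margin + 1
    rr, cc = np.mgrid[0:h, 0:w]
    pix = np.column_stack([rr.ravel(), cc.ravel()])
    dist, idx = cKDTree(shifted).query(pix, k=1)
    mask = (dist <= half).reshape(h, w)
    arclen = (idx * _CENTERLINE_STEP).reshape(h, w)
    amp = 55.0 * band_contrast
    gray = BODY_MEAN + amp * np.sin(2.0 * np.pi * arclen / band_period)
    tile = np.full((h, w), float(BACKGROUND))
    tile[mask] = gray[mask]
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return np.clip(np.rint(tile[sl]), 0, 255).astype(np.uint8), mask[sl]


def render_chromosome(
    length_px: float,
    width_px: float,
    bend_deg: float,
    band_contrast: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one chromosome body tile (gray uint8, bool mask).

    ``bend_deg`` is the total turn of the centerline tangent: 0 gives a
    straight vertical body, larger values an increasingly curved one.
    """
    if width_px < 2:
        raise ValueError("width_px must be >= 2")
    if length_px <= width_px:
        raise ValueError("length_px must exceed width_px")
    period = max(4.0, 1.1 * width_px) * float(rng.uniform(0.9, 1.1))
    return _stamp(_centerline(length_px, bend_deg), width_px, band_contrast, period)


def _rotate_tile(tile: np.ndarray, mask: np.ndarray, angle_deg: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    mask_r = ndi.rotate(mask.astype(np.uint8), angle_deg, order=0, reshape=True) > 0
    tile_r = ndi.rotate(tile, angle_deg, order=0, reshape=True, cval=BACKGROUND)
    rows = np.flatnonzero(mask_r.any(axis=1))
    cols = np.flatnonzero(mask_r.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    tile_r = tile_r[sl].copy()
    mask_r = mask_r[sl]
    tile_r[~mask_r] = BACKGROUND
    return tile_r, mask_r


def _paste_centered(canvas: np.ndarray, occ: np.ndarray, tile: np.ndarray,
                    mask: np.ndarray, center: tuple[int, int]) -> None:
    h, w = mask.shape
    r0 = center[0] - h // 2
    c0 = center[1] - w // 2
    view_c = canvas[r0:r0 + h, c0:c0 + w]
    view_o = occ[r0:r0 + h, c0:c0 + w]
    view_c[mask] = np.minimum(view_c[mask], tile[mask])
    view_o[mask] = True


def _render_cluster(spec: SynthSpec, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Fuse 2-3 straight bodies crossing near a common center (class 3)."""
    n_bodies = int(rng.integers(2, 4))
    if n_bodies == 2:
        angles = [rng.uniform(-10, 10), rng.uniform(70, 90)]
    else:
        base = rng.uniform(-10, 10)
        angles = [base, base + 60 + rng.uniform(-10, 10),
                  base + 120 + rng.uniform(-10, 10)]
    size = int(np.ceil(spec.chrom_len_range_px[1] * 1.8))
    canvas = np.full((size, size), np.uint8(BACKGROUND))
    occ = np.zeros((size, size), dtype=bool)
    center = (size // 2, size // 2)
    for angle in angles:
        length = rng.uniform(*spec.chrom_len_range_px)
        tile, mask = render_chromosome(
            length, spec.chrom_width_px, rng.uniform(0, 10),
            spec.band_contrast, rng,
        )
        tile, mask = _rotate_tile(tile, mask, angle)
        jitter = (int(rng.integers(-3, 4)), int(rng.integers(-3, 4)))
        _paste_centered(canvas, occ, tile, mask,
                        (center[0] + jitter[0], center[1] + jitter[1]))
    labels, n = ndi.label(occ, structure=_EIGHT)
    if n > 1:
        # keep the largest component; crossing at the center makes this rare
        counts = np.bincount(labels.ravel())[1:]
        occ = labels == (int(np.argmax(counts)) + 1)
        canvas = canvas.copy()
        canvas[~occ] = BACKGROUND
    rows = np.flatnonzero(occ.any(axis=1))
    cols = np.flatnonzero(occ.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return canvas[sl], occ[sl]


def _render_small_debris(spec: SynthSpec, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Round blob clearly narrower than a chromosome (class 4, small)."""
    radius = rng.uniform(0.29, 0.36) * spec.chrom_width_px
    size = int(np.ceil(radius * 2)) + 3
    rr, cc = np.mgrid[0:size, 0:size] - (size - 1) / 2.0
    mask = np.hypot(rr, cc) <= radius
    tile = np.full((size, size), np.uint8(BACKGROUND))
    tile[mask] = np.uint8(BODY_MEAN + rng.integers(-15, 16))
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return tile[sl], mask[sl]


def _render_large_debris(spec: SynthSpec, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Wide elliptical blob with a wobbly outline (class 4, large)."""
    b = rng.uniform(0.95, 1.15) * spec.chrom_width_px
    a = b * rng.uniform(1.2, 1.4)
    k = int(rng.integers(2, 4))
    phase = rng.uniform(0, 2 * np.pi)
    size = int(np.ceil(a * 2.6))
    rr, cc = np.mgrid[0:size, 0:size] - (size - 1) / 2.0
    theta = np.arctan2(cc, rr)
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    wobble = 1.0 + 0.10 * np.sin(k * theta + phase)
    mask = np.hypot(rr, cc) <= r_ell * wobble
    tile = np.full((size, size), np.uint8(BACKGROUND))
    tile[mask] = np.uint8(BODY_MEAN + rng.integers(-10, 11))
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return tile[sl], mask[sl]


def render_spread(spec: SynthSpec) -> tuple[np.ndarray, list[GroundTruthRecord]]:
    """Render a full spread image plus its ground-truth object list.

    Non-cluster objects are placed mutually non-touching (a dilated-mask
    collision test keeps an 8-connectivity gap), so at ``noise_sd = 0``
    segmentation recovers exactly one component per ground-truth record.

    Raises
    ------
    RuntimeError
        When rejection-sampling placement exceeds its retry budget
        (overcrowded spec).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    canvas = np.full((h, w), float(BACKGROUND))
    occupancy = np.zeros((h, w), dtype=bool)
    records: list[GroundTruthRecord] = []

    n_large = spec.n_debris // 2
    n_small = spec.n_debris - n_large
    plan: list[int] = (
        [3] * spec.n_overlap_clusters
        + [40] * n_large           # 40/41: class-4 large/small markers
        + [1] * spec.n_straight
        + [2] * spec.n_bent
        + [41] * n_small
    )

    for kind in plan:
        if kind == 1:
            tile, mask = render_chromosome(
                rng.uniform(*spec.chrom_len_range_px), spec.chrom_width_px,
                rng.uniform(0, 5), spec.band_contrast, rng,
            )
        elif kind == 2:
            tile, mask = render_chromosome(
                rng.uniform(*spec.chrom_len_range_px), spec.chrom_width_px,
                rng.uniform(*spec.bend_angle_range_deg) * rng.choice([-1, 1]),
                spec.band_contrast, rng,
            )
        elif kind == 3:
            tile, mask = _render_cluster(spec, rng)
        elif kind == 40:
            tile, mask = _render_large_debris(spec, rng)
        else:
            tile, mask = _render_small_debris(spec, rng)
        if kind != 41:  # rotating a tiny disk only erodes it
            tile, mask = _rotate_tile(tile, mask, float(rng.uniform(0, 180)))
        dilated = ndi.binary_dilation(mask, structure=_EIGHT, iterations=2)
        th, tw = mask.shape
        if th + 2 >= h or tw + 2 >= w:
            raise RuntimeError("object larger than canvas")
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            r0 = int(rng.integers(1, h - th - 1))
            c0 = int(rng.integers(1, w - tw - 1))
            if not (occupancy[r0:r0 + th, c0:c0 + tw] & dilated).any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "placement retry budget exhausted: overcrowded spec"
            )
        view = canvas[r0:r0 + th, c0:c0 + tw]
        view[mask] = tile[mask]
        occupancy[r0:r0 + th, c0:c0 + tw] |= dilated
        com = ndi.center_of_mass(mask)
        records.append(GroundTruthRecord(
            object_id=len(records) + 1,
            true_class=kind if kind < 10 else 4,
            centroid=(r0 + float(com[0]), c0 + float(com[1])),
            bbox=(r0, c0, r0 + th, c0 + tw),
        ))

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return image, records


_GT_FIELDS = ["object_id", "true_class", "centroid_row", "centroid_col",
              "bbox_r0", "bbox_c0", "bbox_r1", "bbox_c1"]


def write_spread(image: np.ndarray, records: list[GroundTruthRecord],
                 png_path: str | Path, csv_path: str | Path) -> None:
    """Write the spread as PNG and its ground truth as CSV."""
    iio.imwrite(Path(png_path), image)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GT_FIELDS)
        for rec in records:
            writer.writerow([
                rec.object_id, rec.true_class,
                f"{rec.centroid[0]:.3f}", f"{rec.centroid[1]:.3f}",
                *rec.bbox,
            ])


def read_ground_truth(csv_path: str | Path) -> list[GroundTruthRecord]:
    records = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(GroundTruthRecord(
                object_id=int(row["object_id"]),
                true_class=int(row["true_class"]),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                bbox=(int(row["bbox_r0"]), int(row["bbox_c0"]),
                      int(row["bbox_r1"]), int(row["bbox_c1"])),
            ))
    return records


def generate_batch(out_dir: str | Path, n_images: int,
                   base_spec: SynthSpec) -> list[Path]:
    """Materialize ``n_images`` spreads (PNG + ground-truth CSV) in a directory.

    Image i uses seed ``base_spec.seed + i`` so the batch is reproducible
    and the images distinct.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n_images):
        spec = replace(base_spec, seed=base_spec.seed + i)
        image, records = render_spread(spec)
        png = out_dir / f"spread_{i:03d}.png"
        write_spread(image, records, png, out_dir / f"spread_{i:03d}_truth.csv")
        paths.append(png)
    return paths


def match_objects(
    records: list[GroundTruthRecord],
    objects: list[SegmentedObject],
) -> list[tuple[GroundTruthRecord, SegmentedObject]]:
    """Pair ground-truth records with segmented objects by nearest centroid."""
    if not records or not objects:
        return []
    seg_centroids = []
    for obj in objects:
        com = ndi.center_of_mass(obj.mask)
        seg_centroids.append((obj.bbox_origin[0] + com[0],
                              obj.bbox_origin[1] + com[1]))
    gt_c = np.array([r.centroid for r in records])
    sg_c = np.array(seg_centroids)
    cost = np.linalg.norm(gt_c[:, None, :] - sg_c[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return [(records[i], objects[j]) for i, j in zip(rows, cols)]
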