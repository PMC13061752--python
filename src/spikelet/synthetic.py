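"""Synthetic wheat-spike images with exactly known spikelet centers.

Real spike photographs for this task (a spike laid on a blue background,
spikelets attached in two alternating ranks along a curved rachis) are
not publicly deposited, so the package ships a generator that emulates
their geometry at desk scale: textured ellipses alternating left/right
of a smooth rachis curve on a noisy blue background.  The generator
returns the exact geometric centers it rendered, which makes it usable
as ground truth for every other module, and a jitter model emulates the
radially Gaussian imprecision of expert clicks.

The generator aims for pipeline testability, not photorealism: no awns,
glumes, clothespins or color-calibration cards are rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .annotations import Point2D, PointAnnotationSet, ScaleCalibration, write_point_annotations

__all__ = [
    "SpikeSynthParams",
    "generate_spike_image",
    "jitter_annotations",
    "generate_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class SpikeSynthParams:
    """Generative parameters of one synthetic spike image.

    Defaults describe a mid-size spike: spikelet ellipses of 6 x 3 mm,
    4 mm steps along the rachis, ranks offset laterally by 2.5 mm, and
    a gently curved rachis — sized so that the 2 mm disc and 6 mm box
    target defaults are sensible on the synthetic data.
    """

    image_size: tuple[int, int] = (384, 160)  # (height, width) px
    px_per_mm: float = 3.0
    n_spikelets: int = 12
    curvature_amplitude_mm: float = 3.0  # lateral amplitude of the rachis curve
    curvature_periods: float = 0.75  # sine periods over the image height
    curvature_phase: float = 0.0  # radians
    rank_offset_mm: float = 2.5  # lateral offset of the two alternating ranks
    spacing_mm: float = 4.0  # along-rachis step between consecutive spikelets
    blob_axes_mm: tuple[float, float] = (6.0, 3.0)  # (major, minor) full axes
    background_rgb: tuple[int, int, int] = (45, 70, 160)
    spikelet_rgb: tuple[int, int, int] = (185, 165, 85)
    hue_jitter: int = 25  # per-blob additive variation of R/G channels
    noise_sd: float = 6.0  # Gaussian pixel noise, 8-bit scale
    annotation_jitter_mm: float = 0.0  # sd of the simulated click error
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spikelets < 0:
            raise ValueError("n_spikelets must be >= 0")
        if self.spacing_mm <= 0 or min(self.blob_axes_mm) <= 0:
            raise ValueError("spacing and blob axes must be positive")
        if self.annotation_jitter_mm < 0:
            raise ValueError("annotation_jitter_mm must be >= 0")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")

    @property
    def scale(self) -> ScaleCalibration:
        return ScaleCalibration(self.px_per_mm)


def _rachis_x(params: SpikeSynthParams, y: np.ndarray | float):
    """Column coordinate of the rachis curve at row ``y``."""
    h, w = params.image_size
    amp = params.curvature_amplitude_mm * params.px_per_mm
    return (w - 1) / 2.0 + amp * np.sin(
        2.0 * math.pi * params.curvature_periods * np.asarray(y, dtype=float) / h
        + params.curvature_phase
    )


def spikelet_centers(params: SpikeSynthParams) -> list[Point2D]:
    """Exact geometric centers of the spikelets, in rendering order.

    Centers sit at equal steps along the image rows, alternating left
    and right of the rachis curve by the rank offset.
    """
    h, w = params.image_size
    ppm = params.px_per_mm
    n = params.n_spikelets
    if n == 0:
        return []
    spacing_px = params.spacing_mm * ppm
    span = spacing_px * (n - 1)
    major_half_px = params.blob_axes_mm[0] / 2.0 * ppm
    margin = major_half_px + 2.0
    y0 = (h - 1 - span) / 2.0
    if y0 < margin or y0 + span > h - 1 - margin:
        raise ValueError(
            f"{n} spikelets at {params.spacing_mm} mm spacing do not fit in a "
            f"{h}x{w} image at {ppm} px/mm; use a larger image or fewer spikelets"
        )
    offset_px = params.rank_offset_mm * ppm
    centers = []
    for k in range(n):
        y = y0 + k * spacing_px
        x = float(_rachis_x(params, y)) + (1 if k % 2 == 0 else -1) * offset_px
        minor_half_px = params.blob_axes_mm[1] / 2.0 * ppm
        if not (minor_half_px <= x <= w - 1 - minor_half_px):
            raise ValueError(
                f"spikelet {k} at x={x:.1f} exceeds the frame laterally; "
                "use a larger image or smaller offsets"
            )
        centers.append(Point2D(x, y))
    return centers


def generate_spike_image(params: SpikeSynthParams) -> tuple[np.ndarray, PointAnnotationSet]:
    """Render one synthetic spike image.

    Returns an (H, W, 3) uint8 RGB array and the annotation set holding
    the *exact* rendered centers (no click jitter; see
    :func:`jitter_annotations` for that).  Fully determined by
    ``params`` including its seed.
    """
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    ppm = params.px_per_mm
    centers = spikelet_centers(params)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(params.background_rgb, dtype=np.float64)
    img += rng.normal(0.0, params.noise_sd, size=img.shape)

    a = params.blob_axes_mm[0] / 2.0 * ppm  # semi-major, along the rachis
    b = params.blob_axes_mm[1] / 2.0 * ppm  # semi-minor, lateral
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    for k, c in enumerate(centers):
        # blob tilted along the local rachis tangent
        eps = 0.5
        dxdy = (float(_rachis_x(params, c.y + eps)) - float(_rachis_x(params, c.y - eps))) / (
            2 * eps
        )
        theta = math.atan2(dxdy, 1.0)  # angle of the tangent from the row axis
        color = np.asarray(params.spikelet_rgb, dtype=np.float64)
        color[0] += rng.uniform(-params.hue_jitter, params.hue_jitter)
        color[1] += rng.uniform(-params.hue_jitter, params.hue_jitter)
        r0 = max(int(np.floor(c.y - a - 1)), 0)
        r1 = min(int(np.ceil(c.y + a + 1)), h - 1)
        c0 = max(int(np.floor(c.x - a - 1)), 0)
        c1 = min(int(np.ceil(c.x + a + 1)), w - 1)
        yy = rows[r0 : r1 + 1, None] - c.y
        xx = cols[None, c0 : c1 + 1] - c.x
        # coordinates in the blob frame: u along the tangent, v across it
        u = yy * math.cos(theta) + xx * math.sin(theta)
        v = -yy * math.sin(theta) + xx * math.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        texture = rng.normal(0.0, params.noise_sd, size=inside.shape)
        region = img[r0 : r1 + 1, c0 : c1 + 1]
        for ch in range(3):
            region[..., ch] = np.where(inside, color[ch] + texture, region[..., ch])

    annotations = PointAnnotationSet(
        image_id=f"synthetic-{params.seed}",
        image_size=params.image_size,
        points=centers,
        scale=params.scale,
    )
    return np.clip(img, 0, 255).astype(np.uint8), annotations


def jitter_annotations(
    annotations: PointAnnotationSet, sigma_mm: float, seed: int
) -> PointAnnotationSet:
    """Displace each point by an isotropic Gaussian click error.

    The displacement has standard deviation ``sigma_mm`` (converted to
    pixels) independently on each axis, i.e. a radially symmetric 2-D
    Gaussian around the true center.  Points are clipped to the image
    bounds; the count never changes.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return PointAnnotationSet(
            annotations.image_id, annotations.image_size, list(annotations.points), annotations.scale
        )
    rng = np.random.default_rng(seed)
    h, w = annotations.image_size
    sigma_px = annotations.scale.mm_to_px(sigma_mm)
    pts = []
    for p in annotations.points:
        dx, dy = rng.normal(0.0, sigma_px, size=2)
        pts.append(
            Point2D(float(np.clip(p.x + dx, 0, w - 1)), float(np.clip(p.y + dy, 0, h - 1)))
        )
    return PointAnnotationSet(annotations.image_id, annotations.image_size, pts, annotations.scale)


def generate_dataset(
    n_images: int,
    params: SpikeSynthParams,
    seed: int,
    out_dir: str | Path,
    count_range: tuple[int, int] = (8, 21),
) -> pd.DataFrame:
    """Write a dataset of seeded synthetic spike images to disk.

    Layout: ``images/<id>.png``, ``annotations/<id>.csv`` (X,Y dialect)
    and ``manifest.csv`` with columns id, n_spikelets, px_per_mm, seed.
    Each image varies the spikelet count (uniform in ``count_range``),
    rachis curvature phase and amplitude; if ``params.annotation_jitter_mm``
    is positive, the *saved annotations* carry simulated click error while
    the manifest records the true rendered count.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    lo, hi = count_range
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid count_range {count_range}")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(seed)
    records = []
    for i in range(n_images):
        image_seed = int(master.integers(0, 2**31 - 1))
        local = np.random.default_rng(image_seed)
        p_i = replace(
            params,
            n_spikelets=int(local.integers(lo, hi + 1)),
            curvature_phase=float(local.uniform(0, 2 * math.pi)),
            curvature_amplitude_mm=params.curvature_amplitude_mm * float(local.uniform(0.5, 1.0)),
            seed=image_seed,
        )
        image_id = f"spike_{i:04d}"
        img, ann = generate_spike_image(p_i)
        ann.image_id = image_id
        Image.fromarray(img).save(out_dir / "images" / f"{image_id}.png")
        saved = ann
        if params.annotation_jitter_mm > 0:
            saved = jitter_annotations(ann, params.annotation_jitter_mm, image_seed + 1)
        write_point_annotations(saved, out_dir / "annotations" / f"{image_id}.csv")
        records.append(
            {
                "id": image_id,
                "n_spikelets": p_i.n_spikelets,
                "px_per_mm": params.px_per_mm,
                "seed": image_seed,
            }
        )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(dataset_dir: str | Path):
    """Load an on-disk dataset (the :func:`generate_dataset` layout).

    Returns a list of :class:`~spikelet.training.Sample` in manifest
    order; the per-image scale comes from the manifest's ``px_per_mm``
    column.
    """
    from .annotations import read_point_annotations
    from .training import Sample

    dataset_dir = Path(dataset_dir)
    manifest = pd.read_csv(dataset_dir / "manifest.csv")
    samples = []
    for row in manifest.itertuples(index=False):
        img = np.asarray(Image.open(dataset_dir / "images" / f"{row.id}.png"))
        ann = read_point_annotations(
            dataset_dir / "annotations" / f"{row.id}.csv",
            image_size=img.shape[:2],
            scale=ScaleCalibration(float(row.px_per_mm)),
            image_id=str(row.id),
        )
        samples.append(Sample(image_id=str(row.id), image=img, annotations=ann))
    return samples
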