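"""Decode predicted maps (or box detections) into spikelet-center points.

Two decoders mirror the two segmentation target schemes:

* **binary** — threshold the probability map, label 8-connected
  components, drop small regions, return each region's centroid;
* **Gaussian** — the threshold-C rule: find candidate areas above a
  floor, keep within each area only pixels whose value is at least C
  times that area's maximum, re-label the survivors, and return each
  resulting region's argmax pixel (plateau ties broken toward the
  smallest row, then column).

Box detections (YOLO-format text) decode to their box centers.
All decoders report centers in the coordinate frame of the map they
are given; 8-connectivity is used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure

from .annotations import Point2D, ScaleCalibration
from .masks import BoxSet

__all__ = [
    "ExtractionParams",
    "extract_centers_binary",
    "extract_centers_gaussian",
    "boxes_to_centers",
    "write_centers",
    "read_centers",
    "DetectionParseError",
]


class DetectionParseError(ValueError):
    """Raised on a malformed detection-file line (carries the line number)."""


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable decoding parameters.

    ``binary_threshold`` binarizes the probability map; regions smaller
    than ``min_region_area_px`` are discarded.  For density maps,
    ``gaussian_floor`` (a fraction of the global maximum) delimits the
    candidate areas and ``gaussian_C`` is the per-area relative cut of
    the threshold-C rule.
    """

    binary_threshold: float = 0.5
    min_region_area_px: int = 0
    gaussian_C: float = 0.5
    gaussian_floor: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.binary_threshold < 1):
            raise ValueError(f"binary_threshold must be in (0,1), got {self.binary_threshold}")
        if self.min_region_area_px < 0:
            raise ValueError("min_region_area_px must be >= 0")
        if not (0 < self.gaussian_C <= 1):
            raise ValueError(f"gaussian_C must be in (0,1], got {self.gaussian_C}")
        if self.gaussian_floor < 0:
            raise ValueError("gaussian_floor must be >= 0")


def extract_centers_binary(
    prob_map: np.ndarray,
    params: ExtractionParams = ExtractionParams(),
    scale: ScaleCalibration | None = None,
) -> list[Point2D]:
    """Geometric centers of the predicted mask regions.

    The map is binarized at ``binary_threshold``; 8-connected regions
    at least ``min_region_area_px`` pixels large each contribute their
    centroid (mean of member pixel coordinates).
    """
    prob_map = np.asarray(prob_map, dtype=float)
    fg = prob_map >= params.binary_threshold
    labels = measure.label(fg, connectivity=2)
    centers = []
    for region in measure.regionprops(labels):
        if region.area < params.min_region_area_px:
            continue
        r, c = region.centroid
        centers.append(Point2D(float(c), float(r)))
    return centers


def extract_centers_gaussian(
    density_map: np.ndarray,
    params: ExtractionParams = ExtractionParams(),
    scale: ScaleCalibration | None = None,
) -> list[Point2D]:
    """Threshold-C decoding of a predicted density map.

    Candidate areas are 8-connected regions above
    ``gaussian_floor x global max``.  Within each area, only pixels
    whose value is >= ``gaussian_C`` times the area's own maximum
    survive; the survivors are re-labeled, and every resulting region
    contributes its argmax pixel as one center.
    """
    density_map = np.asarray(density_map, dtype=float)
    peak = density_map.max(initial=0.0)
    if peak <= 0:
        return []
    floor = params.gaussian_floor * peak
    candidate = density_map > floor
    area_labels = measure.label(candidate, connectivity=2)
    keep = np.zeros_like(candidate)
    for lab in range(1, area_labels.max() + 1):
        area = area_labels == lab
        area_max = density_map[area].max()
        keep |= area & (density_map >= params.gaussian_C * area_max)
    peak_labels = measure.label(keep, connectivity=2)
    centers = []
    for lab in range(1, peak_labels.max() + 1):
        region = peak_labels == lab
        vals = np.where(region, density_map, -np.inf)
        best = vals.max()
        rows, cols = np.nonzero(vals == best)
        i = np.lexsort((cols, rows))[0]  # plateau tie-break: smallest row, then column
        centers.append(Point2D(float(cols[i]), float(rows[i])))
    return centers


def boxes_to_centers(
    detections: BoxSet | str | Path, image_size: tuple[int, int] | None = None
) -> list[Point2D]:
    """Centers of detected boxes.

    Accepts either a :class:`~spikelet.masks.BoxSet` or a YOLO-format
    label file (``class cx cy w h``, normalized); the latter requires
    ``image_size`` (height, width) to denormalize into pixels.
    """
    if isinstance(detections, BoxSet):
        return [b.center for b in detections.boxes]
    path = Path(detections)
    if image_size is None:
        raise ValueError("image_size is required to denormalize a YOLO-format file")
    h, w = image_size
    centers = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 5:
            raise DetectionParseError(f"{path}:{lineno}: expected 'class cx cy w h', got {line!r}")
        try:
            cx, cy = float(fields[1]), float(fields[2])
        except ValueError as exc:
            raise DetectionParseError(f"{path}:{lineno}: non-numeric coordinate in {line!r}") from exc
        centers.append(Point2D(cx * w, cy * h))
    return centers


def write_centers(points: list[Point2D], path: str | Path) -> None:
    """Write predicted centers in the same X,Y CSV dialect as annotations."""
    lines = ["X,Y"] + [f"{p.x!r},{p.y!r}" for p in points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_centers(path: str | Path) -> list[Point2D]:
    """Read a predicted-centers CSV (X,Y header) back into points."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    return [Point2D(float(x), float(y)) for x, y in zip(df[cols["x"]], df[cols["y"]])]
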