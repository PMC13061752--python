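"""Images, point annotations and the millimetre/pixel calibration.

Coordinate convention used throughout the package: ``x`` is the column
axis, ``y`` the row axis, origin at the top-left corner, 0-based, with
pixel centers at integer coordinates.  A point annotation marks the
center of one spikelet; the number of points in an image is its
ground-truth spikelet count.

Annotation files are the ImageJ point-measurement dialect: a delimited
text file (comma or tab) with a header row containing ``X`` and ``Y``
columns (case-insensitive) in pixel units; extra columns are ignored.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "Point2D",
    "ScaleCalibration",
    "PointAnnotationSet",
    "AnnotationFormatError",
    "AnnotationValidationError",
    "read_point_annotations",
    "write_point_annotations",
    "mm_to_px",
    "px_to_mm",
]


class AnnotationFormatError(ValueError):
    """Raised when an annotation file does not follow the X/Y dialect."""


class AnnotationValidationError(ValueError):
    """Raised when a parsed point violates the image-bounds invariant."""


@dataclass(frozen=True)
class Point2D:
    """A point in pixel coordinates (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise AnnotationValidationError(f"non-finite point ({self.x}, {self.y})")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixels-per-millimetre calibration of an image or dataset.

    The physical parameters of the method (2 mm matching radius, 2 mm
    disc radius, 6 mm boxes) are stated in millimetres; this object
    converts them onto the raster.
    """

    px_per_mm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.px_per_mm) and self.px_per_mm > 0):
            raise ValueError(f"px_per_mm must be a positive finite number, got {self.px_per_mm}")

    def mm_to_px(self, value_mm: float) -> float:
        return value_mm * self.px_per_mm

    def px_to_mm(self, value_px: float) -> float:
        return value_px / self.px_per_mm


def mm_to_px(value_mm: float, scale: ScaleCalibration) -> float:
    """Convert a length in millimetres to pixels."""
    return scale.mm_to_px(value_mm)


def px_to_mm(value_px: float, scale: ScaleCalibration) -> float:
    """Convert a length in pixels to millimetres."""
    return scale.px_to_mm(value_px)


@dataclass
class PointAnnotationSet:
    """All expert-clicked spikelet centers of one image.

    ``len(points)`` is the manually counted number of spikelets, i.e.
    the true count t_i entering the MAE/MAPE counting metrics.
    """

    image_id: str
    image_size: tuple[int, int]  # (height, width) in pixels
    points: list[Point2D] = field(default_factory=list)
    scale: ScaleCalibration = field(default_factory=lambda: ScaleCalibration(1.0))

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError(f"image_size must be positive, got {self.image_size}")
        for i, p in enumerate(self.points):
            _check_in_bounds(p, self.image_size, row=i)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def count(self) -> int:
        """Ground-truth spikelet count of the image."""
        return len(self.points)

    def xy_array(self):
        import numpy as np

        return np.array([[p.x, p.y] for p in self.points], dtype=float).reshape(-1, 2)


def _check_in_bounds(p: Point2D, image_size: tuple[int, int], row: int) -> None:
    h, w = image_size
    if not (0 <= p.x < w and 0 <= p.y < h):
        raise AnnotationValidationError(
            f"row {row}: point ({p.x}, {p.y}) outside image of size {h}x{w} (height x width)"
        )


def _resolve_xy_columns(columns: Sequence[str]) -> tuple[str, str]:
    """Find the X and Y columns, case-insensitively; reject duplicates."""
    x_cols = [c for c in columns if str(c).strip().lower() == "x"]
    y_cols = [c for c in columns if str(c).strip().lower() == "y"]
    if len(x_cols) != 1 or len(y_cols) != 1:
        raise AnnotationFormatError(
            f"annotation header must contain exactly one X and one Y column, got {list(columns)}"
        )
    return x_cols[0], y_cols[0]


def read_point_annotations(
    path: str | Path,
    image_size: tuple[int, int],
    scale: ScaleCalibration,
    image_id: str | None = None,
) -> PointAnnotationSet:
    """Read a point-annotation file into a :class:`PointAnnotationSet`.

    Accepts comma- or tab-separated files with a header row; ImageJ
    measurement exports carry extra columns, which are ignored.  Row
    order is preserved.  Out-of-bounds points raise
    :class:`AnnotationValidationError` naming the offending row.
    """
    path = Path(path)
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas-specific failures
        raise AnnotationFormatError(f"cannot parse {path}: {exc}") from exc
    xcol, ycol = _resolve_xy_columns(df.columns)
    points = [Point2D(float(x), float(y)) for x, y in zip(df[xcol], df[ycol])]
    return PointAnnotationSet(
        image_id=image_id if image_id is not None else path.stem,
        image_size=image_size,
        points=points,
        scale=scale,
    )


def write_point_annotations(annotations: PointAnnotationSet, path: str | Path) -> None:
    """Write points as a two-column CSV (header ``X,Y``); round-trips exactly.

    Coordinates are written with :func:`repr`-style float formatting so
    that reading the file back reproduces the same binary floats.
    """
    path = Path(path)
    lines = ["X,Y"]
    lines += [f"{p.x!r},{p.y!r}" for p in annotations.points]
    path.write_text("\n".join(lines) + "\n")
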