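import numpy as np
import pytest

from spikelet.annotations import Point2D, PointAnnotationSet, ScaleCalibration


@pytest.fixture
def scale10():
    return ScaleCalibration(10.0)


@pytest.fixture
def simple_annotations(scale10):
    """Two well-separated points on a 200x200 image at 10 px/mm."""
    return PointAnnotationSet(
        image_id="simple",
        image_size=(200, 200),
        points=[Point2D(100.0, 100.0), Point2D(40.0, 60.0)],
        scale=scale10,
    )


def random_annotation_set(rng: np.random.Generator, n_points=None, size=(128, 128),
                          px_per_mm=None) -> PointAnnotationSet:
    h, w = size
    if n_points is None:
        n_points = int(rng.integers(0, 11))
    if px_per_mm is None:
        px_per_mm = float(rng.uniform(2.0, 12.0))
    pts = [
        Point2D(float(rng.uniform(0, w - 1)), float(rng.uniform(0, h - 1)))
        for _ in range(n_points)
    ]
    return PointAnnotationSet(
        image_id="random", image_size=size, points=pts, scale=ScaleCalibration(px_per_mm)
    )
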