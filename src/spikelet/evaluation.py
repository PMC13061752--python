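"""Spatial matching of predicted vs true centers and accuracy metrics.

A predicted center is a true positive if it can be paired one-to-one
with a true center within a fixed physical radius (default 2 mm);
unmatched predictions are false positives and unmatched truths are
false negatives.  The pairing itself is a maximum-cardinality
bipartite matching on the within-radius graph, breaking ties by
minimum total distance (solved exactly with the Hungarian algorithm);
a greedy nearest-pair mode is available for comparison.

Counting accuracy is summarized by the mean absolute error and the
mean absolute percentage error of per-image counts,

    MAE  = (1/n) sum_i |t_i - p_i|
    MAPE = (100/n') sum_{i: t_i>0} |t_i - p_i| / t_i

with t_i the manual count, p_i the predicted count, and images with
t_i = 0 excluded from MAPE (division by zero), with a warning.

Detection accuracy pools TP/FP/FN over images (micro-averaging) for
the headline precision/recall/F1; per-image macro means are also
reported for transparency.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .annotations import Point2D, PointAnnotationSet, ScaleCalibration

__all__ = [
    "MatchResult",
    "DetectionMetrics",
    "CountMetrics",
    "EvaluationReport",
    "match_centers",
    "detection_metrics",
    "count_error_metrics",
    "evaluate_run",
    "DEFAULT_MATCH_RADIUS_MM",
]

DEFAULT_MATCH_RADIUS_MM = 2.0


@dataclass
class MatchResult:
    """One-to-one pairing of predicted and true centers within a radius."""

    tp_pairs: list[tuple[int, int, float]]  # (true index, pred index, distance mm)
    fp: list[int]  # unmatched prediction indices
    fn: list[int]  # unmatched truth indices
    radius_mm: float

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def n_true(self) -> int:
        return self.tp + len(self.fn)

    @property
    def n_pred(self) -> int:
        return self.tp + len(self.fp)


@dataclass(frozen=True)
class DetectionMetrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class CountMetrics:
    mae: float
    mape: float  # percent
    n: int


def _pairwise_mm(pred: list[Point2D], true: list[Point2D], scale: ScaleCalibration) -> np.ndarray:
    """(n_true, n_pred) matrix of distances in millimetres."""
    if not pred or not true:
        return np.zeros((len(true), len(pred)))
    p = np.array([[q.x, q.y] for q in pred], dtype=float)
    t = np.array([[q.x, q.y] for q in true], dtype=float)
    return cdist(t, p) / scale.px_per_mm


def match_centers(
    pred: list[Point2D],
    true: list[Point2D],
    radius_mm: float = DEFAULT_MATCH_RADIUS_MM,
    scale: ScaleCalibration = ScaleCalibration(1.0),
    method: str = "hungarian",
) -> MatchResult:
    """Pair predicted with true centers within ``radius_mm``.

    ``method='hungarian'`` (default) computes a maximum-cardinality
    matching restricted to within-radius pairs and, among those, one of
    minimum total distance, by solving a linear assignment problem in
    which every out-of-radius pair carries a cost too large ever to be
    preferred over an additional feasible pair.  ``method='greedy'``
    repeatedly takes the closest remaining feasible pair.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    d = _pairwise_mm(pred, true, scale)
    nt, npred = d.shape
    feasible = d <= radius_mm
    if nt == 0 or npred == 0 or not feasible.any():
        return MatchResult([], list(range(npred)), list(range(nt)), radius_mm)

    if method == "greedy":
        pairs = []
        used_t: set[int] = set()
        used_p: set[int] = set()
        order = np.argsort(d, axis=None)
        for flat in order:
            ti, pi = np.unravel_index(flat, d.shape)
            if d[ti, pi] > radius_mm:
                break
            if ti in used_t or pi in used_p:
                continue
            used_t.add(int(ti))
            used_p.add(int(pi))
            pairs.append((int(ti), int(pi), float(d[ti, pi])))
    elif method == "hungarian":
        # big-M exceeds any achievable total feasible distance, so the
        # solver first maximizes the number of within-radius pairs and
        # only then minimizes their total distance
        big = radius_mm * (min(nt, npred) + 1) + 1.0
        cost = np.where(feasible, d, big)
        rows, cols = linear_sum_assignment(cost)
        pairs = [
            (int(ti), int(pi), float(d[ti, pi]))
            for ti, pi in zip(rows, cols)
            if feasible[ti, pi]
        ]
    else:
        raise ValueError(f"unknown matching method {method!r}")

    matched_t = {ti for ti, _, _ in pairs}
    matched_p = {pi for _, pi, _ in pairs}
    return MatchResult(
        tp_pairs=sorted(pairs),
        fp=[i for i in range(npred) if i not in matched_p],
        fn=[i for i in range(nt) if i not in matched_t],
        radius_mm=radius_mm,
    )


def _prf(tp: int, fp: int, fn: int) -> DetectionMetrics:
    if tp + fp == 0:
        precision = 1.0 if fn == 0 else 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 1.0 if fp == 0 else 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return DetectionMetrics(precision=precision, recall=recall, f1=f1)


def detection_metrics(match: MatchResult) -> DetectionMetrics:
    """Precision, recall and F1 of one matching result.

    Degenerate cases follow the usual conventions: with no predictions
    and no truths everything is perfect (P = R = F1 = 1); with no
    predictions but existing truths precision is 0, and symmetrically
    for recall; F1 is 0 whenever P + R = 0.
    """
    return _prf(match.tp, len(match.fp), len(match.fn))


def count_error_metrics(pairs: list[tuple[int, int]]) -> CountMetrics:
    """MAE and MAPE of per-image spikelet counts.

    ``pairs`` holds (true count t_i, predicted count p_i) per image.
    Images with t_i = 0 contribute to MAE but are excluded from MAPE
    (the percentage error divides by t_i), with a warning.
    """
    if not pairs:
        raise ValueError("count_error_metrics requires at least one image")
    t = np.array([p[0] for p in pairs], dtype=float)
    p = np.array([q[1] for q in pairs], dtype=float)
    if (t < 0).any():
        raise ValueError("true counts must be >= 0")
    mae = float(np.abs(t - p).mean())
    nonzero = t > 0
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} image(s) with zero true count excluded from MAPE",
            stacklevel=2,
        )
    if nonzero.any():
        mape = float(100.0 * (np.abs(t - p)[nonzero] / t[nonzero]).mean())
    else:
        mape = float("nan")
    return CountMetrics(mae=mae, mape=mape, n=len(pairs))


@dataclass
class EvaluationReport:
    """Per-image and pooled detection/counting accuracy of one run."""

    per_image: dict[str, dict] = field(default_factory=dict)
    micro: DetectionMetrics | None = None
    macro: DetectionMetrics | None = None
    counts: CountMetrics | None = None
    radius_mm: float = DEFAULT_MATCH_RADIUS_MM

    def to_dict(self) -> dict:
        return {
            "radius_mm": self.radius_mm,
            "aggregate": {
                "precision": self.micro.precision,
                "recall": self.micro.recall,
                "f1": self.micro.f1,
                "macro_precision": self.macro.precision,
                "macro_recall": self.macro.recall,
                "macro_f1": self.macro.f1,
                "mae": self.counts.mae,
                "mape": self.counts.mape,
                "n_images": self.counts.n,
            },
            "per_image": self.per_image,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [dict(image_id=k, **v) for k, v in self.per_image.items()]
        pd.DataFrame(rows).to_csv(path, index=False)

    def summary_row(self, method: str = "run") -> str:
        a = self.to_dict()["aggregate"]
        return (
            f"{method}\tMAE={a['mae']:.3f}\tMAPE={a['mape']:.1f}%\t"
            f"P={a['precision']:.3f}\tR={a['recall']:.3f}\tF1={a['f1']:.3f}"
        )


def evaluate_run(
    predictions: dict[str, list[Point2D]],
    annotations: dict[str, PointAnnotationSet],
    radius_mm: float = DEFAULT_MATCH_RADIUS_MM,
    scale: ScaleCalibration | None = None,
    method: str = "hungarian",
) -> EvaluationReport:
    """Match and score a whole run of per-image center predictions.

    The headline precision/recall/F1 pools TP/FP/FN over all images
    (micro-average); unweighted per-image means (macro) and the count
    metrics are reported alongside.  Image-id sets must coincide.
    """
    missing_pred = sorted(set(annotations) - set(predictions))
    missing_true = sorted(set(predictions) - set(annotations))
    if missing_pred or missing_true:
        raise ValueError(
            f"image id mismatch: missing predictions for {missing_pred}, "
            f"missing annotations for {missing_true}"
        )
    per_image: dict[str, dict] = {}
    tp = fp = fn = 0
    per_image_prf = []
    count_pairs = []
    for image_id in sorted(annotations):
        ann = annotations[image_id]
        img_scale = scale if scale is not None else ann.scale
        m = match_centers(predictions[image_id], ann.points, radius_mm, img_scale, method)
        dm = detection_metrics(m)
        per_image_prf.append(dm)
        tp += m.tp
        fp += len(m.fp)
        fn += len(m.fn)
        count_pairs.append((len(ann.points), len(predictions[image_id])))
        per_image[image_id] = {
            "tp": m.tp,
            "fp": len(m.fp),
            "fn": len(m.fn),
            "precision": dm.precision,
            "recall": dm.recall,
            "f1": dm.f1,
            "true_count": len(ann.points),
            "pred_count": len(predictions[image_id]),
        }
    macro = DetectionMetrics(
        precision=float(np.mean([m.precision for m in per_image_prf])),
        recall=float(np.mean([m.recall for m in per_image_prf])),
        f1=float(np.mean([m.f1 for m in per_image_prf])),
    )
    return EvaluationReport(
        per_image=per_image,
        micro=_prf(tp, fp, fn),
        macro=macro,
        counts=count_error_metrics(count_pairs),
        radius_mm=radius_mm,
    )
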