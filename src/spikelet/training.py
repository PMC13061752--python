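"""Encoder-decoder segmentation training on disc or density targets.

The model is a compact U-Net-style convolutional encoder-decoder
implemented directly on numpy (explicit forward/backward passes and an
Adam optimizer), sized by a named encoder preset so that CPU-scale
experiments stay fast.  Two training contracts are supported:

* **binary scheme** — per-pixel logits trained with binary
  cross-entropy against disc masks; prediction is a per-pixel
  probability map.
* **gaussian scheme** — a log-softmax over the flattened raster trained
  with the Kullback-Leibler divergence against normalized density
  masks; prediction is a probability distribution over pixels.

Images are resized to a fixed training geometry (default 512 x 224, the
full-scale recipe) and predictions are resampled back to the original
image geometry before center decoding, so extracted centers and all
evaluation remain in original pixel coordinates where the millimetre
calibration is meaningful.

The augmentation pipeline mirrors the full recipe: resize, horizontal
flip p=0.5, vertical flip p=0.277, rotation within +-30 deg p=0.735,
Gaussian blur p=0.25, Gaussian noise p=0.15, brightness/contrast p=0.5,
RGB channel shift +-15 p=0.5, color jitter p=0.703, grayscale p=0.1.
Geometric transforms act identically on image, target raster and point
annotations; photometric transforms touch the image only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import transform as sktransform

from .annotations import PointAnnotationSet
from .extraction import ExtractionParams, extract_centers_binary, extract_centers_gaussian
from .masks import BinaryMask, DensityMask, make_binary_mask, make_gaussian_mask
from .masks import DEFAULT_DISC_RADIUS_MM, DEFAULT_SIGMA_MM

__all__ = [
    "AugmentationSpec",
    "AugmentationPipeline",
    "TrainConfig",
    "TrainingHistory",
    "Sample",
    "split_dataset",
    "build_augmentation_pipeline",
    "loss_bce",
    "loss_kldiv",
    "train_segmentation_model",
    "predict_mask",
    "SegmentationModel",
    "save_checkpoint",
    "load_checkpoint",
    "ENCODER_PRESETS",
]

CHECKPOINT_SCHEMA_VERSION = 1

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# channel widths (level 1, level 2, bottleneck) of the numpy U-Net backend
ENCODER_PRESETS: dict[str, tuple[int, int, int]] = {
    "unet-micro": (4, 8, 16),
    "unet-tiny": (6, 12, 24),
    "unet-small": (10, 20, 40),
    "unet-base": (16, 32, 64),
}
# full-scale encoder names map onto the largest preset of this backend
_ENCODER_ALIASES = {"mit_b2": "unet-base", "efficientnet-b4": "unet-base"}


def _resolve_encoder(name: str) -> tuple[int, int, int]:
    key = _ENCODER_ALIASES.get(name, name)
    if key not in ENCODER_PRESETS:
        raise ValueError(
            f"unknown encoder {name!r}; available presets: {sorted(ENCODER_PRESETS)} "
            f"plus aliases {sorted(_ENCODER_ALIASES)}"
        )
    return ENCODER_PRESETS[key]


@dataclass(frozen=True)
class AugmentationSpec:
    """Probabilities and ranges of the training-time augmentations."""

    resize_to: tuple[int, int] = (512, 224)  # (height, width)
    hflip_p: float = 0.5
    vflip_p: float = 0.277
    rotate_limit_deg: float = 30.0
    rotate_p: float = 0.735
    blur_limit: tuple[int, int] = (1, 3)  # kernel size range
    blur_p: float = 0.25
    noise_p: float = 0.15
    noise_sd_range: tuple[float, float] = (0.01, 0.03)  # on unit-scale images
    brightness_contrast_p: float = 0.5
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    rgb_shift_limit: int = 15  # 8-bit units
    rgb_shift_p: float = 0.5
    color_jitter: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.2)
    color_jitter_p: float = 0.703
    grayscale_p: float = 0.1

    def __post_init__(self) -> None:
        probs = [
            self.hflip_p, self.vflip_p, self.rotate_p, self.blur_p, self.noise_p,
            self.brightness_contrast_p, self.rgb_shift_p, self.color_jitter_p,
            self.grayscale_p,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("augmentation probabilities must lie in [0, 1]")
        if not (0.0 <= self.rotate_limit_deg <= 180.0):
            raise ValueError("rotate_limit_deg must lie in [0, 180]")
        h, w = self.resize_to
        if h % 4 or w % 4:
            raise ValueError("resize_to sides must be multiples of 4 (two pooling levels)")

    @classmethod
    def identity(cls, resize_to: tuple[int, int]) -> "AugmentationSpec":
        """A spec with every stochastic transform disabled (resize only)."""
        return cls(
            resize_to=resize_to, hflip_p=0, vflip_p=0, rotate_p=0, blur_p=0, noise_p=0,
            brightness_contrast_p=0, rgb_shift_p=0, color_jitter_p=0, grayscale_p=0,
        )


@dataclass
class TrainConfig:
    """Training recipe for one segmentation run.

    The full-scale defaults follow the published recipe (500 epochs,
    Adam, 60/20/20 split, the augmentation list above); learning rate,
    batch size and Adam betas are conventional defaults, exposed as
    configuration.  ``loss`` must agree with ``target_scheme``
    (bce <-> binary, kldiv <-> gaussian) and is filled in automatically
    when left empty.
    """

    target_scheme: str = "binary"  # "binary" | "gaussian"
    encoder_name: str = ""  # empty -> scheme default
    loss: str = ""  # empty -> scheme default
    epochs: int = 500
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 4
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    pretrained: bool = False
    disc_radius_mm: float = DEFAULT_DISC_RADIUS_MM
    sigma_mm: float = DEFAULT_SIGMA_MM
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    match_radius_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.target_scheme not in ("binary", "gaussian"):
            raise ValueError(f"unknown target_scheme {self.target_scheme!r}")
        if not self.encoder_name:
            self.encoder_name = "mit_b2" if self.target_scheme == "binary" else "efficientnet-b4"
        expected_loss = "bce" if self.target_scheme == "binary" else "kldiv"
        if not self.loss:
            self.loss = expected_loss
        if self.loss != expected_loss:
            raise ValueError(
                f"loss {self.loss!r} incompatible with target_scheme "
                f"{self.target_scheme!r} (expected {expected_loss!r})"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9 or min(self.split_fractions) <= 0:
            raise ValueError("split fractions must be positive and sum to 1")
        _resolve_encoder(self.encoder_name)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            aug = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["augmentation"].items()
            }
            d["augmentation"] = AugmentationSpec(**aug)
        if "extraction" in d and isinstance(d["extraction"], dict):
            d["extraction"] = ExtractionParams(**d["extraction"])
        for key in ("adam_betas", "split_fractions"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 0-based index into the series

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_f1": self.val_f1,
            }
        ).to_csv(path, index=False)


@dataclass
class Sample:
    """One training/evaluation item: an RGB image and its point annotations."""

    image_id: str
    image: np.ndarray  # (H, W, 3) uint8 or float
    annotations: PointAnnotationSet


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------


def split_dataset(
    image_ids: list[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Random disjoint train/validation/test partition of image ids.

    Subset sizes are the rounded fractions of the total (the test set
    takes the remainder); the shuffle is deterministic in the seed.
    """
    if len(image_ids) < 3:
        raise ValueError("need at least 3 images to build a 3-way split")
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n = len(image_ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n - 2)
    n_val = min(max(n_val, 1), n - n_train - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = [image_ids[i] for i in order]
    return ids[:n_train], ids[n_train : n_train + n_val], ids[n_train + n_val :]


# ---------------------------------------------------------------------------
# augmentation pipeline
# ---------------------------------------------------------------------------


def _resize_points(points: np.ndarray, old: tuple[int, int], new: tuple[int, int]) -> np.ndarray:
    (h0, w0), (h1, w1) = old, new
    out = points.copy()
    out[:, 0] = (points[:, 0] + 0.5) * (w1 / w0) - 0.5
    out[:, 1] = (points[:, 1] + 0.5) * (h1 / h0) - 0.5
    return out


def _rotate_points(points: np.ndarray, angle_deg: float, shape: tuple[int, int]) -> np.ndarray:
    """Point images under skimage.transform.rotate(image, angle_deg).

    The image rotation maps a feature at p to R(-a) (p - c) + c where
    c is the pixel-center of the raster and a is the angle in radians
    (y grows downward, hence the sign).
    """
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]])
    return (points - c) @ rot.T + c


class AugmentationPipeline:
    """Seeded, jointly-consistent image/target/point transform.

    Each call consumes random draws from the pipeline's own generator;
    constructing two pipelines with the same spec and seed yields the
    same sequence of augmented samples.
    """

    def __init__(self, spec: AugmentationSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)

    def __call__(
        self,
        image: np.ndarray,
        target: np.ndarray | None = None,
        points: np.ndarray | None = None,
        binary_target: bool = True,
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
        """Apply resize plus the stochastic recipe.

        ``image`` is (H, W, 3) in any dtype (converted to float [0,1]);
        ``target`` a (H, W) raster aligned with the image; ``points``
        an (N, 2) array of x,y coordinates.  Binary targets are warped
        with nearest-neighbour interpolation, density targets
        bilinearly with their total renormalized.
        """
        spec, rng = self.spec, self.rng
        img = np.asarray(image, dtype=np.float64)
        if img.max(initial=0.0) > 1.5:
            img = img / 255.0
        if target is not None and target.shape != img.shape[:2]:
            raise ValueError(f"target shape {target.shape} != image shape {img.shape[:2]}")
        tgt = None if target is None else np.asarray(target, dtype=np.float64)
        pts = None if points is None else np.asarray(points, dtype=np.float64).reshape(-1, 2)

        old_shape = img.shape[:2]
        new_shape = spec.resize_to
        if old_shape != new_shape:
            img = sktransform.resize(img, new_shape, order=1, anti_aliasing=True)
            if tgt is not None:
                tgt = self._warp_target(tgt, new_shape, binary_target)
            if pts is not None:
                pts = _resize_points(pts, old_shape, new_shape)
        h, w = new_shape

        if rng.random() < spec.hflip_p:
            img = img[:, ::-1]
            if tgt is not None:
                tgt = tgt[:, ::-1]
            if pts is not None:
                pts = pts.copy()
                pts[:, 0] = w - 1 - pts[:, 0]
        if rng.random() < spec.vflip_p:
            img = img[::-1]
            if tgt is not None:
                tgt = tgt[::-1]
            if pts is not None:
                pts = pts.copy()
                pts[:, 1] = h - 1 - pts[:, 1]
        if rng.random() < spec.rotate_p:
            angle = rng.uniform(-spec.rotate_limit_deg, spec.rotate_limit_deg)
            img = sktransform.rotate(img, angle, order=1, preserve_range=True)
            if tgt is not None:
                order = 0 if binary_target else 1
                total = tgt.sum()
                tgt = sktransform.rotate(tgt, angle, order=order, preserve_range=True)
                if not binary_target and tgt.sum() > 0 and total > 0:
                    tgt *= total / tgt.sum()
            if pts is not None:
                pts = _rotate_points(pts, angle, (h, w))

        # photometric transforms: image only
        if rng.random() < spec.blur_p:
            k = int(rng.integers(spec.blur_limit[0], spec.blur_limit[1] + 1))
            img = skfilters.gaussian(img, sigma=max(k / 3.0, 0.3), channel_axis=-1)
        if rng.random() < spec.noise_p:
            sd = rng.uniform(*spec.noise_sd_range)
            img = img + rng.normal(0.0, sd, size=img.shape)
        if rng.random() < spec.brightness_contrast_p:
            b = rng.uniform(-spec.brightness_limit, spec.brightness_limit)
            cf = 1.0 + rng.uniform(-spec.contrast_limit, spec.contrast_limit)
            img = (img - 0.5) * cf + 0.5 + b
        if rng.random() < spec.rgb_shift_p:
            shift = rng.uniform(-spec.rgb_shift_limit, spec.rgb_shift_limit, size=3) / 255.0
            img = img + shift[None, None, :]
        if rng.random() < spec.color_jitter_p:
            img = self._color_jitter(np.clip(img, 0, 1), rng)
        if rng.random() < spec.grayscale_p:
            gray = skcolor.rgb2gray(np.clip(img, 0, 1))
            img = np.repeat(gray[:, :, None], 3, axis=2)

        img = np.ascontiguousarray(np.clip(img, 0.0, 1.0))
        tgt = None if tgt is None else np.ascontiguousarray(tgt)
        return img, tgt, pts

    @staticmethod
    def _warp_target(tgt: np.ndarray, new_shape: tuple[int, int], binary: bool) -> np.ndarray:
        if binary:
            out = sktransform.resize(tgt, new_shape, order=0, anti_aliasing=False)
            return (out > 0.5).astype(np.float64)
        total = tgt.sum()
        out = sktransform.resize(tgt, new_shape, order=1, anti_aliasing=False)
        if total > 0 and out.sum() > 0:
            out *= total / out.sum()
        return out

    def _color_jitter(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        bj, cj, sj, hj = self.spec.color_jitter
        img = img * (1.0 + rng.uniform(-bj, bj))
        mean = img.mean()
        img = (img - mean) * (1.0 + rng.uniform(-cj, cj)) + mean
        gray = skcolor.rgb2gray(np.clip(img, 0, 1))[:, :, None]
        img = gray + (img - gray) * (1.0 + rng.uniform(-sj, sj))
        hsv = skcolor.rgb2hsv(np.clip(img, 0, 1))
        hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-hj, hj)) % 1.0
        return skcolor.hsv2rgb(hsv)


def build_augmentation_pipeline(spec: AugmentationSpec, seed: int = 0) -> AugmentationPipeline:
    """Construct the seeded augmentation pipeline for a training run."""
    return AugmentationPipeline(spec, seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _raster(target) -> np.ndarray:
    if isinstance(target, (BinaryMask, DensityMask)):
        return target.raster
    return np.asarray(target)


def loss_bce(pred_logits: np.ndarray, target) -> float:
    """Mean per-pixel binary cross-entropy between sigmoid(logits) and a
    {0,1} target (numerically stable logits formulation)."""
    z = np.asarray(pred_logits, dtype=np.float64)
    t = _raster(target).astype(np.float64)
    if z.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs target {t.shape}")
    if not np.isin(np.unique(t), (0.0, 1.0)).all():
        raise ValueError("binary cross-entropy target must contain only 0 and 1")
    # max(z,0) - z*t + log(1 + exp(-|z|))
    per_pixel = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    return float(per_pixel.mean())


def loss_kldiv(pred_log_density: np.ndarray, target) -> float:
    """KL(target || pred) = sum target * (log target - pred_log_density).

    ``target`` must be a normalized density (sums to 1); the prediction
    is a log-probability map (log-softmax over the flattened raster).
    The 0 * log 0 terms contribute zero.
    """
    logp = np.asarray(pred_log_density, dtype=np.float64)
    t = _raster(target).astype(np.float64)
    if isinstance(target, DensityMask) and not target.normalized:
        raise ValueError("KL divergence requires a normalized density target")
    if logp.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {logp.shape} vs target {t.shape}")
    if abs(t.sum() - 1.0) > 1e-6:
        raise ValueError(f"target density must sum to 1, got {t.sum():.6g}")
    if (t < 0).any():
        raise ValueError("target density must be non-negative")
    mask = t > 0
    return float(np.sum(t[mask] * (np.log(t[mask]) - logp[mask])))


def _log_softmax(z: np.ndarray) -> np.ndarray:
    m = z.max()
    return z - m - math.log(np.exp(z - m).sum())


# ---------------------------------------------------------------------------
# numpy U-Net backend
# ---------------------------------------------------------------------------


class _Conv3x3:
    """3x3 same-padding convolution with explicit forward/backward."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        sd = math.sqrt(2.0 / (cin * 9))
        self.W = rng.normal(0.0, sd, size=(cout, cin, 3, 3))
        self.b = np.zeros(cout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp
        out = np.empty((n, self.W.shape[0], h, w))
        out[:] = self.b[None, :, None, None]
        for di in range(3):
            for dj in range(3):
                out += np.einsum(
                    "oc,nchw->nohw", self.W[:, :, di, dj], xp[:, :, di : di + h, dj : dj + w]
                )
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, _, h, w = dout.shape
        self.dW = np.empty_like(self.W)
        self.db = dout.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xs = xp[:, :, di : di + h, dj : dj + w]
                self.dW[:, :, di, dj] = np.einsum("nohw,nchw->oc", dout, xs)
                dxp[:, :, di : di + h, dj : dj + w] += np.einsum(
                    "oc,nohw->nchw", self.W[:, :, di, dj], dout
                )
        self._xp = None
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _maxpool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _maxpool_backward(dout, cache):
    idx, shape = cache
    n, c, h, w = shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(shape)


def _upsample_forward(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SegmentationModel:
    """Two-level U-Net-style encoder-decoder on numpy.

    Encoder: two conv pairs with 2x2 max-pooling between levels and a
    conv-pair bottleneck; decoder: nearest-neighbour upsampling with
    skip concatenation and one conv per level; a final 3x3 conv emits
    one logit channel.  Channel widths come from the encoder preset.
    """

    def __init__(self, config: TrainConfig):
        self.config = config
        c1, c2, c3 = _resolve_encoder(config.encoder_name)
        if config.pretrained:
            warnings.warn(
                "no pretrained weights ship with the numpy backend presets; "
                "initializing randomly",
                stacklevel=2,
            )
        rng = np.random.default_rng(config.seed)
        self.c11 = _Conv3x3(3, c1, rng)
        self.c12 = _Conv3x3(c1, c1, rng)
        self.c21 = _Conv3x3(c1, c2, rng)
        self.c22 = _Conv3x3(c2, c2, rng)
        self.c31 = _Conv3x3(c2, c3, rng)
        self.c32 = _Conv3x3(c3, c3, rng)
        self.d2 = _Conv3x3(c3 + c2, c2, rng)
        self.d1 = _Conv3x3(c2 + c1, c1, rng)
        self.head = _Conv3x3(c1, 1, rng)
        self._layers = [
            self.c11, self.c12, self.c21, self.c22, self.c31, self.c32,
            self.d2, self.d1, self.head,
        ]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W) float in [0,1]; returns (N, 1, H, W) logits."""
        cache = {}
        a, cache["m11"] = _relu_forward(self.c11.forward(x))
        a1, cache["m12"] = _relu_forward(self.c12.forward(a))
        p1, cache["p1"] = _maxpool_forward(a1)
        a, cache["m21"] = _relu_forward(self.c21.forward(p1))
        a2, cache["m22"] = _relu_forward(self.c22.forward(a))
        p2, cache["p2"] = _maxpool_forward(a2)
        a, cache["m31"] = _relu_forward(self.c31.forward(p2))
        a3, cache["m32"] = _relu_forward(self.c32.forward(a))
        u2 = _upsample_forward(a3)
        cat2 = np.concatenate([u2, a2], axis=1)
        b2, cache["md2"] = _relu_forward(self.d2.forward(cat2))
        u1 = _upsample_forward(b2)
        cat1 = np.concatenate([u1, a1], axis=1)
        b1, cache["md1"] = _relu_forward(self.d1.forward(cat1))
        z = self.head.forward(b1)
        self._cache = cache
        self._split2 = u2.shape[1]
        self._split1 = u1.shape[1]
        return z

    def backward(self, dz: np.ndarray) -> None:
        cache = self._cache
        db1 = self.head.backward(dz) * cache["md1"]
        dcat1 = self.d1.backward(db1)
        du1, da1_skip = dcat1[:, : self._split1], dcat1[:, self._split1 :]
        db2 = _upsample_backward(du1) * cache["md2"]
        dcat2 = self.d2.backward(db2)
        du2, da2_skip = dcat2[:, : self._split2], dcat2[:, self._split2 :]
        da3 = _upsample_backward(du2) * cache["m32"]
        da = self.c32.backward(da3) * cache["m31"]
        dp2 = self.c31.backward(da)
        da2 = _maxpool_backward(dp2, cache["p2"]) + da2_skip
        da = self.c22.backward(da2 * cache["m22"]) * cache["m21"]
        dp1 = self.c21.backward(da)
        da1 = _maxpool_backward(dp1, cache["p1"]) + da1_skip
        da = self.c12.backward(da1 * cache["m12"]) * cache["m11"]
        self.c11.backward(da)
        self._cache = None

    # -- parameter access ---------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers for g in layer.grads()]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, betas: tuple[float, float]):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def _build_target(sample: Sample, config: TrainConfig) -> np.ndarray:
    if config.target_scheme == "binary":
        return make_binary_mask(sample.annotations, config.disc_radius_mm).raster.astype(float)
    return make_gaussian_mask(sample.annotations, config.sigma_mm, normalize=True).raster


def _batch_loss_and_grad(z: np.ndarray, targets: np.ndarray, scheme: str):
    """Mean per-image loss over the batch and its gradient wrt logits."""
    n = z.shape[0]
    if scheme == "binary":
        t = targets
        per_pixel = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
        loss = float(per_pixel.mean())
        dz = (1.0 / (1.0 + np.exp(-z)) - t) / z.size
    else:
        loss = 0.0
        dz = np.empty_like(z)
        for i in range(n):
            zi = z[i, 0]
            logp = _log_softmax(zi)
            ti = targets[i, 0]
            mask = ti > 0
            loss += float(np.sum(ti[mask] * (np.log(ti[mask]) - logp[mask])))
            dz[i, 0] = (np.exp(logp) - ti) / n
        loss /= n
    return loss, dz


def train_segmentation_model(
    train_samples: list[Sample],
    val_samples: list[Sample],
    config: TrainConfig,
) -> tuple[SegmentationModel, TrainingHistory]:
    """Train the encoder-decoder on disc or density targets.

    Per epoch: shuffle, augment, optimize with Adam; then score the
    validation split by decoding predicted maps into centers and
    matching them against the annotations at the configured radius
    (micro-F1).  The returned model carries the parameters of the
    best-validation-F1 epoch (ties favor the earlier epoch), aligning
    checkpoint selection with the tuning objective.  Fully
    deterministic in ``config.seed`` on CPU.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation subsets must be non-empty")
    model = SegmentationModel(config)
    optimizer = _Adam(model.parameters(), config.learning_rate, config.adam_betas)
    pipeline = AugmentationPipeline(config.augmentation, seed=config.seed + 1)
    order_rng = np.random.default_rng(config.seed + 2)
    binary = config.target_scheme == "binary"

    targets = {s.image_id: _build_target(s, config) for s in train_samples}
    history = TrainingHistory()
    best_f1 = -1.0
    best_state = model.get_state()

    for epoch in range(config.epochs):
        order = order_rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_samples[i] for i in order[start : start + config.batch_size]]
            imgs, tgts = [], []
            for s in batch:
                img, tgt, _ = pipeline(s.image, targets[s.image_id], binary_target=binary)
                if not binary:
                    total = tgt.sum()
                    if total > 0:
                        tgt = tgt / total  # keep a proper distribution after warping
                imgs.append(img.transpose(2, 0, 1))
                tgts.append(tgt[None])
            x = np.stack(imgs)
            t = np.stack(tgts)
            z = model.forward(x)
            loss, dz = _batch_loss_and_grad(z, t, config.target_scheme)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "lower the learning rate or check the targets"
                )
            model.backward(dz)
            optimizer.step(model.gradients())
            epoch_losses.append(loss)
        history.train_loss.append(float(np.mean(epoch_losses)))

        val_loss, val_f1 = _validate(model, val_samples, config)
        history.val_loss.append(val_loss)
        history.val_f1.append(val_f1)
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_state = model.get_state()
            history.best_epoch = epoch

    model.set_state(best_state)
    return model, history


def _validate(model: SegmentationModel, samples: list[Sample], config: TrainConfig):
    from .evaluation import _prf, match_centers

    binary = config.target_scheme == "binary"
    losses = []
    tp = fp = fn = 0
    for s in samples:
        pred = predict_mask(model, s.image)
        tgt = _build_target(s, config)
        if binary:
            eps = 1e-7
            z = np.log(np.clip(pred, eps, 1 - eps) / np.clip(1 - pred, eps, 1 - eps))
            losses.append(loss_bce(z, tgt))
            centers = extract_centers_binary(pred, config.extraction, s.annotations.scale)
        else:
            total = tgt.sum()
            tgt = tgt / total if total > 0 else tgt
            losses.append(loss_kldiv(np.log(np.clip(pred, 1e-300, None)), tgt))
            centers = extract_centers_gaussian(pred, config.extraction, s.annotations.scale)
        m = match_centers(
            centers, s.annotations.points, config.match_radius_mm, s.annotations.scale
        )
        tp += m.tp
        fp += len(m.fp)
        fn += len(m.fn)
    return float(np.mean(losses)), _prf(tp, fp, fn).f1


def predict_mask(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel prediction map in the original image geometry.

    The image is resized to the training geometry, passed through the
    network, and the map is resampled back, so decoded centers live in
    original pixel coordinates.  Binary scheme: probabilities in [0,1];
    gaussian scheme: non-negative map summing to 1.
    """
    config = model.config
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
    if img.max(initial=0.0) > 1.5:
        img = img / 255.0
    orig_shape = img.shape[:2]
    if orig_shape != config.augmentation.resize_to:
        img = sktransform.resize(img, config.augmentation.resize_to, order=1, anti_aliasing=True)
    z = model.forward(img.transpose(2, 0, 1)[None])[0, 0]
    if config.target_scheme == "binary":
        out = 1.0 / (1.0 + np.exp(-z))
        if out.shape != orig_shape:
            out = sktransform.resize(out, orig_shape, order=1)
        return np.clip(out, 0.0, 1.0)
    out = np.exp(_log_softmax(z))
    if out.shape != orig_shape:
        out = sktransform.resize(out, orig_shape, order=1)
        out = np.clip(out, 0.0, None)
    total = out.sum()
    return out / total if total > 0 else out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Single-file model archive with embedded config and schema version."""
    import json

    payload = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    np.savez(
        Path(path),
        schema_version=CHECKPOINT_SCHEMA_VERSION,
        config_json=json.dumps(model.config.to_dict()),
        **payload,
    )


def load_checkpoint(path: str | Path) -> SegmentationModel:
    import json

    with np.load(Path(path), allow_pickle=False) as data:
        version = int(data["schema_version"])
        if version != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema version {version}")
        config = TrainConfig.from_dict(json.loads(str(data["config_json"])))
        model = SegmentationModel(config)
        state = [data[f"param_{i}"] for i in range(len(model.parameters()))]
    model.set_state(state)
    return model
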