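"""Affine augmentation: translation, horizontal flip, rotation, random crop.

All transforms are 3×3 matrices in homogeneous image coordinates acting on
column vectors (x, y, 1)ᵀ, with x the column and y the row index:

* translation by (x0, y0):      x' = x + x0,        y' = y + y0
* horizontal flip at ``width``: x' = width − x,     y' = y
* clockwise rotation by θ:      x' = x·cosθ − y·sinθ, y' = x·sinθ + y·cosθ

Images are resampled by inverse-mapping each output pixel through the
transform (nearest-neighbour by default, bilinear optionally); pixels whose
pre-image falls outside the source take the ``fill`` value.  Rotating an
image pivots about its centre — the origin-pivot matrix conjugated with the
centre translation — so content stays in frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantoms import LabeledImage

__all__ = [
    "AugmentConfig",
    "translation_matrix",
    "hflip_matrix",
    "rotation_matrix",
    "rotation_about_center",
    "translate_point",
    "hflip_point",
    "rotate_point",
    "apply_transform",
    "hflip_image",
    "augment_batch",
    "reject_invalid",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Batch-augmentation settings.

    ``max_translation`` bounds |x0| and |y0| in pixels; ``rotation_range``
    bounds |θ| in degrees; ``crop_size`` is the (H, W) of the random crop;
    ``reject_min_foreground`` is the minimum non-fill pixel fraction an
    augmented image must keep to survive rejection.
    """

    max_translation: int = 8
    rotation_range: float = 15.0
    crop_size: tuple[int, int] | None = None
    flip_probability: float = 0.5
    reject_min_foreground: float = 0.1
    fill: int = 0
    interpolation: str = "nearest"  # or "bilinear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_probability <= 1.0):
            raise ValueError("flip_probability must lie in [0, 1]")
        if not (0.0 <= self.reject_min_foreground <= 1.0):
            raise ValueError("reject_min_foreground must lie in [0, 1]")


def translation_matrix(x0: float, y0: float) -> np.ndarray:
    return np.array([[1.0, 0.0, x0], [0.0, 1.0, y0], [0.0, 0.0, 1.0]])


def hflip_matrix(width: float) -> np.ndarray:
    return np.array([[-1.0, 0.0, width], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


def rotation_matrix(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about_center(theta_deg: float, shape: tuple[int, int]) -> np.ndarray:
    """Origin-pivot rotation conjugated to pivot about the pixel-grid centre."""
    h, w = shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return translation_matrix(cx, cy) @ rotation_matrix(theta_deg) @ translation_matrix(-cx, -cy)


def _apply_point(matrix: np.ndarray, p: tuple[float, float]) -> tuple[float, float]:
    v = matrix @ np.array([p[0], p[1], 1.0])
    return float(v[0]), float(v[1])


def translate_point(p: tuple[float, float], x0: float, y0: float) -> tuple[float, float]:
    return _apply_point(translation_matrix(x0, y0), p)


def hflip_point(p: tuple[float, float], width: float) -> tuple[float, float]:
    return _apply_point(hflip_matrix(width), p)


def rotate_point(p: tuple[float, float], theta_deg: float) -> tuple[float, float]:
    return _apply_point(rotation_matrix(theta_deg), p)


def apply_transform(
    image: np.ndarray,
    matrix: np.ndarray,
    fill: float = 0,
    interpolation: str = "nearest",
) -> np.ndarray:
    """Warp ``image`` by the forward homogeneous ``matrix``.

    Each output pixel is inverse-mapped through ``matrix`` and sampled from
    the source; a singular matrix is rejected.
    """
    matrix = np.asarray(matrix, dtype=float)
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("singular transform cannot be inverted for resampling")
    inv = np.linalg.inv(matrix)
    h, w = image.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    ones = np.ones_like(xx, dtype=float)
    src = np.einsum("ij,jhw->ihw", inv, np.stack([xx.astype(float), yy.astype(float), ones]))
    src_cols, src_rows = src[0], src[1]
    order = {"nearest": 0, "bilinear": 1}[interpolation]
    out = ndimage.map_coordinates(
        image.astype(float), [src_rows, src_cols], order=order, mode="constant", cval=fill
    )
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out


def hflip_image(image: np.ndarray) -> np.ndarray:
    """Exact pixel-grid horizontal mirror (width = W−1 keeps the grid closed)."""
    return image[:, ::-1].copy()


def augment_batch(
    images: list[LabeledImage], cfg: AugmentConfig
) -> list[LabeledImage]:
    """Randomly translate, rotate, crop and flip each image; labels carry over.

    The per-image order is translate → rotate (about centre) → random crop →
    horizontal flip with ``flip_probability``; over-enhanced images (non-fill
    fraction below ``reject_min_foreground``) are dropped afterwards.
    Reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[LabeledImage] = []
    for item in images:
        img = item.image
        h, w = img.shape[:2]
        tx = float(rng.uniform(-cfg.max_translation, cfg.max_translation)) if cfg.max_translation else 0.0
        ty = float(rng.uniform(-cfg.max_translation, cfg.max_translation)) if cfg.max_translation else 0.0
        theta = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range)) if cfg.rotation_range else 0.0
        matrix = rotation_about_center(theta, (h, w)) @ translation_matrix(tx, ty)
        warped = apply_transform(img, matrix, fill=cfg.fill, interpolation=cfg.interpolation)
        if cfg.crop_size is not None and tuple(cfg.crop_size) != (h, w):
            ch, cw = cfg.crop_size
            row = int(rng.integers(0, h - ch + 1))
            col = int(rng.integers(0, w - cw + 1))
            warped = warped[row : row + ch, col : col + cw]
        if cfg.flip_probability > 0 and rng.random() < cfg.flip_probability:
            warped = hflip_image(warped)
        out.append(LabeledImage(image=warped, label=item.label))
    return reject_invalid(out, cfg.reject_min_foreground, fill=cfg.fill)


def reject_invalid(
    images: list[LabeledImage], min_foreground: float, fill: float = 0
) -> list[LabeledImage]:
    """Drop images whose non-fill pixel fraction is below ``min_foreground``."""
    if not (0.0 <= min_foreground <= 1.0):
        raise ValueError("min_foreground must lie in [0, 1]")
    kept = []
    for item in images:
        frac = float(np.mean(item.image != fill))
        if frac >= min_foreground:
            kept.append(item)
    return kept
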