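"""Cropping and histogram equalization of grayscale tube images.

A grayscale image here is an integer array with values in 0..L−1 (L = 256).
Equalization remaps each gray level i through the empirical CDF:

    m(i) = round((cdf(i) − cdf_min) / (1 − cdf_min) · (L − 1))

where cdf_min is the smallest nonzero CDF value, so the darkest occupied
level maps to 0 and the brightest to L−1.  The mapping is monotone, hence
order-preserving on gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HistogramModel",
    "to_gray",
    "crop_region",
    "random_crop",
    "compute_histogram",
    "equalize",
]

L_LEVELS = 256

#: Luma weights for RGB → gray conversion (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class HistogramModel:
    """Gray-level counts, occurrence probabilities and their running sum."""

    counts: np.ndarray  # length-L integer vector n_i
    probs: np.ndarray  # p(i) = n_i / n
    cdf: np.ndarray  # cumulative sum of probs


def to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an H×W×3 image to luma grayscale; pass grayscale through."""
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return np.rint(image.astype(float) @ _LUMA).astype(np.uint8)
    raise ValueError(f"expected H×W or H×W×3 image, got shape {image.shape}")


def crop_region(image: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Extract the ``(row, col, h, w)`` sub-image; rejects out-of-bounds rects."""
    row, col, h, w = rect
    H, W = image.shape[:2]
    if row < 0 or col < 0 or h < 1 or w < 1 or row + h > H or col + w > W:
        raise ValueError(f"crop rect {rect} outside image bounds {(H, W)}")
    return image[row : row + h, col : col + w].copy()


def random_crop(
    image: np.ndarray, size: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Crop a random ``size = (h, w)`` window; reproducible through ``rng``."""
    h, w = size
    H, W = image.shape[:2]
    if h > H or w > W:
        raise ValueError(f"crop size {size} exceeds image size {(H, W)}")
    row = int(rng.integers(0, H - h + 1))
    col = int(rng.integers(0, W - w + 1))
    return crop_region(image, (row, col, h, w))


def compute_histogram(image: np.ndarray, levels: int = L_LEVELS) -> HistogramModel:
    """Tally gray-level counts and build the empirical CDF.

    ``counts[i]`` is the number of pixels at level i, ``probs[i] = counts[i]/n``
    and ``cdf[i]`` the cumulative sum of probs up to i.
    """
    gray = to_gray(np.asarray(image))
    counts = np.bincount(gray.ravel(), minlength=levels)
    n = gray.size
    probs = counts / n
    cdf = np.cumsum(probs)
    return HistogramModel(counts=counts, probs=probs, cdf=cdf)


def equalize(image: np.ndarray, levels: int = L_LEVELS) -> np.ndarray:
    """Histogram-equalize a grayscale (or per-luma) image.

    Color inputs are converted to luma first.  A single-level image is
    returned unchanged (the transform is degenerate there).
    """
    gray = to_gray(np.asarray(image))
    hist = compute_histogram(gray, levels=levels)
    occupied = np.nonzero(hist.counts)[0]
    cdf_min = hist.cdf[occupied[0]]
    if cdf_min >= 1.0:  # single gray level
        return gray.copy()
    lut = np.rint((hist.cdf - cdf_min) / (1.0 - cdf_min) * (levels - 1))
    lut = np.clip(lut, 0, levels - 1).astype(gray.dtype)
    return lut[gray]


def equalize_color(image: np.ndarray, levels: int = L_LEVELS) -> np.ndarray:
    """Per-channel equalization for H×W×3 inputs."""
    if image.ndim != 3:
        return equalize(image, levels=levels)
    return np.stack(
        [equalize(image[:, :, c], levels=levels) for c in range(image.shape[2])],
        axis=2,
    )
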