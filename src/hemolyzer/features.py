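"""Convolutional feature extraction with fixed random filters.

Images pass through a small stack of conv → Leaky ReLU → pool blocks and the
last layer's feature maps are flattened row-major into one feature vector per
image; stacking vectors gives the N×L feature matrix consumed by the ELM
classifier.  The spatial size after each convolution follows

    W' = floor((w + 2p − k) / s) + 1

for input size w, kernel k, stride s and zero-padding p.  Convolution is
cross-correlation (no kernel flip), the deep-learning convention.

The default backbone uses fixed, seeded random filters: random convolutional
projections pair naturally with an ELM head, whose own hidden layer is also
random, and make feature extraction a pure function of (images, spec, seed).
Externally trained filters can be supplied through ``weights``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ConvLayerSpec",
    "PoolSpec",
    "Backbone",
    "conv_out_size",
    "conv2d",
    "leaky_relu",
    "avg_pool",
    "max_pool",
    "flatten_last",
    "default_backbone",
    "extract_features",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    kernel_size: int
    n_kernels: int
    stride: int = 1
    padding: int = 0
    activation: str = "leaky_relu"  # or "none"
    leaky_slope: float = 0.1

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1 or self.padding < 0:
            raise ValueError("require kernel_size >= 1, stride >= 1, padding >= 0")


@dataclass(frozen=True)
class PoolSpec:
    kind: str  # "avg" or "max"
    size: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("avg", "max"):
            raise ValueError(f"pool kind must be 'avg' or 'max', got {self.kind!r}")


def conv_out_size(w: int, k: int, s: int, p: int) -> int:
    """Spatial output size of a convolution: floor((w + 2p − k)/s) + 1."""
    out = (w + 2 * p - k) // s + 1
    if out < 1:
        raise ValueError(
            f"non-positive conv output size for w={w}, k={k}, s={s}, p={p}"
        )
    return out


def leaky_relu(x, slope: float = 0.1):
    """x for x ≥ 0, slope·x otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, slope * x)


def conv2d(
    x: np.ndarray,
    kernels: np.ndarray,
    bias: np.ndarray | float = 0.0,
    stride: int = 1,
    padding: int = 0,
) -> np.ndarray:
    """Multi-channel 2-D cross-correlation.

    ``x`` is (C, H, W) or (H, W); ``kernels`` is (K, C, kh, kw) or (kh, kw).
    Returns (K, H', W') with H', W' given by :func:`conv_out_size`.
    """
    x = np.asarray(x, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if kernels.ndim == 2:
        kernels = kernels[None, None]
    C, H, W = x.shape
    K, Ck, kh, kw = kernels.shape
    if Ck != C:
        raise ValueError(f"kernel channels {Ck} != input channels {C}")
    if kh > H + 2 * padding or kw > W + 2 * padding:
        raise ValueError("kernel larger than padded input")
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    y = np.einsum("kcuv,cijuv->kij", kernels, win, optimize=True)
    b = np.asarray(bias, dtype=float).reshape(-1)
    if b.size == 1:
        b = np.repeat(b, K)
    return y + b[:, None, None]


def _pool(x: np.ndarray, k: int, kind: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    C, H, W = x.shape
    if k > H or k > W:
        raise ValueError(f"pool size {k} exceeds map size {(H, W)}")
    Ho, Wo = H // k, W // k
    x = x[:, : Ho * k, : Wo * k]  # truncate trailing rows/cols
    blocks = x.reshape(C, Ho, k, Wo, k)
    y = blocks.mean(axis=(2, 4)) if kind == "avg" else blocks.max(axis=(2, 4))
    return y[0] if squeeze else y


def avg_pool(x: np.ndarray, k: int) -> np.ndarray:
    """Mean over each k×k block (trailing rows/cols beyond a multiple of k drop)."""
    return _pool(x, k, "avg")


def max_pool(x: np.ndarray, k: int) -> np.ndarray:
    """Maximum over each k×k block."""
    return _pool(x, k, "max")


def flatten_last(maps: np.ndarray) -> np.ndarray:
    """Row-major flattening of the last layer's maps into one feature vector."""
    maps = np.asarray(maps, dtype=float)
    if maps.size == 0:
        raise ValueError("empty feature maps")
    return maps.reshape(-1)


@dataclass
class Backbone:
    """An ordered conv/pool stack with realized filter weights."""

    layers: tuple  # of ConvLayerSpec | PoolSpec
    weights: list = field(default_factory=list)  # (kernels, bias) per conv layer
    seed: int | None = None

    def output_dim(self, input_shape: tuple[int, int]) -> int:
        h, w = input_shape
        c = 1
        for spec in self.layers:
            if isinstance(spec, ConvLayerSpec):
                h = conv_out_size(h, spec.kernel_size, spec.stride, spec.padding)
                w = conv_out_size(w, spec.kernel_size, spec.stride, spec.padding)
                c = spec.n_kernels
            else:
                h, w = h // spec.size, w // spec.size
        return c * h * w


def default_backbone(
    seed: int = 0,
    layers: tuple | None = None,
    in_channels: int = 1,
    weights: list | None = None,
) -> Backbone:
    """Three conv → Leaky ReLU → pool blocks with seeded random filters.

    The first block pools by averaging — it damps pixel noise before the
    later max-pools pick out structural extremes (sediment edges, particle
    specks).  Filters are He-scaled normal draws, fixed for the backbone's
    lifetime; pass ``weights`` (a list of (kernels, bias) pairs) to use
    trained filters instead.
    """
    if layers is None:
        layers = (
            ConvLayerSpec(kernel_size=3, n_kernels=8),
            PoolSpec("avg", 2),
            ConvLayerSpec(kernel_size=3, n_kernels=16),
            PoolSpec("max", 2),
            ConvLayerSpec(kernel_size=3, n_kernels=32),
            PoolSpec("max", 2),
        )
    if weights is None:
        rng = np.random.default_rng(seed)
        weights = []
        c = in_channels
        for spec in layers:
            if isinstance(spec, ConvLayerSpec):
                fan_in = c * spec.kernel_size**2
                kernels = rng.normal(
                    0.0,
                    np.sqrt(2.0 / fan_in),
                    size=(spec.n_kernels, c, spec.kernel_size, spec.kernel_size),
                )
                weights.append((kernels, np.zeros(spec.n_kernels)))
                c = spec.n_kernels
    return Backbone(layers=tuple(layers), weights=weights, seed=seed)


def forward_maps(image: np.ndarray, backbone: Backbone) -> np.ndarray:
    """Run one image (H×W or C×H×W, float in [0,1]) through the stack."""
    x = np.asarray(image, dtype=float)
    if x.ndim == 2:
        x = x[None]
    wi = 0
    for spec in backbone.layers:
        if isinstance(spec, ConvLayerSpec):
            kernels, bias = backbone.weights[wi]
            wi += 1
            x = conv2d(x, kernels, bias, stride=spec.stride, padding=spec.padding)
            if spec.activation == "leaky_relu":
                x = leaky_relu(x, spec.leaky_slope)
        else:
            x = _pool(x, spec.size, spec.kind)
    return x


def extract_features(images, backbone: Backbone) -> np.ndarray:
    """Build the N×L feature matrix, one flattened map stack per image.

    ``images`` is a sequence of uint8 arrays (or objects with an ``.image``
    attribute); pixel values are scaled to [0, 1] first.  All images must
    share one shape.
    """
    arrays = []
    for i, item in enumerate(images):
        img = getattr(item, "image", item)
        img = np.asarray(img)
        if img.ndim == 3:
            img = img.mean(axis=2)
        arrays.append(img.astype(float) / 255.0)
    if not arrays:
        raise ValueError("no images given")
    shape0 = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape0:
            raise ValueError(f"image {i} has shape {a.shape}, expected {shape0}")
    rows = [flatten_last(forward_maps(a, backbone)) for a in arrays]
    F = np.vstack(rows)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite entries in feature matrix")
    return F
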