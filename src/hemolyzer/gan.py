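"""Adversarial sample synthesis for dataset expansion.

A generator G maps latent noise z to an image x′ = G(z, θ_g) with pixels in
[0, 1]; a discriminator D maps an image to the probability that it came from
the real distribution.  The two play the minimax game

    min_G max_D V(G, D) = E_x[log D(x)] + E_z[log(1 − D(G(z)))]

optimised by alternating gradient steps.  By default the generator ascends
log D(G(z)) (the non-saturating variant) instead of descending
log(1 − D(G(z))), which avoids the vanishing gradient of the literal
objective early in training; the literal minimax loss is selectable.

Both networks are small two-layer fully-connected nets with hand-written
gradients and Adam updates — at the tube-image scale this package targets,
dense nets train in seconds on one CPU and keep the module dependency-free.
One model is trained per class so synthesized images inherit a valid label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GanModel",
    "GanTrainConfig",
    "generate",
    "discriminate",
    "value_function",
    "train",
    "sample_and_filter",
]

_EPS = 1e-7
_LEAK = 0.2


@dataclass(frozen=True)
class GanTrainConfig:
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 2e-3
    latent_dim: int = 16
    hidden_dim: int = 64
    seed: int = 0
    loss_variant: str = "nonsaturating"  # or "minimax"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss_variant not in ("nonsaturating", "minimax"):
            raise ValueError(f"unknown loss_variant {self.loss_variant!r}")


@dataclass
class GanModel:
    """Generator + discriminator parameters and the latent-noise contract."""

    gen: dict[str, np.ndarray]
    disc: dict[str, np.ndarray]
    latent_dim: int
    image_shape: tuple[int, ...]
    history: dict[str, list[float]] = field(default_factory=dict)


def _init_params(rng: np.random.Generator, latent_dim: int, hidden: int, n_pix: int):
    def he(n_in, n_out):
        return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

    gen = {
        "W1": he(latent_dim, hidden),
        "b1": np.zeros(hidden),
        "W2": he(hidden, n_pix) * 0.1,
        "b2": np.zeros(n_pix),
    }
    disc = {
        "W1": he(n_pix, hidden),
        "b1": np.zeros(hidden),
        "W2": he(hidden, 1) * 0.1,
        "b2": np.zeros(1),
    }
    return gen, disc


def _leaky(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, x, _LEAK * x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _gen_forward(z: np.ndarray, gen: dict):
    pre1 = z @ gen["W1"] + gen["b1"]
    h = _leaky(pre1)
    pre2 = h @ gen["W2"] + gen["b2"]
    x = _sigmoid(pre2)
    return x, (pre1, h)


def _disc_forward(xflat: np.ndarray, disc: dict):
    pre1 = xflat @ disc["W1"] + disc["b1"]
    h = _leaky(pre1)
    logit = (h @ disc["W2"] + disc["b2"]).ravel()
    return logit, (pre1, h)


def _disc_backward(xflat, dlogit, disc, cache):
    pre1, h = cache
    dlogit = dlogit[:, None]
    grads = {
        "W2": h.T @ dlogit,
        "b2": dlogit.sum(axis=0),
    }
    dh = dlogit @ disc["W2"].T
    dpre1 = dh * np.where(pre1 >= 0, 1.0, _LEAK)
    grads["W1"] = xflat.T @ dpre1
    grads["b1"] = dpre1.sum(axis=0)
    dx = dpre1 @ disc["W1"].T
    return grads, dx


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.5, beta2=0.999):
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k].reshape(params[k].shape)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def generate(z: np.ndarray, model: GanModel) -> np.ndarray:
    """Map latent vectors to images in [0, 1].

    ``z`` may be a single latent vector or an (m, latent_dim) batch; the
    output has the model's image shape (with a leading batch axis for
    batched input).  Deterministic for fixed (z, parameters).
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.shape[1] != model.latent_dim:
        raise ValueError(
            f"latent dimension mismatch: expected {model.latent_dim}, got {z.shape[1]}"
        )
    x, _ = _gen_forward(z, model.gen)
    x = x.reshape((z.shape[0],) + tuple(model.image_shape))
    return x[0] if single else x


def discriminate(x: np.ndarray, model: GanModel) -> np.ndarray:
    """Probability that each image is drawn from the real distribution.

    Returns a scalar for a single image, a vector for a batch; values are
    clamped to (0, 1) exclusive.
    """
    x = np.asarray(x, dtype=float)
    shape = tuple(model.image_shape)
    single = x.shape == shape
    if single:
        x = x[None]
    if x.shape[1:] != shape:
        raise ValueError(f"image shape mismatch: expected {shape}, got {x.shape[1:]}")
    logit, _ = _disc_forward(x.reshape(x.shape[0], -1), model.disc)
    p = np.clip(_sigmoid(logit), _EPS, 1.0 - _EPS)
    return float(p[0]) if single else p


def value_function(
    real_batch: np.ndarray, fake_batch: np.ndarray, model: GanModel
) -> float:
    """The minimax objective V(G, D) on the given batches.

    Mean of log D(x) over real images plus mean of log(1 − D(x′)) over fake
    ones, with D clamped away from {0, 1} so both logs stay finite.
    """
    d_real = np.atleast_1d(discriminate(np.asarray(real_batch), model))
    d_fake = np.atleast_1d(discriminate(np.asarray(fake_batch), model))
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("batches must be non-empty")
    return float(np.mean(np.log(d_real)) + np.mean(np.log1p(-d_fake)))


def train(real_images: np.ndarray, cfg: GanTrainConfig) -> GanModel:
    """Fit a GAN to ``real_images`` (an (n, H, W) array with values in [0, 1]).

    Alternates one discriminator ascent step and one generator step per
    minibatch; per-epoch mean losses are recorded in ``model.history``.
    Reproducible given ``cfg.seed``; aborts on non-finite losses.
    """
    real = np.asarray(real_images, dtype=float)
    if real.ndim < 3 or real.shape[0] < cfg.batch_size:
        raise ValueError(
            f"need at least batch_size={cfg.batch_size} real images, got {real.shape}"
        )
    image_shape = real.shape[1:]
    n_pix = int(np.prod(image_shape))
    rng = np.random.default_rng(cfg.seed)
    gen, disc = _init_params(rng, cfg.latent_dim, cfg.hidden_dim, n_pix)
    opt_g = _Adam(gen, cfg.learning_rate)
    opt_d = _Adam(disc, cfg.learning_rate)
    flat_real = real.reshape(real.shape[0], -1)
    n = flat_real.shape[0]
    history: dict[str, list[float]] = {"d_loss": [], "g_loss": []}

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            xb = flat_real[order[start : start + cfg.batch_size]]
            m = xb.shape[0]

            # --- discriminator step: ascend V ---
            z = rng.standard_normal((m, cfg.latent_dim))
            xf, _ = _gen_forward(z, gen)
            lr_logit, cache_r = _disc_forward(xb, disc)
            lf_logit, cache_f = _disc_forward(xf, disc)
            d_loss = float(np.mean(_softplus(-lr_logit)) + np.mean(_softplus(lf_logit)))
            g_r, _ = _disc_backward(xb, -_sigmoid(-lr_logit) / m, disc, cache_r)
            g_f, _ = _disc_backward(xf, _sigmoid(lf_logit) / m, disc, cache_f)
            opt_d.step(disc, {k: g_r[k] + g_f[k] for k in g_r})

            # --- generator step ---
            z = rng.standard_normal((m, cfg.latent_dim))
            xf, (pre1g, hg) = _gen_forward(z, gen)
            lf_logit, cache_f = _disc_forward(xf, disc)
            if cfg.loss_variant == "nonsaturating":
                g_loss = float(np.mean(_softplus(-lf_logit)))
                dlogit = -_sigmoid(-lf_logit) / m
            else:  # literal minimax: descend log(1 − D(G(z)))
                g_loss = float(np.mean(-_softplus(lf_logit)))
                dlogit = -_sigmoid(lf_logit) / m
            _, dx = _disc_backward(xf, dlogit, disc, cache_f)
            dpre2 = dx * xf * (1.0 - xf)
            grads_g = {
                "W2": hg.T @ dpre2,
                "b2": dpre2.sum(axis=0),
            }
            dh = dpre2 @ gen["W2"].T
            dpre1 = dh * np.where(pre1g >= 0, 1.0, _LEAK)
            grads_g["W1"] = z.T @ dpre1
            grads_g["b1"] = dpre1.sum(axis=0)
            opt_g.step(gen, grads_g)

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: d={d_loss}, g={g_loss}"
                )
            d_losses.append(d_loss)
            g_losses.append(g_loss)
        history["d_loss"].append(float(np.mean(d_losses)))
        history["g_loss"].append(float(np.mean(g_losses)))

    return GanModel(
        gen=gen, disc=disc, latent_dim=cfg.latent_dim,
        image_shape=tuple(image_shape), history=history,
    )


def sample_and_filter(
    model: GanModel,
    n: int,
    seed: int,
    filter_band: tuple[float, float] = (0.0, 1.0),
    min_foreground: float = 0.0,
    foreground_threshold: float = 0.05,
    max_attempts: int | None = None,
) -> list[np.ndarray]:
    """Draw generated images until ``n`` pass the quality filter.

    A candidate passes when its discriminator score lies inside
    ``filter_band`` and its foreground fraction (pixels above
    ``foreground_threshold``) is at least ``min_foreground``.  Sampling stops
    after ``max_attempts`` candidates (default 50·n) — a warning is issued
    and the partial list returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if max_attempts is None:
        max_attempts = 50 * n
    rng = np.random.default_rng(seed)
    lo, hi = filter_band
    accepted: list[np.ndarray] = []
    attempts = 0
    batch = max(8, min(256, n))
    while len(accepted) < n and attempts < max_attempts:
        m = min(batch, max_attempts - attempts)
        z = rng.standard_normal((m, model.latent_dim))
        xs = generate(z, model)
        scores = np.atleast_1d(discriminate(xs, model))
        attempts += m
        for x, s in zip(xs, scores):
            if lo <= s <= hi and float(np.mean(x > foreground_threshold)) >= min_foreground:
                accepted.append(x)
                if len(accepted) == n:
                    break
    if len(accepted) < n:
        warnings.warn(
            f"sample_and_filter: attempt cap {max_attempts} reached with "
            f"{len(accepted)}/{n} accepted samples",
            RuntimeWarning,
            stacklevel=2,
        )
    return accepted
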