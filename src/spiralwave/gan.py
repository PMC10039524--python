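"""Generative adversarial network for activity snapshots, in pure numpy.

The model follows the deep-convolutional GAN recipe: a generator maps a
Gaussian latent vector (default mean 0, SD 25) through a dense projection
and a stack of convolutional hidden layers with rectified-linear units to a
tanh output volume (default 64 x 64 x 6, one plane per evenly spaced
snapshot of a wave); the discriminator runs convolutional hidden layers
with leaky rectified-linear units to a scalar tanh head, mapped to a
probability by ``p = (h + 1) / 2`` (a sigmoid head is available). Both are
trained on the minimax objective

    min_G max_D  E[log D(x)] + E[log(1 - D(G(z)))]

with Adam (discriminator learning rate 2e-4, generator 1e-3). By default
the generator uses the non-saturating gradient ``-E[log D(G(z))]``, the
standard stable reformulation of its minimax term; the literal minimax
variant is selectable.

Forward and backward passes are written out explicitly (im2col
convolutions), so the whole model is seeded and deterministic.

Training balance is tracked by the scores

    S_G = mean(p_generated)
    S_D = 0.5 mean(p_real) + 0.5 mean(1 - p_generated),

both in [0, 1]; 0.5 for both is the ideal equilibrium.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg as sla

from .containers import SnapshotStack, derive_seed
from .preprocess import select_evenly_spaced

__all__ = [
    "GANConfig",
    "GANModel",
    "TrainingSet",
    "ScoreHistory",
    "build_training_set",
    "build_model",
    "train",
    "sample",
    "noise_sweep",
    "generator_score",
    "discriminator_score",
    "frechet_distance",
    "inception_style_score",
    "PCAEmbedder",
    "PrototypeClassifier",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-6


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

def _im2col(x, kh, kw, stride, pad):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride,
                                 j:j + stride * ow:stride]
    return cols.reshape(b, c * kh * kw, oh * ow), oh, ow


def _col2im(cols, x_shape, kh, kw, stride, pad):
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    x = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:hp - pad, pad:wp - pad]
    return x


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x):            # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):        # pragma: no cover - interface
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng, w_scale=0.02):
        super().__init__()
        self.params = {"W": rng.normal(0, w_scale, (n_in, n_out)),
                       "b": np.zeros(n_out)}

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self.grads.get("W", 0) + self._x.T @ dout
        self.grads["b"] = self.grads.get("b", 0) + dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv2d(_Layer):
    def __init__(self, c_in, c_out, rng, kernel=3, stride=1, pad=1, w_scale=0.02):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = {"W": rng.normal(0, w_scale, (c_out, c_in * kernel * kernel)),
                       "b": np.zeros(c_out)}

    def forward(self, x):
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        self._cols = cols
        out = np.matmul(self.params["W"], cols) + self.params["b"][:, None]
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout):
        b = dout.shape[0]
        dout_mat = dout.reshape(b, dout.shape[1], -1)
        self.grads["W"] = (self.grads.get("W", 0)
                           + np.einsum("bol,bkl->ok", dout_mat, self._cols))
        self.grads["b"] = self.grads.get("b", 0) + dout_mat.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T, dout_mat)
        return _col2im(dcols, self._x_shape, self.kernel, self.kernel,
                       self.stride, self.pad)


class Upsample2x(_Layer):
    """Nearest-neighbor 2x spatial upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class BatchNorm2d(_Layer):
    """Per-channel batch normalization with learned scale and shift.

    Training uses batch statistics (and keeps exponential running
    averages); ``eval_mode`` switches to the running statistics so sampling
    is independent of batch composition.
    """

    def __init__(self, n_channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(n_channels), "beta": np.zeros(n_channels)}
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(n_channels)
        self.run_var = np.ones(n_channels)
        self.eval_mode = False

    def forward(self, x):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if self.eval_mode:
            mu = self.run_mean[None, :, None, None]
            var = self.run_var[None, :, None, None]
            return g * (x - mu) / np.sqrt(var + self.eps) + b
        axes = (0, 2, 3)
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
        self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mu[None, :, None, None]) / self._std
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return g * self._xhat + b

    def backward(self, dout):
        axes = (0, 2, 3)
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] = (self.grads.get("gamma", 0)
                               + (dout * self._xhat).sum(axis=axes))
        self.grads["beta"] = self.grads.get("beta", 0) + dout.sum(axis=axes)
        dxhat = dout * g
        m = self._m
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
              ) / self._std
        return dx


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(_Layer):
    def __init__(self, alpha=0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Tanh(_Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1 - self._y * self._y)


class Reshape(_Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Flatten(_Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Network:
    """A plain sequential stack of layers with explicit backprop."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.grads = {}

    def parameters(self):
        out = []
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"{li}.{name}", layer))
        return out

    def flat_params(self):
        return np.concatenate([layer.params[key.split(".")[1]].ravel()
                               for key, layer in self.parameters()])

    def load_flat_params(self, flat):
        i = 0
        for key, layer in self.parameters():
            name = key.split(".")[1]
            p = layer.params[name]
            layer.params[name] = flat[i:i + p.size].reshape(p.shape)
            i += p.size
        if i != flat.size:
            raise ValueError("parameter vector size mismatch")

    def flat_state(self):
        """Non-trained state (normalization running statistics), flattened."""
        arrs = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                arrs += [layer.run_mean, layer.run_var]
        return np.concatenate(arrs) if arrs else np.zeros(0)

    def load_flat_state(self, flat):
        i = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                n = layer.run_mean.size
                layer.run_mean = flat[i:i + n].copy()
                layer.run_var = flat[i + n:i + 2 * n].copy()
                i += 2 * n

    def set_eval(self, eval_mode: bool):
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.eval_mode = eval_mode


class Adam:
    def __init__(self, network, lr, betas=(0.5, 0.999), eps=1e-8):
        self.network, self.lr = network, lr
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(layer.params[k.split(".")[1]])
                  for k, layer in network.parameters()}
        self.v = {k: np.zeros_like(layer.params[k.split(".")[1]])
                  for k, layer in network.parameters()}

    def step(self):
        self.t += 1
        for key, layer in self.network.parameters():
            name = key.split(".")[1]
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            layer.params[name] = layer.params[name] - self.lr * mhat / (
                np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# configuration and model assembly
# --------------------------------------------------------------------------

@dataclass
class GANConfig:
    """Architecture and training hyperparameters.

    Defaults mirror the full-scale configuration (64 x 64 x 6 output, six
    generator / eight discriminator hidden convolutional layers, 10,000
    iterations, latent noise mean 0 and SD 25). Tests and examples use a
    reduced profile (16 x 16 x 1, fewer channels, a few hundred
    iterations).
    """

    image_shape: tuple = (64, 64, 6)       # rows, cols, planes
    latent_dim: int = 100
    latent_mean: float = 0.0
    latent_sd: float = 25.0
    gen_hidden_layers: int = 6
    disc_hidden_layers: int = 8
    base_width: int = 32
    disc_width: int | None = None          # default: same as base_width
    label_smoothing: float = 0.9           # one-sided real-label target
    disc_warmup_iters: int = 100           # discriminator-only steps first
    lr_gen: float = 0.001
    lr_disc: float = 0.0002
    adam_betas: tuple = (0.5, 0.999)
    iterations: int = 10_000
    batch_size: int = 32
    log_every: int = 50
    seed: int = 0
    gen_loss: str = "non-saturating"       # or "minimax"
    disc_head: str = "tanh"                # or "sigmoid"

    def __post_init__(self):
        h, w, _ = self.image_shape
        if h != w or h & (h - 1):
            raise ValueError("image side must be a power of two (square)")
        if self.lr_gen <= 0 or self.lr_disc <= 0:
            raise ValueError("learning rates must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        n_up = int(np.log2(h // 4))
        if self.gen_hidden_layers < n_up:
            raise ValueError("too few generator layers for the image size")


@dataclass
class ScoreHistory:
    """Generator/discriminator scores and losses per logging step."""

    iterations: list = field(default_factory=list)
    s_g: list = field(default_factory=list)
    s_d: list = field(default_factory=list)
    loss_g: list = field(default_factory=list)
    loss_d: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"iteration": self.iterations, "s_g": self.s_g,
                             "s_d": self.s_d, "loss_g": self.loss_g,
                             "loss_d": self.loss_d})


@dataclass
class TrainingSet:
    """Normalized wave volumes: (n_items, planes, rows, cols) in [-1, 1]."""

    items: np.ndarray
    offsets: np.ndarray                # per-item affine inverse: x*scale+offset
    scales: np.ndarray
    degenerate: np.ndarray             # per-item flag (constant input)

    @property
    def n_items(self) -> int:
        return self.items.shape[0]

    @property
    def n_images(self) -> int:
        """Total number of snapshot planes (items x planes per item)."""
        return self.items.shape[0] * self.items.shape[1]

    def denormalize(self, item: np.ndarray, index: int) -> np.ndarray:
        return item * self.scales[index] + self.offsets[index]


class GANModel:
    """Generator + discriminator pair with their optimizers."""

    def __init__(self, config: GANConfig):
        self.config = config
        rng = np.random.default_rng(derive_seed(config.seed, "gan-init"))
        h, w, c = config.image_shape
        wd = config.base_width
        n_up = int(np.log2(h // 4))

        layers = [Dense(config.latent_dim, wd * 4 * 4, rng), Reshape((wd, 4, 4))]
        for i in range(config.gen_hidden_layers):
            if i < n_up:
                layers.append(Upsample2x())
            layers.append(Conv2d(wd, wd, rng, kernel=3, stride=1, pad=1))
            layers.append(BatchNorm2d(wd))
            layers.append(ReLU())
        layers += [Conv2d(wd, c, rng, kernel=3, stride=1, pad=1), Tanh()]
        self.generator = Network(layers)

        layers = []
        dw = config.disc_width or wd
        c_in, side = c, h
        n_down = int(np.log2(h // 4))
        for i in range(config.disc_hidden_layers):
            if i < n_down:
                layers.append(Conv2d(c_in, dw, rng, kernel=4, stride=2, pad=1))
                side //= 2
            else:
                layers.append(Conv2d(c_in, dw, rng, kernel=3, stride=1, pad=1))
            if i > 0:      # no normalization on the first discriminator layer
                layers.append(BatchNorm2d(dw))
            layers.append(LeakyReLU(0.2))
            c_in = dw
        layers += [Flatten(), Dense(dw * side * side, 1, rng)]
        if config.disc_head == "tanh":
            layers.append(Tanh())
        self.discriminator = Network(layers)

        self.opt_g = Adam(self.generator, config.lr_gen, config.adam_betas)
        self.opt_d = Adam(self.discriminator, config.lr_disc, config.adam_betas)
        self.iteration = 0
        # affine inverse of the training normalization (set by train())
        self.denorm_offset = 0.0
        self.denorm_scale = 1.0

    # -- probability head ---------------------------------------------------
    def disc_prob(self, x):
        """Discriminator probability in (0, 1) for a batch of volumes."""
        h = self.discriminator.forward(x).ravel()
        if self.config.disc_head == "tanh":
            p = (h + 1.0) / 2.0
        else:
            p = 1.0 / (1.0 + np.exp(-h))
        return np.clip(p, _EPS, 1 - _EPS)

    def _dprob_to_dhead(self, dp, p):
        """Convert dL/dp to dL/d(head output) for backward()."""
        if self.config.disc_head == "tanh":
            return (dp * 0.5)[:, None]
        return (dp * p * (1 - p))[:, None]

    def generate(self, z):
        return self.generator.forward(z)


def build_model(config: GANConfig) -> GANModel:
    return GANModel(config)


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------

def build_training_set(events, k: int = 6) -> TrainingSet:
    """Volumes of k evenly spaced snapshots per wave, rescaled to [-1, 1].

    ``events`` may be WaveEvent objects (their ``stack`` attribute is used)
    or SnapshotStack objects directly. Events with fewer than ``k`` frames
    are skipped with a warning. Each item is linearly mapped to [-1, 1]
    with the affine transform recorded for inversion; constant items map to
    the midpoint 0 and are flagged degenerate.
    """
    items, offsets, scales, degenerate = [], [], [], []
    n_skipped = 0
    for ev in events:
        stack = ev if isinstance(ev, SnapshotStack) else ev.stack
        if stack is None or stack.n_frames < k:
            n_skipped += 1
            continue
        sel = select_evenly_spaced(stack, k)
        x = sel.frames.astype(np.float64)
        lo, hi = x.min(), x.max()
        offset, scale = (hi + lo) / 2.0, (hi - lo) / 2.0
        if scale == 0:
            items.append(np.zeros_like(x))
            degenerate.append(True)
            scales.append(1.0)
        else:
            items.append((x - offset) / scale)
            degenerate.append(False)
            scales.append(scale)
        offsets.append(offset)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} event(s) with fewer than {k} frames")
    if not items:
        raise ValueError("no usable events")
    return TrainingSet(np.stack(items).astype(np.float32),
                       np.asarray(offsets), np.asarray(scales),
                       np.asarray(degenerate, dtype=bool))


# --------------------------------------------------------------------------
# scores (training-balance bookkeeping)
# --------------------------------------------------------------------------

def generator_score(p_generated) -> float:
    """S_G: mean discriminator probability assigned to generated images."""
    p = np.asarray(list(p_generated), dtype=float)
    if p.size == 0:
        raise ValueError("empty probability list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p.mean())


def discriminator_score(p_real, p_generated) -> float:
    """S_D = 0.5 mean(p_real) + 0.5 mean(1 - p_generated)."""
    pr = np.asarray(list(p_real), dtype=float)
    pg = np.asarray(list(p_generated), dtype=float)
    if pr.size == 0 or pg.size == 0:
        raise ValueError("empty probability list")
    for p in (pr, pg):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
    return float(0.5 * pr.mean() + 0.5 * (1 - pg).mean())


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def train(model: GANModel, data: TrainingSet,
          config: GANConfig | None = None):
    """Alternating adversarial updates; returns (model, ScoreHistory).

    Each iteration takes one discriminator Adam step on a real and a
    generated minibatch, then one generator step through the (frozen)
    discriminator. Fully seeded; identical seeds give identical histories.
    Aborts on non-finite losses.
    """
    config = config or model.config
    if data.n_items == 0:
        raise ValueError("empty training set")
    bs = min(config.batch_size, data.n_items)
    rng = np.random.default_rng(derive_seed(config.seed, "gan-train"))
    history = ScoreHistory()
    x_all = data.items.astype(np.float64)
    model.denorm_offset = float(data.offsets.mean())
    model.denorm_scale = float(data.scales.mean())

    # brief discriminator-only warm-up so the adversarial phase (and its
    # logged scores) starts from a meaningful discriminator
    smooth = config.label_smoothing
    for _ in range(config.disc_warmup_iters):
        idx = rng.choice(data.n_items, size=bs, replace=data.n_items < bs)
        z = rng.normal(config.latent_mean, config.latent_sd,
                       (bs, config.latent_dim))
        model.discriminator.zero_grad()
        p_real = model.disc_prob(x_all[idx])
        dl = (-smooth / p_real + (1 - smooth) / (1 - p_real)) / bs
        model.discriminator.backward(model._dprob_to_dhead(dl, p_real))
        p_fake = model.disc_prob(model.generate(z))
        dl = 1.0 / (bs * (1 - p_fake))
        model.discriminator.backward(model._dprob_to_dhead(dl, p_fake))
        model.opt_d.step()

    for it in range(config.iterations):
        idx = rng.choice(data.n_items, size=bs, replace=data.n_items < bs)
        x_real = x_all[idx]
        z = rng.normal(config.latent_mean, config.latent_sd,
                       (bs, config.latent_dim))

        # ---- discriminator step ----
        # one-sided label smoothing: real targets at `smooth` instead of 1
        model.discriminator.zero_grad()
        x_fake = model.generate(z)
        p_real = model.disc_prob(x_real)
        dl = (-smooth / p_real + (1 - smooth) / (1 - p_real)) / bs
        model.discriminator.backward(model._dprob_to_dhead(dl, p_real))
        p_fake = model.disc_prob(x_fake)
        dl = 1.0 / (bs * (1 - p_fake))
        model.discriminator.backward(model._dprob_to_dhead(dl, p_fake))
        loss_d = float(-np.log(p_real).mean() - np.log1p(-p_fake).mean())
        model.opt_d.step()

        # ---- generator step ----
        model.generator.zero_grad()
        model.discriminator.zero_grad()
        x_fake = model.generate(z)
        p_fake = model.disc_prob(x_fake)
        if config.gen_loss == "non-saturating":
            loss_g = float(-np.log(p_fake).mean())
            dl = -1.0 / (bs * p_fake)
        else:  # literal minimax term of the objective
            loss_g = float(np.log1p(-p_fake).mean())
            dl = -1.0 / (bs * (1 - p_fake))
        dx = model.discriminator.backward(model._dprob_to_dhead(dl, p_fake))
        model.generator.backward(dx)
        model.opt_g.step()

        if not (np.isfinite(loss_d) and np.isfinite(loss_g)):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: "
                f"loss_d={loss_d}, loss_g={loss_g}")

        model.iteration += 1
        if it % config.log_every == 0 or it == config.iterations - 1:
            history.iterations.append(model.iteration)
            history.s_g.append(generator_score(p_fake))
            history.s_d.append(discriminator_score(p_real, p_fake))
            history.loss_g.append(loss_g)
            history.loss_d.append(loss_d)
    return model, history


def sample(model: GANModel, n: int, noise_mean: float | None = None,
           noise_sd: float | None = None, seed: int = 0):
    """Draw ``n`` denormalized snapshot volumes from the generator.

    Returns a list of :class:`SnapshotStack` (one per volume; each plane is
    one snapshot). ``noise_mean``/``noise_sd`` default to the configured
    latent statistics.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = model.config
    mean = cfg.latent_mean if noise_mean is None else noise_mean
    sd = cfg.latent_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    out = []
    batch = 64
    model.generator.set_eval(True)
    try:
        for i0 in range(0, n, batch):
            nb = min(batch, n - i0)
            z = rng.normal(mean, sd, (nb, cfg.latent_dim))
            x = model.generate(z)
            x = x * model.denorm_scale + model.denorm_offset
            for v in x:
                out.append(SnapshotStack(v.astype(np.float32)))
    finally:
        model.generator.set_eval(False)
    return out


def noise_sweep(model: GANModel, sds, means=(None,), n_per_setting: int = 100,
                seed: int = 0, mode: str = "stacked-svd"):
    """PR of generated volumes as a function of latent noise SD and mean."""
    import pandas as pd
    from .complexity import pr_of_stack

    rows = []
    for mean in means:
        for sd in sds:
            stacks = sample(model, n_per_setting, noise_mean=mean, noise_sd=sd,
                            seed=derive_seed(seed, f"sweep-{mean}-{sd}"))
            prs = np.array([pr_of_stack(s, mode).pr for s in stacks])
            rows.append({"mean": model.config.latent_mean if mean is None else mean,
                         "sd": sd, "n": len(stacks),
                         "pr_mean": prs.mean(),
                         "pr_sd": prs.std(ddof=1) if len(prs) > 1 else 0.0})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# evaluation metrics with a pluggable embedder
# --------------------------------------------------------------------------

def frechet_distance(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Frechet distance between Gaussian fits of two feature sets.

    ``|mu_a - mu_b|^2 + Tr(S_a + S_b - 2 (S_a S_b)^(1/2))``. A non-PSD
    matrix square root (numerical) is handled by adding diagonal jitter
    with a warning.
    """
    a = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 samples per feature set")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    sa = np.cov(a, rowvar=False)
    sb = np.cov(b, rowvar=False)
    sa, sb = np.atleast_2d(sa), np.atleast_2d(sb)
    prod = sa @ sb
    covmean = sla.sqrtm(prod)
    if not np.isfinite(covmean).all():
        warnings.warn("covariance product not PSD; adding diagonal jitter")
        jitter = 1e-6 * np.eye(sa.shape[0])
        covmean = sla.sqrtm((sa + jitter) @ (sb + jitter))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    diff = mu_a - mu_b
    return float(diff @ diff + np.trace(sa + sb - 2 * covmean))


def inception_style_score(class_probs: np.ndarray) -> float:
    """exp(mean KL(p(y|x) || mean_x p(y|x))) over a batch of class posteriors."""
    p = np.asarray(class_probs, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] < 1:
        raise ValueError("class_probs must be (n_samples, n_classes)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    p = np.clip(p, 1e-12, None)
    marginal = p.mean(axis=0)
    kl = (p * (np.log(p) - np.log(marginal))).sum(axis=1)
    return float(np.exp(kl.mean()))


class PCAEmbedder:
    """Feature embedder backed by a PCA fit on reference images.

    Stands in for a pretrained classifier backbone in Frechet-distance
    computations; any object with ``transform(images) -> features`` works.
    """

    def __init__(self, n_components: int = 16, seed: int = 0):
        from sklearn.decomposition import PCA
        self._pca = PCA(n_components=n_components, random_state=seed)
        self.fitted = False

    @staticmethod
    def _flatten(images) -> np.ndarray:
        arr = [im.frames.ravel() if isinstance(im, SnapshotStack)
               else np.asarray(im).ravel() for im in images]
        return np.asarray(arr, dtype=np.float64)

    def fit(self, images):
        self._pca.fit(self._flatten(images))
        self.fitted = True
        return self

    def transform(self, images) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("embedder not fitted")
        return self._pca.transform(self._flatten(images))


class PrototypeClassifier:
    """Soft classifier over k-means prototypes of reference features.

    Emits class posteriors via a softmax over negative squared distances to
    cluster centers; used by the inception-style score.
    """

    def __init__(self, n_classes: int = 8, temperature: float | None = None,
                 seed: int = 0):
        from sklearn.cluster import KMeans
        self._km = KMeans(n_clusters=n_classes, n_init=4, random_state=seed)
        self.temperature = temperature
        self.fitted = False

    def fit(self, features: np.ndarray):
        f = np.asarray(features, dtype=np.float64)
        self._km.fit(f)
        if self.temperature is None:
            d = self._km.transform(f) ** 2
            self.temperature = max(float(np.median(d)), 1e-12)
        self.fitted = True
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("classifier not fitted")
        d = self._km.transform(np.asarray(features, dtype=np.float64)) ** 2
        logits = -d / self.temperature
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(model: GANModel, path) -> None:
    """Single-file checkpoint: config JSON + flat parameter arrays (.npz)."""
    np.savez(path,
             config=json.dumps(asdict(model.config)),
             gen=model.generator.flat_params(),
             disc=model.discriminator.flat_params(),
             gen_state=model.generator.flat_state(),
             disc_state=model.discriminator.flat_state(),
             denorm=np.array([model.denorm_offset, model.denorm_scale]),
             iteration=np.array([model.iteration]))


def load_checkpoint(path) -> GANModel:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        for key in ("image_shape", "adam_betas"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = GANModel(GANConfig(**cfg_dict))
        model.generator.load_flat_params(data["gen"])
        model.discriminator.load_flat_params(data["disc"])
        if "gen_state" in data:
            model.generator.load_flat_state(data["gen_state"])
            model.discriminator.load_flat_state(data["disc_state"])
        model.denorm_offset, model.denorm_scale = data["denorm"]
        model.iteration = int(data["iteration"][0])
    return model
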