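"""A small convolutional network for window-image classification.

Implemented directly on numpy: im2col convolutions, max pooling, dense layers,
softmax cross-entropy and Adam, all behind a single seed so that building,
training and inference are bit-reproducible.  Two presets are provided:

``default``
    3 conv+pool blocks (32/64/128 filters, 3x3 kernels, 2x2 max-pool), a
    256-unit dense layer and a 2-way softmax on the raw 256x256x3 input.
``small``
    The same topology behind an initial 4x4 average-pool downsample, with
    8/16/32 filters and a 64-unit dense layer — the desk-scale preset used
    by the built-in benchmarks, trainable in seconds on one CPU.

Images enter as (N, 256, 256, 3) uint8 pixel grids and are scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IMAGE_SHAPE = (256, 256, 3)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 same-padding convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * cin))   # He initialization
        self.w = (rng.standard_normal((k * k * cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.cin, self.cout = k, cin, cout
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # view: (n, h, w, c, k, k) -> (n*h*w, k*k*c) with (k, k, c) ordering
        cols = view.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, self.k * self.k * c)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.x_shape = x.shape
        cols = self._im2col(x)
        if train:
            self.cols = cols
        n, h, w, _ = x.shape
        return (cols @ self.w + self.b).reshape(n, h, w, self.cout)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self.x_shape
        gf = g.reshape(-1, self.cout).astype(np.float32)
        self.grads[0][...] = self.cols.T @ gf
        self.grads[1][...] = gf.sum(axis=0)
        gcols = gf @ self.w.T                           # (n*h*w, k*k*c)
        gcols = gcols.reshape(n, h, w, self.k, self.k, c)
        p = self.k // 2
        gx = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for di in range(self.k):
            for dj in range(self.k):
                gx[:, di:di + h, dj:dj + w, :] += gcols[:, :, :, di, dj, :]
        return gx[:, p:p + h, p:p + w, :]


class MaxPool(Layer):
    def __init__(self, size: int):
        self.s = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        s = self.s
        xr = x.reshape(n, h // s, s, w // s, s, c)
        out = xr.max(axis=(2, 4))
        if train:
            # even gradient split across tied maxima keeps the backward exact
            mask = (xr == out[:, :, None, :, None, :])
            self.mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
            self.x_shape = x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self.x_shape
        return (self.mask * g[:, :, None, :, None, :]).reshape(n, h, w, c)


class AvgPool(Layer):
    """Fixed average-pool downsampling (no parameters)."""

    def __init__(self, size: int):
        self.s = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        s = self.s
        self.x_shape = x.shape
        return x.reshape(n, h // s, s, w // s, s, c).mean(axis=(2, 4),
                                                          dtype=np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self.x_shape
        s = self.s
        g = g[:, :, None, :, None, :] / (s * s)
        return np.broadcast_to(g, (n, h // s, s, w // s, s, c)).reshape(n, h, w, c)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self.mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self.x_shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / nin)
        self.w = (rng.standard_normal((nin, nout)) * scale).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self.x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

PRESETS = {
    "default": dict(downsample=1, filters=(32, 64, 128), pools=(2, 2, 2), dense=256),
    "small": dict(downsample=4, filters=(8, 16, 32), pools=(2, 2, 4), dense=64),
}


class Model:
    """Feed-forward CNN with softmax output over {non-deletion, deletion}."""

    def __init__(self, preset: str, seed: int = 0):
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        cfg = PRESETS[preset]
        self.preset, self.seed = preset, seed
        rng = np.random.default_rng(seed)
        h, w, c = IMAGE_SHAPE
        layers: list[Layer] = []
        if cfg["downsample"] > 1:
            layers.append(AvgPool(cfg["downsample"]))
            h //= cfg["downsample"]
            w //= cfg["downsample"]
        for f, pool in zip(cfg["filters"], cfg["pools"]):
            layers += [Conv2D(c, f, 3, rng), ReLU(), MaxPool(pool)]
            c = f
            h //= pool
            w //= pool
        layers += [Flatten(), Dense(h * w * c, cfg["dense"], rng), ReLU(),
                   Dense(cfg["dense"], 2, rng)]
        self.layers = layers

    # -- plumbing -----------------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-image probability of each class; rows sum to 1."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        # fused path: pool raw uint8 pixels and rescale in one pass
        fused = (images.dtype == np.uint8
                 and isinstance(self.layers[0], AvgPool)
                 and images.shape[1:] == IMAGE_SHAPE)
        if not fused:
            images = _as_input(images)
        out = []
        for i in range(0, len(images), batch_size):
            xb = images[i:i + batch_size]
            if fused:
                xb = _pool_uint8(xb, self.layers[0].s)
                for layer in self.layers[1:]:
                    xb = layer.forward(xb)
                logits = xb
            else:
                logits = self.forward(xb)
            out.append(_softmax(logits))
        return np.concatenate(out) if out else np.zeros((0, 2))

    def save(self, path: str) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters)}
        np.savez(path, preset=self.preset, seed=self.seed, **arrays)

    @classmethod
    def load(cls, path: str) -> "Model":
        data = np.load(path, allow_pickle=False)
        model = cls(str(data["preset"]), int(data["seed"]))
        for i, p in enumerate(model.parameters):
            p[...] = data[f"p{i}"]
        return model


def build_model(preset: str = "small", seed: int = 0) -> Model:
    return Model(preset, seed=seed)


def _pool_uint8(images: np.ndarray, s: int) -> np.ndarray:
    """Average-pool raw uint8 pixels to float32 in [0, 1] (integer block sums)."""
    n, h, w, c = images.shape
    s1 = images.reshape(n, h // s, s, w * c).sum(axis=2, dtype=np.uint16)
    s2 = s1.reshape(n, h // s, w // s, s, c).sum(axis=3, dtype=np.uint16)
    return s2 * np.float32(1.0 / (s * s * 255.0))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _as_input(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1:] != IMAGE_SHAPE:
        raise ValueError(f"expected images of shape {IMAGE_SHAPE}, got {images.shape[1:]}")
    if images.dtype != np.float32:
        images = images.astype(np.float32) / 255.0
    return images


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 128
    epochs: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    preset: str = "small"
    validation_fraction: float = 0.0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation fraction must be in [0, 1)")


@dataclass
class TrainHistory:
    train_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({k: getattr(self, k) for k in
                             ("train_accuracy", "train_loss")} |
                            ({"val_accuracy": self.val_accuracy,
                              "val_loss": self.val_loss} if self.val_accuracy else {}))


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: Model, images: np.ndarray, labels: np.ndarray,
          config: TrainConfig | None = None) -> TrainHistory:
    """Mini-batch Adam training with softmax cross-entropy.

    Requires both classes in ``labels``.  With a positive validation fraction
    the tail of a seeded shuffle is held out and scored each epoch.  For
    presets with a fixed average-pool front end, raw uint8 images are pooled
    once up front (the pooling has no trainable parameters).
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise ValueError("training labels must contain both classes")
    history = TrainHistory()
    if config.epochs == 0:
        return history

    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if (images.dtype == np.uint8 and isinstance(model.layers[0], AvgPool)
            and images.shape[1:] == IMAGE_SHAPE):
        x = _pool_uint8(images, model.layers[0].s)
        active = model.layers[1:]
    else:
        x = _as_input(images)
        active = model.layers

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_val = int(round(config.validation_fraction * len(x)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    xt, yt = x[train_idx], labels[train_idx]
    xv, yv = x[val_idx], labels[val_idx]
    opt = Adam(model.parameters, lr=config.learning_rate)

    def fwd(xb, train=False):
        for layer in active:
            xb = layer.forward(xb, train)
        return xb

    for _epoch in range(config.epochs):
        perm = rng.permutation(len(xt))
        losses, hits, seen = 0.0, 0, 0
        for i in range(0, len(xt), config.batch_size):
            bidx = perm[i:i + config.batch_size]
            xb, yb = xt[bidx], yt[bidx]
            probs = _softmax(fwd(xb, train=True))
            eps = 1e-12
            loss = -np.log(probs[np.arange(len(yb)), yb] + eps).mean()
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            g = (grad / len(yb)).astype(np.float32)
            for layer in reversed(active):
                g = layer.backward(g)
            opt.step(model.gradients)
            losses += float(loss) * len(yb)
            hits += int((probs.argmax(axis=1) == yb).sum())
            seen += len(yb)
        history.train_loss.append(losses / seen)
        history.train_accuracy.append(hits / seen)
        if n_val:
            pv = _softmax(fwd(xv))
            history.val_loss.append(float(
                -np.log(pv[np.arange(len(yv)), yv] + 1e-12).mean()))
            history.val_accuracy.append(float((pv.argmax(axis=1) == yv).mean()))
    return history


def predict(model: Model, images: np.ndarray) -> np.ndarray:
    """Deletion (class 1) probability per image, order-preserving."""
    return model.predict_proba(images)[:, 1]
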