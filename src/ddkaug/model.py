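"""Compact 2D CNN for 80x41 log-mel inputs, implemented in NumPy.

The architecture is a stack of ``n`` blocks of (3x3 same-padded
convolution -> ReLU -> 2x2 max pool with floor division), with channels
doubling from 4 (1 -> 4 -> 8 -> 16 -> 32 -> 64), followed by three fully
connected layers (flatten -> 128 -> 64 -> 2) with ReLU between them.
For the default four-block network on an 80x41 input the spatial map
shrinks 80x41 -> 40x20 -> 20x10 -> 10x5 -> 5x2, so the flattened
dimension entering the first fully connected layer is 32*5*2 = 320 and
the trainable parameter count is 55,618.

Forward and backward passes are explicit (im2col convolution, scatter
pooling gradients), which keeps the model dependency-free and exactly
reproducible: weight initialization is a seeded uniform fan-in scheme
and evaluation-mode output is deterministic for fixed weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .errors import ArchitectureError, ShapeError
from .melspec import N_FRAMES, N_MELS, MelSpectrogram

_DB_SCALE = 80.0  # dynamic range of the dB matrices fed to the network


def default_channel_schedule(n_conv_layers: int) -> tuple[int, ...]:
    """1 input channel, then 4 doubling per block: (1, 4, 8, 16, ...)."""
    return (1,) + tuple(4 * 2 ** i for i in range(n_conv_layers))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults give the four-block network."""

    n_conv_layers: int = 4
    channel_schedule: tuple[int, ...] = ()
    fc_hidden: tuple[int, ...] = (128, 64)
    input_shape: tuple[int, int] = (N_MELS, N_FRAMES)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.n_conv_layers <= 5:
            raise ArchitectureError("n_conv_layers must be in 1..5")
        schedule = self.channel_schedule or default_channel_schedule(self.n_conv_layers)
        if len(schedule) != self.n_conv_layers + 1:
            raise ArchitectureError(
                "channel_schedule length must be n_conv_layers + 1")
        object.__setattr__(self, "channel_schedule", tuple(schedule))

    @property
    def flatten(self) -> int:
        return flatten_dim(self.input_shape, self.n_conv_layers,
                           self.channel_schedule[-1])

    @property
    def fc_dims(self) -> tuple[int, ...]:
        return (self.flatten,) + tuple(self.fc_hidden) + (self.n_classes,)


def flatten_dim(input_shape: tuple[int, int], n_conv_layers: int,
                out_channels: int | None = None) -> int:
    """Flattened size after ``n`` same-padded conv + 2x2 floor-pool blocks.

    Same-padded 3x3 convolutions preserve spatial size, so each block
    floor-halves height and width once.
    """
    h, w = input_shape
    for _ in range(n_conv_layers):
        h, w = h // 2, w // 2
        if h == 0 or w == 0:
            raise ArchitectureError(
                f"spatial dimension collapsed to 0 at depth {n_conv_layers}")
    if out_channels is None:
        out_channels = default_channel_schedule(n_conv_layers)[-1]
    return out_channels * h * w


# ------------------------------------------------------------------ layers

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches of the 1-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    sn, sc, sh, sw = xp.strides
    view = as_strided(xp, shape=(n, c, 3, 3, h, w),
                      strides=(sn, sc, sh, sw, sh, sw))
    return np.ascontiguousarray(view).reshape(n, c * 9, h * w)


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(c_in * 9)
        self.w = rng.uniform(-bound, bound, (c_out, c_in * 9))
        self.b = rng.uniform(-bound, bound, c_out)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray, cache: dict) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x)
        y = np.matmul(self.w, cols) + self.b[:, None]
        cache["cols"], cache["shape"] = cols, (n, c, h, w)
        return y.reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray, cache: dict) -> np.ndarray:
        n, c, h, w = cache["shape"]
        dyf = dy.reshape(n, self.c_out, h * w)
        cols = cache["cols"]
        self.dw = np.einsum("nol,nkl->ok", dyf, cols)
        self.db = dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, dyf).reshape(n, c, 3, 3, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("w", self), ("b", self)]


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d_in)
        self.w = rng.uniform(-bound, bound, (d_out, d_in))
        self.b = rng.uniform(-bound, bound, d_out)

    def forward(self, x: np.ndarray, cache: dict) -> np.ndarray:
        cache["x"] = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray, cache: dict) -> np.ndarray:
        self.dw = dy.T @ cache["x"]
        self.db = dy.sum(axis=0)
        return dy @ self.w


def _maxpool(x: np.ndarray):
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, : 2 * h2, : 2 * w2]
    r = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h2, w2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, (idx, (n, c, h, w))


def _maxpool_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, (n, c, h, w) = cache
    h2, w2 = h // 2, w // 2
    dr = np.zeros((n, c, h2, w2, 4))
    np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
    dxc = dr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    dxc = dxc.reshape(n, c, 2 * h2, 2 * w2)
    dx = np.zeros((n, c, h, w))
    dx[:, :, : 2 * h2, : 2 * w2] = dxc
    return dx


# ------------------------------------------------------------------ model

class CNNClassifier:
    """The conv->ReLU->pool stack plus three fully connected layers."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channel_schedule
        self.convs = [_Conv3x3(ch[i], ch[i + 1], rng)
                      for i in range(config.n_conv_layers)]
        dims = config.fc_dims
        self.fcs = [_Linear(dims[i], dims[i + 1], rng)
                    for i in range(len(dims) - 1)]

    # -- forward -----------------------------------------------------
    def forward(self, x: np.ndarray, caches: list | None = None) -> np.ndarray:
        """Map a (N, 80, 41) or (N, 1, 80, 41) batch to (N, 2) scores."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2:] != self.config.input_shape:
            raise ShapeError(
                f"expected spatial shape {self.config.input_shape}, got {x.shape[2:]}")
        record = caches is not None
        for conv in self.convs:
            cache: dict = {}
            z = conv.forward(x, cache)
            a = np.maximum(z, 0.0)
            x, pcache = _maxpool(a)
            if record:
                caches.append((cache, z, pcache))
        n = x.shape[0]
        flat = x.reshape(n, -1)
        h = flat
        fc_caches = []
        for i, fc in enumerate(self.fcs):
            cache = {}
            h = fc.forward(h, cache)
            if i < len(self.fcs) - 1:
                if record:
                    fc_caches.append((cache, h.copy()))
                h = np.maximum(h, 0.0)
            elif record:
                fc_caches.append((cache, None))
        if record:
            caches.append((fc_caches, x.shape))
        return h

    def backward(self, dscores: np.ndarray, caches: list) -> None:
        fc_caches, conv_out_shape = caches[-1]
        dy = dscores
        for i in range(len(self.fcs) - 1, -1, -1):
            cache, pre_act = fc_caches[i]
            if i < len(self.fcs) - 1:
                dy = dy * (pre_act > 0)
            dy = self.fcs[i].backward(dy, cache)
        dx = dy.reshape(conv_out_shape)
        for i in range(len(self.convs) - 1, -1, -1):
            cache, z, pcache = caches[i]
            da = _maxpool_backward(dx, pcache)
            dz = da * (z > 0)
            dx = self.convs[i].backward(dz, cache)

    # -- bookkeeping ---------------------------------------------------
    def parameters(self) -> list:
        return self.convs + self.fcs

    def n_parameters(self) -> int:
        return sum(layer.w.size + layer.b.size for layer in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.parameters():
            out.extend([layer.w.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.parameters():
            layer.w = next(it).copy()
            layer.b = next(it).copy()


def build_model(config: ModelConfig, seed: int = 0) -> CNNClassifier:
    """Construct and initialize the network described by ``config``."""
    return CNNClassifier(config, seed=seed)


def spectrograms_to_array(spectrograms) -> np.ndarray:
    """Stack dB matrices into a (N, 80, 41) array scaled to [-0.5, 0.5]."""
    values = [s.values if isinstance(s, MelSpectrogram) else np.asarray(s)
              for s in spectrograms]
    arr = np.stack(values).astype(np.float64)
    return arr / _DB_SCALE + 0.5


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(classifier: CNNClassifier, spectrograms) -> np.ndarray:
    """Per-item (P(HC), P(PD)) probabilities; rows sum to 1."""
    x = spectrograms_to_array(spectrograms)
    return softmax(classifier.forward(x))
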