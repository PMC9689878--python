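"""Compact 16-weight-layer residual CNN for 64 x 64 spectral images.

A self-contained NumPy implementation (im2col convolutions, batch
normalization, identity residual blocks, global average pooling) with
hand-written backpropagation and SGD (momentum + weight decay). The
assembled network has exactly 16 weight layers: one stem convolution,
seven residual blocks of two 3x3 convolutions each, and a final linear
classifier. Downsampling blocks subsample the identity path and
zero-pad its channels, so skips stay parameter-free.

At this scale (about 200 single-channel 64 x 64 images) CPU training
takes seconds per epoch, which is the supported target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CNNConfig",
    "TrainHistory",
    "TrainingFailure",
    "ResCNN",
    "build_model",
    "train",
    "evaluate",
    "rasterize_spectra",
    "sync_maps_to_images",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_DTYPE = np.float32  # all activations/parameters; ample precision at this scale


@dataclass
class CNNConfig:
    n_classes: int
    input_size: tuple[int, int] = (64, 64)
    channels: int = 1
    learning_rate: float = 0.01
    weight_decay: float = 0.001
    momentum: float = 0.9
    batch_size: int = 16
    max_epochs: int = 30
    stem_channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need >= 2 classes")
        if self.input_size != (64, 64):
            raise ValueError("network is assembled for 64 x 64 inputs")


@dataclass
class TrainHistory:
    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.loss)


class TrainingFailure(RuntimeError):
    def __init__(self, message: str, history: TrainHistory):
        super().__init__(message)
        self.history = history


# ---------------------------------------------------------------- layers


def _im2col(x: np.ndarray, stride: int) -> tuple[np.ndarray, tuple]:
    """3x3 / pad-1 patches: (N, C, H, W) -> (N, C*9, oh*ow)."""
    n, c, h, w = x.shape
    oh = (h + 2 - 3) // stride + 1
    ow = (w + 2 - 3) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 3, 3, oh, ow), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * 9, oh * ow), (n, c, h, w, oh, ow)


def _col2im(dcols: np.ndarray, shape: tuple, stride: int) -> np.ndarray:
    n, c, h, w, oh, ow = shape
    dcols = dcols.reshape(n, c, 3, 3, oh, ow)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    return dxp[:, :, 1:-1, 1:-1]


class Conv3x3:
    """3x3 convolution, padding 1, no bias (batch norm follows)."""

    is_weight_layer = True
    decay = True

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * 9))
        self.W = rng.normal(0.0, scale, (out_ch, in_ch * 9)).astype(_DTYPE)
        self.stride = stride
        self.dW = np.zeros_like(self.W)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        cols, shape = _im2col(x, self.stride)
        self._cache = (cols, shape)
        out = np.matmul(self.W, cols)  # (K,C9) @ (N,C9,L) -> (N,K,L), BLAS-batched
        n, _, _, _, oh, ow = shape
        return out.reshape(n, self.W.shape[0], oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, shape = self._cache
        n, _, _, _, oh, ow = shape
        dflat = np.ascontiguousarray(dout.reshape(n, self.W.shape[0], oh * ow))
        self.dW = np.matmul(dflat, cols.transpose(0, 2, 1)).sum(axis=0)
        dcols = np.matmul(self.W.T, dflat)
        return _col2im(dcols, shape, self.stride)

    def params(self):
        yield self.W, self.dW, self.decay


class BatchNorm:
    is_weight_layer = False
    decay = False

    def __init__(self, n_ch: int):
        self.gamma = np.ones(n_ch, dtype=_DTYPE)
        self.beta = np.zeros(n_ch, dtype=_DTYPE)
        self.running_mean = np.zeros(n_ch, dtype=_DTYPE)
        self.running_var = np.ones(n_ch, dtype=_DTYPE)
        self.dgamma = np.zeros(n_ch, dtype=_DTYPE)
        self.dbeta = np.zeros(n_ch, dtype=_DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += _BN_MOMENTUM * (mean - self.running_mean)
            self.running_var += _BN_MOMENTUM * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + _BN_EPS)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = np.sum(dout * xhat, axis=axes)
        self.dbeta = np.sum(dout, axis=axes)
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
        ) / std[None, :, None, None]
        return dx

    def params(self):
        yield self.gamma, self.dgamma, False
        yield self.beta, self.dbeta, False


class ResidualBlock:
    """conv-bn-relu-conv-bn plus an identity skip, then relu.

    With stride 2 the skip path is spatially subsampled and zero-padded
    in channels (parameter-free), so the block adds exactly two weight
    layers.
    """

    is_weight_layer = False

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv3x3(in_ch, out_ch, stride, rng)
        self.bn1 = BatchNorm(out_ch)
        self.conv2 = Conv3x3(out_ch, out_ch, 1, rng)
        self.bn2 = BatchNorm(out_ch)
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = self.bn1.forward(self.conv1.forward(x, training), training)
        self._mask1 = h > 0
        h = h * self._mask1
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        skip = x[:, :, :: self.stride, :: self.stride] if self.stride > 1 else x
        if self.out_ch > self.in_ch:
            pad = np.zeros(
                (skip.shape[0], self.out_ch - self.in_ch, skip.shape[2], skip.shape[3]),
                dtype=skip.dtype,
            )
            skip = np.concatenate([skip, pad], axis=1)
        out = h + skip
        self._mask_out = out > 0
        return out * self._mask_out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout * self._mask_out
        dh = self.conv2.backward(self.bn2.backward(dout))
        dh *= self._mask1
        dx = self.conv1.backward(self.bn1.backward(dh))
        dskip = dout[:, : self.in_ch]
        if self.stride > 1:
            scattered = np.zeros_like(dx)
            scattered[:, :, :: self.stride, :: self.stride] = dskip
            dx += scattered
        else:
            dx += dskip
        return dx

    def params(self):
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2):
            yield from layer.params()


class ResCNN:
    """Stem conv -> 7 residual blocks -> global average pool -> linear."""

    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.stem_channels
        self.stem = Conv3x3(cfg.channels, c, stride=2, rng=rng)  # 64 -> 32
        self.bn_stem = BatchNorm(c)
        self.blocks = [
            ResidualBlock(c, c, 1, rng),
            ResidualBlock(c, c, 1, rng),
            ResidualBlock(c, 2 * c, 2, rng),  # 32 -> 16
            ResidualBlock(2 * c, 2 * c, 1, rng),
            ResidualBlock(2 * c, 4 * c, 2, rng),  # 16 -> 8
            ResidualBlock(4 * c, 4 * c, 1, rng),
            ResidualBlock(4 * c, 4 * c, 1, rng),
        ]
        scale = np.sqrt(2.0 / (4 * c))
        self.fc_W = rng.normal(0.0, scale, (cfg.n_classes, 4 * c)).astype(_DTYPE)
        self.fc_b = np.zeros(cfg.n_classes, dtype=_DTYPE)
        self.dfc_W = np.zeros_like(self.fc_W)
        self.dfc_b = np.zeros_like(self.fc_b)

    @property
    def n_weight_layers(self) -> int:
        return 1 + 2 * len(self.blocks) + 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[2:] != self.cfg.input_size or x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected input (N, {self.cfg.channels}, {self.cfg.input_size[0]}, "
                f"{self.cfg.input_size[1]}), got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        h = self.bn_stem.forward(self.stem.forward(x, training), training)
        self._mask_stem = h > 0
        h = h * self._mask_stem
        for block in self.blocks:
            h = block.forward(h, training)
        self._pool_shape = h.shape
        pooled = h.mean(axis=(2, 3))
        self._pooled = pooled
        return pooled @ self.fc_W.T + self.fc_b

    def backward(self, dlogits: np.ndarray) -> None:
        self.dfc_W = dlogits.T @ self._pooled
        self.dfc_b = dlogits.sum(axis=0)
        dpool = dlogits @ self.fc_W
        n, c, h, w = self._pool_shape
        dh = np.broadcast_to(dpool[:, :, None, None], self._pool_shape) / (h * w)
        dh = np.ascontiguousarray(dh)
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        dh *= self._mask_stem
        self.stem.backward(self.bn_stem.backward(dh))

    def params(self):
        yield from self.stem.params()
        yield from self.bn_stem.params()
        for block in self.blocks:
            yield from block.params()
        yield self.fc_W, self.dfc_W, True
        yield self.fc_b, self.dfc_b, False

    def parameter_norm(self) -> float:
        return float(np.sqrt(sum(np.sum(p**2) for p, _, _ in self.params())))


def build_model(cfg: CNNConfig) -> ResCNN:
    return ResCNN(cfg)


def _softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    logits = logits.astype(np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(probs[np.arange(n), y] + 1e-300)))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class _SGD:
    def __init__(self, net: ResCNN, lr: float, momentum: float, weight_decay: float):
        self.net = net
        self.lr, self.mu, self.wd = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p) for p, _, _ in net.params()]

    def step(self) -> None:
        for v, (p, g, decays) in zip(self.velocity, self.net.params()):
            grad = (g + self.wd * p if decays else g).astype(p.dtype, copy=False)
            v *= self.mu
            v -= self.lr * grad
            p += v


def evaluate(net: ResCNN, images: np.ndarray, labels: np.ndarray, batch_size: int = 64):
    """Accuracy (fraction) and confusion matrix under argmax decisions."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    preds = []
    for start in range(0, len(labels), batch_size):
        logits = net.forward(images[start : start + batch_size], training=False)
        preds.append(np.argmax(logits, axis=1))
    pred = np.concatenate(preds)
    k = net.cfg.n_classes
    cm = np.zeros((k, k), dtype=int)
    for t, h in zip(labels, pred):
        cm[t, h] += 1
    return float(np.mean(pred == labels)), cm


def train(
    net: ResCNN,
    images: np.ndarray,
    labels: np.ndarray,
    test_images: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    cfg: CNNConfig | None = None,
) -> TrainHistory:
    """SGD training with per-epoch history.

    Stops at max_epochs or once training accuracy holds at 1.0 for two
    consecutive epochs. Raises TrainingFailure (history attached) if the
    loss goes non-finite.
    """
    cfg = cfg or net.cfg
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("training set needs >= 2 classes")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _SGD(net, cfg.learning_rate, cfg.momentum, cfg.weight_decay)
    history = TrainHistory()
    n = len(labels)
    perfect_streak = 0
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            logits = net.forward(images[batch], training=True)
            loss, dlogits = _softmax_xent(logits, labels[batch])
            if not np.isfinite(loss):
                raise TrainingFailure("loss diverged to non-finite value", history)
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(batch)
        history.loss.append(epoch_loss / n)
        train_acc, _ = evaluate(net, images, labels)
        history.train_accuracy.append(train_acc)
        if test_images is not None and test_labels is not None and len(test_labels):
            test_acc, _ = evaluate(net, test_images, test_labels)
            history.test_accuracy.append(test_acc)
        perfect_streak = perfect_streak + 1 if train_acc >= 1.0 else 0
        if perfect_streak >= 2:
            break
    return history


# ------------------------------------------------------- image builders


def rasterize_spectra(X: np.ndarray, size: int = 64) -> np.ndarray:
    """Rasterize spectra as 64 x 64 single-channel line plots.

    The wavenumber axis is block-averaged to `size` columns; intensity
    is scaled by the dataset-wide min/max (so between-sample amplitude
    differences survive); the curve is drawn by filling each column's
    vertical span between consecutive points.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < size:
        raise ValueError("need at least `size` spectral points")
    base, extra = divmod(p, size)
    cols = []
    start = 0
    for b in range(size):
        w = base + (1 if b < extra else 0)
        cols.append(X[:, start : start + w].mean(axis=1))
        start += w
    curve = np.column_stack(cols)  # n x size
    lo, hi = float(curve.min()), float(curve.max())
    span = hi - lo if hi > lo else 1.0
    rows = np.clip(((hi - curve) / span * (size - 1)).round().astype(int), 0, size - 1)
    images = np.zeros((n, 1, size, size), dtype=float)
    for s in range(n):
        for c in range(size):
            r = rows[s, c]
            r_prev = rows[s, c - 1] if c > 0 else r
            lo_r, hi_r = min(r, r_prev), max(r, r_prev)
            images[s, 0, lo_r : hi_r + 1, c] = 1.0
    return images


def sync_maps_to_images(maps: list[np.ndarray]) -> np.ndarray:
    """Stack per-sample synchronous maps as min-max-normalized images."""
    out = np.empty((len(maps), 1, maps[0].shape[0], maps[0].shape[1]))
    for i, phi in enumerate(maps):
        lo, hi = float(phi.min()), float(phi.max())
        span = hi - lo if hi > lo else 1.0
        out[i, 0] = (phi - lo) / span
    return out
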