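"""Two-tower convolutional network for regression on image pairs.

The model mirrors the standard architecture for predicting a continuous
response (e.g. drug-response AUC) from a pair of grayscale images — one
per data modality, such as a cell-line expression image and a drug
descriptor image.  Each tower applies three 5x5 convolution layers, each
followed by batch normalization, ReLU and 2x2 max pooling (valid padding
throughout); the tower outputs are flattened, concatenated and passed
through a fully connected head ending in a single linear unit.

The module is self-contained numpy: layers implement forward/backward
passes (im2col convolution, batch norm, max pooling, dense), and layer
shapes and trainable-parameter counts are pure functions of the
configuration, computable without any training.

Default widths are conv filters (24, 64, 100) per tower with bias-less
convolutions (batch norm supplies the shift) and dense units
(640, 500, 125, 100).  With two 50x50 inputs at convolution stride 1 this
architecture has exactly 1,307,218 trainable parameters; rebuilt for
227x387 and 380x387 inputs at convolution stride 2 it has 2,715,218.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CNNSpec",
    "TrainingConfig",
    "TwoTowerCNN",
    "build_two_tower_cnn",
    "count_trainable_parameters",
    "smoke_train",
]


# ----------------------------------------------------------------------
# Layers
# ----------------------------------------------------------------------

class Layer:
    """Minimal layer protocol: forward/backward plus trainable parameter access."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-padding 2-D convolution, NCHW layout, square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, bias: bool, rng: np.random.Generator):
        self.k = kernel_size
        self.stride = stride
        fan_in = in_channels * kernel_size * kernel_size
        self.W = rng.standard_normal((out_channels, in_channels, self.k, self.k)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_channels) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cols = None
        self._x_shape = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.db is not None else [])

    @staticmethod
    def out_hw(h: int, w: int, k: int, s: int) -> tuple[int, int]:
        return (h - k) // s + 1, (w - k) // s + 1

    def forward(self, x, training):
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        oh, ow = self.out_hw(h, w, k, s)
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        cols = windows[:, :, ::s, ::s].transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        self._cols = cols
        self._x_shape = x.shape
        w_mat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ w_mat.T
        if self.b is not None:
            out += self.b
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, f, oh, ow = grad.shape
        k, s = self.k, self.stride
        grad_mat = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, f)
        self.dW[...] = (grad_mat.T @ self._cols).reshape(self.W.shape)
        if self.b is not None:
            self.db[...] = grad_mat.sum(axis=0)
        w_mat = self.W.reshape(f, -1)
        dcols = (grad_mat @ w_mat).reshape(n, oh, ow, self._x_shape[1], k, k)
        dx = np.zeros(self._x_shape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + oh * s:s, j:j + ow * s:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization; gamma/beta trainable, running stats are buffers."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training):
        axes = (0, 2, 3)
        shape = (1, -1, 1, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std, x.shape, training)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, grad):
        xhat, inv_std, x_shape, trained = self._cache
        axes = (0, 2, 3)
        shape = (1, -1, 1, 1)
        m = x_shape[0] * x_shape[2] * x_shape[3]
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma.reshape(shape)
        if not trained:
            # eval mode: normalization constants do not depend on the batch
            return dxhat * inv_std.reshape(shape)
        dx = (inv_std.reshape(shape) / m) * (
            m * dxhat
            - dxhat.sum(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axes).reshape(shape)
        )
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2 (floor behavior: trailing row/col dropped)."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        cropped = x[:, :, :oh * 2, :ow * 2]
        windows = cropped.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = windows.reshape(n, c, oh, ow, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        x_shape, idx = self._cache
        n, c, h, w = x_shape
        oh, ow = h // 2, w // 2
        dflat = np.zeros((n, c, oh, ow, 4))
        np.put_along_axis(dflat, idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros(x_shape)
        dx[:, :, :oh * 2, :ow * 2] = (
            dflat.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh * 2, ow * 2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self._rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


# ----------------------------------------------------------------------
# Model construction
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CNNSpec:
    """Architecture configuration.

    ``conv_stride`` applies to all convolution layers (1 for compact 50x50
    layouts; 2 for large inputs).  The default widths reproduce the
    published trainable-parameter totals for both input regimes; they are
    configuration, not hard-wired constants.
    """

    input_shapes: tuple = ((50, 50), (50, 50))
    conv_filters: tuple = (24, 64, 100)
    kernel_size: int = 5
    conv_stride: int = 1
    conv_bias: bool = False
    dense_units: tuple = (640, 500, 125, 100)
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.input_shapes) != 2:
            raise ValueError("expected exactly two input image shapes")
        if len(self.conv_filters) != 3:
            raise ValueError("each tower has exactly three convolution layers")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.conv_stride < 1:
            raise ValueError("conv_stride must be >= 1")


@dataclass
class TwoTowerCNN:
    """Built model: two convolutional towers plus a dense head."""

    spec: CNNSpec
    towers: list = field(repr=False)
    head: list = field(repr=False)
    tower_shapes: list  # per tower: list of (layer_name, (C, H, W)) after each stage

    def all_layers(self) -> list[Layer]:
        return [lay for tower in self.towers for lay in tower] + list(self.head)

    def forward(self, xa: np.ndarray, xb: np.ndarray, training: bool = False) -> np.ndarray:
        outs = []
        for x, tower in zip((xa, xb), self.towers):
            t = x[:, None, :, :] if x.ndim == 3 else x
            for lay in tower:
                t = lay.forward(t, training)
            outs.append(t)
        self._split = outs[0].shape[1]
        z = np.concatenate(outs, axis=1)
        for lay in self.head:
            z = lay.forward(z, training)
        return z[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        grad = dpred[:, None]
        for lay in reversed(self.head):
            grad = lay.backward(grad)
        ga, gb = grad[:, :self._split], grad[:, self._split:]
        for g, tower in zip((ga, gb), self.towers):
            for lay in reversed(tower):
                g = lay.backward(g)


def _build_tower(shape: tuple[int, int], spec: CNNSpec, tower_idx: int,
                 rng: np.random.Generator) -> tuple[list[Layer], list, int]:
    layers: list[Layer] = []
    shapes = []
    h, w = shape
    c = 1
    for li, filters in enumerate(spec.conv_filters, start=1):
        oh, ow = Conv2D.out_hw(h, w, spec.kernel_size, spec.conv_stride)
        if oh < 1 or ow < 1:
            raise ValueError(
                f"tower {tower_idx}, conv layer {li}: input {h}x{w} is too small "
                f"for a {spec.kernel_size}x{spec.kernel_size} kernel at stride {spec.conv_stride}"
            )
        layers.append(Conv2D(c, filters, spec.kernel_size, spec.conv_stride, spec.conv_bias, rng))
        layers.append(BatchNorm2D(filters))
        layers.append(ReLU())
        shapes.append((f"conv{li}", (filters, oh, ow)))
        h, w, c = oh, ow, filters
        ph, pw = h // 2, w // 2
        if ph < 1 or pw < 1:
            raise ValueError(
                f"tower {tower_idx}, pool layer {li}: feature map {h}x{w} is too small for 2x2 pooling"
            )
        layers.append(MaxPool2D())
        shapes.append((f"pool{li}", (filters, ph, pw)))
        h, w = ph, pw
    layers.append(Flatten())
    flat = c * h * w
    shapes.append(("flatten", (flat,)))
    return layers, shapes, flat


def build_two_tower_cnn(spec: CNNSpec | None = None) -> TwoTowerCNN:
    """Instantiate the architecture; raises naming the failing layer when
    an input is too small for the three conv/pool reductions."""
    spec = spec or CNNSpec()
    rng = np.random.default_rng(spec.seed)
    towers, tower_shapes, flats = [], [], []
    for idx, shape in enumerate(spec.input_shapes):
        layers, shapes, flat = _build_tower(tuple(shape), spec, idx, rng)
        towers.append(layers)
        tower_shapes.append(shapes)
        flats.append(flat)
    head: list[Layer] = []
    n_in = sum(flats)
    for units in spec.dense_units:
        head.append(Dense(n_in, units, rng))
        head.append(ReLU())
        if spec.dropout_rate > 0:
            head.append(Dropout(spec.dropout_rate, rng))
        n_in = units
    head.append(Dense(n_in, 1, rng))
    return TwoTowerCNN(spec=spec, towers=towers, head=head, tower_shapes=tower_shapes)


def count_trainable_parameters(model) -> int:
    """Total element count of trainable tensors.

    Batch-norm running statistics are buffers, not trainable parameters,
    and are excluded.  Accepts a built model or a single layer.
    """
    layers = model.all_layers() if isinstance(model, TwoTowerCNN) else [model]
    return int(sum(p.size for lay in layers for p in lay.params()))


# ----------------------------------------------------------------------
# Smoke training
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Desk-scale training settings; the loss is mean squared error."""

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 2e-3
    val_fraction: float = 0.2
    patience: int = 15
    seed: int = 0


class _Adam:
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
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def smoke_train(model: TwoTowerCNN, images_a: np.ndarray, images_b: np.ndarray,
                targets: np.ndarray, cfg: TrainingConfig | None = None) -> dict:
    """Train on image pairs and report whether the model beats the mean predictor.

    Splits off a validation set, minimizes MSE with Adam, applies early
    stopping, and compares the best validation MSE against predicting the
    training-target mean.  Raises on divergence (NaN loss), echoing the
    configuration.
    """
    cfg = cfg or TrainingConfig()
    rng = np.random.default_rng(cfg.seed)
    n = len(targets)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    xa_tr, xb_tr, y_tr = images_a[train_idx], images_b[train_idx], targets[train_idx]
    xa_va, xb_va, y_va = images_a[val_idx], images_b[val_idx], targets[val_idx]

    params = [p for lay in model.all_layers() for p in lay.params()]
    opt = _Adam(params, cfg.learning_rate)
    # fit residuals around the training mean so the untrained model already
    # matches the mean predictor and capacity goes into the signal
    mu = float(y_tr.mean())
    baseline_mse = float(np.mean((y_va - mu) ** 2))

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_epoch = -1
    since_best = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(y_tr))
        epoch_losses = []
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            pred = model.forward(xa_tr[batch], xb_tr[batch], training=True)
            resid = pred - (y_tr[batch] - mu)
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (NaN loss) with config {cfg}")
            model.backward(2.0 * resid / len(batch))
            opt.step([g for lay in model.all_layers() for g in lay.grads()])
            epoch_losses.append(loss)
        val_pred = model.forward(xa_va, xb_va, training=False) + mu
        val_loss = float(np.mean((val_pred - y_va) ** 2))
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val, best_epoch, since_best = val_loss, epoch, 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    return {
        "history": history,
        "best_epoch": best_epoch,
        "val_mse": best_val,
        "baseline_mse": baseline_mse,
        "beats_baseline": bool(best_val < baseline_mse),
        "n_parameters": count_trainable_parameters(model),
    }
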