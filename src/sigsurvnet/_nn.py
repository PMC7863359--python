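"""Minimal NumPy neural-network core for the pathway-masked survival regressor.

Implements exactly the layers the architecture needs — a per-gene state
layer, a structurally masked gene->pathway affine layer, 1-D convolutions and
max-pooling for the inception blocks, dropout, dense layers — with explicit
forward/backward passes and an Adadelta optimizer.  Everything is
channels-last: convolution inputs are ``(batch, length, channels)``.

The mask on the gene->pathway layer is a hard structural constraint: the
effective weight is ``W * M`` in every forward pass and the gradient is
masked identically, so a masked-out connection contributes exactly zero at
every point during and after training.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


def nonneg_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Fan-in-scaled uniform init restricted to [0, limit].

    Used for the omics-facing layers: with non-negative weights the initial
    pathway activation is a consensus aggregate of its member-gene states
    instead of a random-sign mixture whose signal cancels, which matters for
    the short training schedules this model runs on.
    """
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(0.0, limit, size=shape)


class Layer:
    """Base layer: named parameters, gradients, and an L2-decay subset."""

    l2_params: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class GeneState(Layer):
    """Per-gene affine map (expression, copy number) -> one rectified state.

    Weights are not shared across genes: each gene g has its own
    ``(w_expr[g], w_cnv[g], bias[g])``.
    """

    def __init__(self, n_genes: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "w_expr": nonneg_uniform(rng, (n_genes,), 2),
            "w_cnv": nonneg_uniform(rng, (n_genes,), 2),
            "bias": np.zeros(n_genes),
        }

    def forward_pair(self, expr: np.ndarray, cnv: np.ndarray) -> np.ndarray:
        self._expr, self._cnv = expr, cnv
        z = expr * self.params["w_expr"] + cnv * self.params["w_cnv"] + self.params["bias"]
        self._active = z > 0
        return np.where(self._active, z, 0.0)

    def backward(self, dout: np.ndarray) -> None:
        dz = dout * self._active
        self.grads = {
            "w_expr": (dz * self._expr).sum(axis=0),
            "w_cnv": (dz * self._cnv).sum(axis=0),
            "bias": dz.sum(axis=0),
        }


class MaskedDense(Layer):
    """Affine layer whose weight matrix is elementwise-masked, with ReLU.

    ``mask`` is a binary (in_features, out_features) membership indicator;
    both the effective weight and its gradient are multiplied by the mask, so
    zero entries are invariant under training.
    """

    def __init__(self, mask: np.ndarray, rng: np.random.Generator) -> None:
        super().__init__()
        self.mask = np.asarray(mask, dtype=float)
        n_in, n_out = self.mask.shape
        w = np.empty((n_in, n_out))
        degree = self.mask.sum(axis=0)  # fan-in per output unit
        for j in range(n_out):
            w[:, j] = nonneg_uniform(rng, (n_in,), int(degree[j]))
        self.params = {"weight": w * self.mask, "bias": np.zeros(n_out)}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        self._x = x
        z = x @ (self.params["weight"] * self.mask) + self.params["bias"]
        self._active = z > 0
        return np.where(self._active, z, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * self._active
        self.grads = {
            "weight": self.mask * (self._x.T @ dz),
            "bias": dz.sum(axis=0),
        }
        return dz @ (self.params["weight"] * self.mask).T


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' zero padding, optional ReLU."""

    l2_params = ("weight",)

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, relu: bool = True) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel_size = kernel_size
        self.pad = (kernel_size - 1) // 2
        self.relu = relu
        fan_in = kernel_size * in_channels
        self.params = {
            "weight": he_uniform(rng, (kernel_size, in_channels, filters), fan_in),
            "bias": np.zeros(filters),
        }

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        # (batch, length, channels, kernel)
        cols = sliding_window_view(xp, self.kernel_size, axis=1)
        self._cols = cols
        self._in_length = x.shape[1]
        z = np.tensordot(cols, self.params["weight"], axes=([3, 2], [0, 1])) + self.params["bias"]
        if self.relu:
            self._active = z > 0
            return np.where(self._active, z, 0.0)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * self._active if self.relu else dout
        dw = np.tensordot(self._cols, dz, axes=([0, 1], [0, 1]))  # (C, K, F)
        self.grads = {"weight": dw.transpose(1, 0, 2), "bias": dz.sum(axis=(0, 1))}
        dcols = np.tensordot(dz, self.params["weight"], axes=([2], [2]))  # (B, L, K, C)
        batch, length = dz.shape[0], self._in_length
        dxp = np.zeros((batch, length + 2 * self.pad, dcols.shape[3]))
        for dk in range(self.kernel_size):
            dxp[:, dk:dk + length, :] += dcols[:, :, dk, :]
        return dxp[:, self.pad:self.pad + length, :]


class MaxPool1D(Layer):
    """Width-w max pool, stride 1, 'same' padding; channel count preserved."""

    def __init__(self, width: int = 3) -> None:
        super().__init__()
        if width % 2 != 1:
            raise ValueError("pool width must be odd for 'same' padding")
        self.width = width
        self.pad = (width - 1) // 2

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)), constant_values=-np.inf)
        windows = sliding_window_view(xp, self.width, axis=1)  # (B, L, C, w)
        self._argmax = windows.argmax(axis=3)
        self._shape = x.shape
        return windows.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        batch, length, channels = self._shape
        dxp = np.zeros((batch, length + 2 * self.pad, channels))
        for dw in range(self.width):
            sel = self._argmax == dw
            contrib = np.where(sel, dout, 0.0)
            dxp[:, dw:dw + length, :] += contrib
        return dxp[:, self.pad:self.pad + length, :]


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    """Fully connected layer, optional ReLU."""

    l2_params = ("weight",)

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, relu: bool = True) -> None:
        super().__init__()
        self.relu = relu
        self.params = {
            "weight": he_uniform(rng, (in_features, out_features), in_features),
            "bias": np.zeros(out_features),
        }

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        self._x = x
        z = x @ self.params["weight"] + self.params["bias"]
        if self.relu:
            self._active = z > 0
            return np.where(self._active, z, 0.0)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * self._active if self.relu else dout
        self.grads = {"weight": self._x.T @ dz, "bias": dz.sum(axis=0)}
        return dz @ self.params["weight"].T


class InceptionBlock(Layer):
    """Parallel 1-D convolutions of several kernel sizes plus a max-pool
    branch, concatenated on the channel axis, followed by dropout.

    With kernel sizes (1, 3, 5) at f filters each and C input channels the
    output has 3f + C channels.
    """

    def __init__(self, in_channels: int, kernel_sizes: tuple[int, ...],
                 filters: int, dropout_rate: float, pool_width: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.convs = [Conv1D(in_channels, filters, k, rng) for k in kernel_sizes]
        self.pool = MaxPool1D(pool_width)
        self.dropout = Dropout(dropout_rate)
        self.out_channels = len(kernel_sizes) * filters + in_channels

    @property
    def sublayers(self) -> list[Layer]:
        return [*self.convs, self.pool, self.dropout]

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        branches = [conv.forward(x) for conv in self.convs]
        branches.append(self.pool.forward(x))
        self._splits = np.cumsum([b.shape[2] for b in branches])[:-1]
        out = np.concatenate(branches, axis=2)
        return self.dropout.forward(out, train, rng)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = self.dropout.backward(dout)
        pieces = np.split(dout, self._splits, axis=2)
        dx = self.pool.backward(pieces[-1])
        for conv, piece in zip(self.convs, pieces[:-1]):
            dx = dx + conv.backward(piece)
        return dx


class Adadelta:
    """Adadelta with running averages of squared gradients and updates."""

    def __init__(self, layers: list[Layer], rho: float = 0.95,
                 eps: float = 1e-6, lr: float = 1.0) -> None:
        self.layers = layers
        self.rho, self.eps, self.lr = rho, eps, lr
        self._eg2 = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in layers]
        self._ed2 = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in layers]

    def step(self, l2_weight: float = 0.0) -> None:
        for i, layer in enumerate(self.layers):
            for name, grad in layer.grads.items():
                if l2_weight and name in layer.l2_params:
                    grad = grad + l2_weight * layer.params[name]
                eg2, ed2 = self._eg2[i][name], self._ed2[i][name]
                eg2 *= self.rho
                eg2 += (1 - self.rho) * grad * grad
                delta = -np.sqrt(ed2 + self.eps) / np.sqrt(eg2 + self.eps) * grad
                ed2 *= self.rho
                ed2 += (1 - self.rho) * delta * delta
                layer.params[name] += self.lr * delta


def snapshot_params(layers: list[Layer]) -> list[dict[str, np.ndarray]]:
    return [{k: v.copy() for k, v in ly.params.items()} for ly in layers]


def restore_params(layers: list[Layer], snapshot: list[dict[str, np.ndarray]]) -> None:
    for layer, saved in zip(layers, snapshot):
        for k, v in saved.items():
            layer.params[k] = v.copy()
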