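"""A compact numpy neural-network engine: the layers, loss and optimizer
needed by the slice detectors.

Supports 2D convolution (3x3, stride 1, zero 'same' padding), 2x2 max
pooling, global average pooling, dense layers, ReLU, inverted dropout,
softmax cross-entropy with optional class weights, and RMSprop. Everything
is double precision and fully deterministic given the seeds, which keeps the
detector training reproducible bit-for-bit.

Array convention: images are (N, C, H, W); flat features are (N, D).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "MaxPool2x2", "GlobalAvgPool", "Flatten", "Dense", "ReLU",
    "Dropout", "Sequential", "RMSprop", "softmax", "softmax_cross_entropy",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    ll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float((w * ll).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad


class Layer:
    """Base layer: parameters live in ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - default
        pass

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero 'same' padding, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.cin * self.k * self.k
        self.params["W"] = rng.normal(0, np.sqrt(2.0 / fan_in),
                                      (self.cout, self.cin, self.k, self.k))
        self.params["b"] = np.zeros(self.cout)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, self.k, self.k, h, w))
        for i in range(self.k):
            for j in range(self.k):
                cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)  # (N, C, k, k, H, W)
        w = self.params["W"].reshape(self.cout, -1)
        n, c, _, _, h, wd = self._cols.shape
        out = w @ self._cols.reshape(n, c * self.k * self.k, h * wd)
        out = out.reshape(n, self.cout, h, wd) + self.params["b"][None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        cols = self._cols.reshape(n, -1, h * w)
        dflat = dout.reshape(n, self.cout, h * w)
        self.grads["W"] = np.einsum("nfp,ncp->fc", dflat, cols).reshape(
            self.params["W"].shape
        )
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        wmat = self.params["W"].reshape(self.cout, -1)
        dcols = np.einsum("fc,nfp->ncp", wmat, dflat).reshape(self._cols.shape)
        # col2im: scatter-add the column gradients back onto the padded grid
        p = self.k // 2
        dxp = np.zeros((n, self.cin, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2 (even H, W assumed; odd trailing row/col dropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : 2 * h2, : 2 * w2]
        self._in_shape = (n, c, h, w)
        xr = x.reshape(n, c, h2, 2, w2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        h2, w2 = dout.shape[2], dout.shape[3]
        dxr = self._mask * dout[:, :, :, None, :, None]
        dx = np.zeros((n, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = dxr.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int) -> None:
        super().__init__()
        self.din, self.dout_dim = in_dim, out_dim

    def init(self, rng: np.random.Generator) -> None:
        self.params["W"] = rng.normal(0, np.sqrt(2.0 / self.din),
                                      (self.din, self.dout_dim))
        self.params["b"] = np.zeros(self.dout_dim)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; active only during training, seeded per network."""

    def __init__(self, rate: float = 0.5) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._rng: np.random.Generator | None = None

    def init(self, rng: np.random.Generator) -> None:
        self._rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class RMSprop:
    """RMSprop: cache = rho*cache + (1-rho)*g^2; p -= lr * g / (sqrt(cache)+eps)."""

    def __init__(self, lr: float = 2e-4, rho: float = 0.9, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers: list[Layer]) -> None:
        for li, layer in enumerate(layers):
            if not layer.trainable:
                continue
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                cache = self._cache.setdefault(key, np.zeros_like(p))
                cache *= self.rho
                cache += (1 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(cache) + self.eps)


class Sequential:
    """A feed-forward stack with softmax cross-entropy training."""

    def __init__(self, layers: list[Layer], seed: int = 0,
                 init_params: bool = True) -> None:
        self.layers = layers
        self.seed = seed
        if init_params:
            rng = np.random.default_rng(seed)
            for layer in layers:
                if layer.trainable:  # frozen layers keep their preset weights
                    layer.init(rng)
        self.loss_history: list[float] = []
        self.accuracy_history: list[float] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward_until(self, x: np.ndarray, n_layers: int) -> np.ndarray:
        """Activations after the first ``n_layers`` layers (inference mode)."""
        for layer in self.layers[:n_layers]:
            x = layer.forward(x, train=False)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [softmax(self.forward(x[i : i + batch_size]))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.empty((0, 2))

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 32,
        optimizer: RMSprop | None = None,
        class_weight: dict[int, float] | None = None,
        shuffle_seed: int = 0,
    ) -> list[float]:
        """Mini-batch training; returns the per-epoch mean loss trace."""
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        y = np.asarray(y, dtype=int)
        opt = optimizer or RMSprop()
        rng = np.random.default_rng(shuffle_seed)
        n = len(x)
        weights = None
        if class_weight is not None:
            weights = np.array([class_weight[int(c)] for c in y])
        for _ in range(epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.forward(x[idx], train=True)
                sw = weights[idx] if weights is not None else None
                loss, grad = softmax_cross_entropy(logits, y[idx], sw)
                correct += int((logits.argmax(axis=1) == y[idx]).sum())
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step(self.layers)
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
            self.accuracy_history.append(correct / n)
        return self.loss_history

    # -- parameter bookkeeping --------------------------------------------
    def parameter_count(self, trainable_only: bool = False) -> int:
        return sum(
            p.size
            for layer in self.layers
            if (layer.trainable or not trainable_only)
            for p in layer.params.values()
        )

    def get_parameters(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_parameters(self, params: list[dict[str, np.ndarray]]) -> None:
        for layer, p in zip(self.layers, params):
            for k, v in p.items():
                layer.params[k] = v.copy()
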