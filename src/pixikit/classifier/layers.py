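"""Minimal CNN building blocks on numpy arrays.

Layout is NCHW throughout.  Each layer owns its parameters and gradients in
name-keyed dicts so the optimizer and the serializer can address them
uniformly; ``trainable`` lets a frozen backbone share the same machinery.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: parameter-free unless a subclass adds params."""

    trainable = True

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def describe(self) -> dict:
        return {"type": type(self).__name__, "name": self.name, "trainable": self.trainable}


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, via im2col."""

    def __init__(self, name: str, in_channels: int, out_channels: int,
                 kernel: int, rng: np.random.Generator):
        super().__init__(name)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        # He initialization, suited to the ReLU that follows
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(out_channels, fan_in))
        self.params["b"] = np.zeros(out_channels)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.kernel, self.kernel),
                                                       axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, c*k*k, h*w)
        return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * self.kernel ** 2, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        n, _, hw = self._cols.shape
        h, w = x.shape[2], x.shape[3]
        out = np.einsum("fk,nkp->nfp", self.params["W"], self._cols)
        out += self.params["b"][None, :, None]
        return out.reshape(n, self.out_channels, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        dflat = dout.reshape(n, f, h * w)
        self.grads["W"] = np.einsum("nfp,nkp->fk", dflat, self._cols)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfp->nkp", self.params["W"], dflat)
        # col2im: scatter the k*k offsets back onto the padded grid
        k = self.kernel
        p = k // 2
        c = self.in_channels
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        dcols = dcols.reshape(n, c, k, k, h, w)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]

    def describe(self) -> dict:
        d = super().describe()
        d.update(in_channels=self.in_channels, out_channels=self.out_channels,
                 kernel=self.kernel)
        return d


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : h2 * 2, : w2 * 2]
        self._x_shape = (n, c, h, w)
        windows = x.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        windows = windows.reshape(n, c, h2, w2, 4)
        self._argmax = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        h2, w2 = h // 2, w // 2
        onehot = np.eye(4, dtype=dout.dtype)[self._argmax]  # (n,c,h2,w2,4)
        d = onehot * dout[..., None]
        d = d.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = d.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(Layer):
    def __init__(self, name: str, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__(name)
        self.in_features = in_features
        self.out_features = out_features
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.params["W"] = rng.uniform(-limit, limit, size=(in_features, out_features))
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T

    def describe(self) -> dict:
        d = super().describe()
        d.update(in_features=self.in_features, out_features=self.out_features)
        return d


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y_idx: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y_idx)), y_idx] + eps).mean())


class Network:
    """A feed-forward stack of layers with a softmax output."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def backward_from_probs(self, probs: np.ndarray, y_idx: np.ndarray) -> None:
        """Gradient of mean cross-entropy w.r.t. logits, then backprop."""
        n = len(y_idx)
        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def named_params(self):
        for layer in self.layers:
            for pname, arr in layer.params.items():
                yield f"{layer.name}/{pname}", layer, pname, arr

    def describe(self) -> list[dict]:
        return [layer.describe() for layer in self.layers]
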