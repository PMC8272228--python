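"""A compact CPU-trainable convolutional network in pure numpy.

Implements exactly what the four-class difference-heat-map classifier needs:
3x3 same-padding convolutions (im2col), ReLU, 2x2 max pooling, dense layers,
softmax cross-entropy and the Adam optimizer.  Single-threaded and fully
deterministic under a seed.

Shapes follow the (N, C, H, W) convention; parameters are float32.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-8


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d:
    """3x3 convolution with same padding, stride 1, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.W = _he_init(rng, (out_ch, in_ch * k * k), in_ch * k * k)
        self.b = np.zeros(out_ch, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, c*k*k, h*w)
        return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        n, _, h, w = x.shape
        out = np.einsum("oc,ncp->nop", self.W, self._cols, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = self._x_shape
        k, p = self.k, self.k // 2
        dflat = dout.reshape(n, self.out_ch, h * w)
        self.dW = np.einsum("nop,ncp->oc", dflat, self._cols, optimize=True)
        self.db = dflat.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.W, dflat, optimize=True)
        dcols = dcols.reshape(n, self.in_ch, k, k, h, w)
        dx = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dx[:, :, p : p + h, p : p + w]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._x_shape = x.shape
        xt = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        flat = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx

    def params(self):
        return []


class Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = _he_init(rng, (in_dim, out_dim), in_dim)
        self.b = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over all layer parameters."""

    def __init__(self, layers, lr: float, beta1: float = 0.9, beta2: float = 0.999):
        self.layers = layers
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.layers):
            for name, param, grad_attr in layer.params():
                g = getattr(layer, grad_attr)
                key = (li, name)
                m = self.m.setdefault(key, np.zeros_like(param))
                v = self.v.setdefault(key, np.zeros_like(param))
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + _EPS)


class SmallCNN:
    """Four-block convolutional classifier for square single-channel images.

    conv3x3 -> ReLU -> maxpool2, repeated over ``channels``, then a hidden
    dense layer and a linear output head.
    """

    def __init__(
        self,
        in_size: int,
        n_classes: int,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        hidden: int = 64,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.in_size = in_size
        self.n_classes = n_classes
        layers: list = []
        c_prev, s = 1, in_size
        for c in channels:
            layers += [Conv2d(c_prev, c, rng), ReLU(), MaxPool2()]
            c_prev, s = c, s // 2
        if s < 1:
            raise ValueError(f"input size {in_size} too small for {len(channels)} pooling stages")
        layers += [Flatten(), Dense(c_prev * s * s, hidden, rng), ReLU(), Dense(hidden, n_classes, rng)]
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(probs)

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> float:
        """One forward/backward/update pass; returns mean cross-entropy."""
        logits = self.forward(x)
        probs = softmax(logits)
        n = len(x)
        loss = -np.log(probs[np.arange(n), y] + _EPS).mean()
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        self.backward(dlogits / n)
        optimizer.step()
        return float(loss)
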