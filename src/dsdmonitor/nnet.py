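"""A small LeNet-derived convolutional network, implemented on numpy.

Architecture (defaults): four 5x5 convolution blocks with SAME padding,
stride 1, ReLU and 2x2 max pooling, followed by three fully-connected
layers ending in a 2-way softmax.  Index 1 of the output is the
descending-duodenum (DSD) class everywhere in this package, so the
classifier's "probability score" is the softmax output for class 1.

Training minimises the focal loss

    FL(p_t) = -alpha_t * (1 - p_t)**gamma * log(p_t)

with p_t the predicted probability of the true class, alpha_t = alpha for
the DSD class and 1 - alpha otherwise, optimised with Adam.  At gamma = 0,
alpha = 0.5 the loss reduces to half the binary cross-entropy.

Everything runs in float32 with im2col/GEMM convolutions; forward and
backward passes are deterministic for a fixed parameter state, and
initialisation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Network",
    "build_network",
    "focal_loss",
    "focal_loss_grad",
    "softmax",
]

_EPS = 1e-7  # probability clamp inside the loss


@dataclass(frozen=True)
class NetworkSpec:
    """Shape of the classifier: conv filter counts and FC widths.

    The layer counts (4 conv, 3 FC) are the operating point of the method;
    the per-layer widths are engineering defaults sized for CPU training
    and are freely configurable.
    """

    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    fc_widths: tuple[int, ...] = (512, 128, 2)
    kernel_size: int = 5
    stride: int = 1
    padding: str = "same"
    pooling: str = "max"
    activation: str = "relu"

    def __post_init__(self) -> None:
        if len(self.conv_filters) < 1 or len(self.fc_widths) < 1:
            raise ValueError("need at least one conv and one FC layer")
        if self.fc_widths[-1] != 2:
            raise ValueError("final FC width must be 2 (binary softmax)")
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError("kernel_size and stride must be positive")
        if self.padding.lower() != "same":
            raise ValueError("only SAME padding is supported")
        if self.pooling.lower() != "max":
            raise ValueError("only max pooling is supported")
        if self.activation.lower() != "relu":
            raise ValueError("only ReLU activation is supported")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe: Adam(2e-4, 0.9, 0.999), batch 64, focal loss."""

    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 20
    gamma: float = 2.0  # focal-loss focusing exponent
    alpha: float = 0.25  # focal-loss DSD-class weight
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("Adam betas must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------


def focal_loss(p, y, gamma: float = 2.0, alpha: float = 0.25) -> np.ndarray:
    """Focal loss of predicted DSD probability ``p`` against label ``y``.

    Vectorised over arrays; probabilities are clamped to
    ``[1e-7, 1 - 1e-7]`` so the endpoints stay finite.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if np.any(~np.isfinite(p)):
        raise ValueError("probabilities must be finite")
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    pt = np.where(y == 1, pc, 1.0 - pc)
    at = np.where(y == 1, alpha, 1.0 - alpha)
    return at * (1.0 - pt) ** gamma * (-np.log(pt))


def focal_loss_grad(p, y, gamma: float = 2.0, alpha: float = 0.25) -> np.ndarray:
    """Analytic d(focal loss)/dp, matching :func:`focal_loss` elementwise."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    pt = np.where(y == 1, pc, 1.0 - pc)
    at = np.where(y == 1, alpha, 1.0 - alpha)
    # dL/dpt = at * (gamma (1-pt)^{gamma-1} log pt - (1-pt)^gamma / pt)
    if gamma == 0:
        dl_dpt = -at / pt
    else:
        dl_dpt = at * (
            gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt) - (1.0 - pt) ** gamma / pt
        )
    return np.where(y == 1, dl_dpt, -dl_dpt)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv2D:
    """5x5 SAME convolution via im2col + GEMM; input layout (N, H, W, C)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        self.k = k
        self.w = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (n, h, w, c, k, k) -> (n*h*w, k*k*c) with (k, k, c) ordering
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        cols = self._im2col(x)
        out = cols @ self.w + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, h, w, c = xshape
        k = self.k
        pad = k // 2
        dyf = dy.reshape(n * h * w, -1).astype(np.float32)
        self.dw = cols.T @ dyf
        self.db = dyf.sum(axis=0)
        dcols = (dyf @ self.w.T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=np.float32)
        for ki in range(k):  # 25 slice-adds instead of a scatter
            for kj in range(k):
                dxp[:, ki : ki + h, kj : kj + w, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, pad : pad + h, pad : pad + w, :]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class _ReLU:
    def forward(self, x, train):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        xr = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx = idx
            self._xshape = x.shape
        return out

    def backward(self, dy):
        n, h, w, c = self._xshape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, 4, c), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dxr.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(
                n, 2 * h2, 2 * w2, c
            )
        )
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(
            np.float32
        )
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class Network:
    """The stacked classifier; build via :func:`build_network`."""

    def __init__(self, spec: NetworkSpec, input_shape: tuple[int, int], seed: int = 0):
        h, w = input_shape
        n_conv = len(spec.conv_filters)
        if min(h, w) < 2**n_conv:
            raise ValueError(
                f"input {input_shape} too small for {n_conv} conv/pool blocks "
                f"(needs min side >= {2 ** n_conv})"
            )
        self.spec = spec
        self.input_shape = input_shape
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.layers: list = []
        c, hh, ww = 1, h, w
        for f in spec.conv_filters:
            self.layers += [_Conv2D(c, f, spec.kernel_size, rng), _ReLU(), _MaxPool2()]
            c, hh, ww = f, hh // 2, ww // 2
        self.layers.append(_Flatten())
        d = c * hh * ww
        for i, width in enumerate(spec.fc_widths):
            self.layers.append(_Dense(d, width, rng))
            if i < len(spec.fc_widths) - 1:
                self.layers.append(_ReLU())
            d = width

    # -- inference -----------------------------------------------------------

    def _as_batch(self, frames: np.ndarray) -> np.ndarray:
        x = np.asarray(frames, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != self.input_shape:
            raise ValueError(
                f"frame shape {x.shape[1:3]} does not match network input "
                f"{self.input_shape}"
            )
        return x

    def forward(self, frames: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities, shape (n, 2); column 1 is the DSD score."""
        x = self._as_batch(frames)
        for layer in self.layers:
            x = layer.forward(x, train)
        return softmax(x.astype(np.float64))

    def predict_score(self, frames: np.ndarray) -> np.ndarray:
        """Per-frame DSD probability score in [0, 1]."""
        return self.forward(frames)[:, 1]

    # -- training ------------------------------------------------------------

    def loss_and_backward(self, frames, labels, gamma, alpha) -> float:
        """Mean focal loss on a batch; leaves gradients on every layer."""
        probs = self.forward(frames, train=True)
        y = np.asarray(labels).astype(np.int64)
        p1 = probs[:, 1]
        loss = float(np.mean(focal_loss(p1, y, gamma, alpha)))

        # Chain rule through pt = prob of the true class and the softmax:
        # dL/dz_j = dL/dpt * pt * (delta_tj - p_j).
        pc = np.clip(probs, _EPS, 1.0 - _EPS)
        pt = pc[np.arange(len(y)), y]
        at = np.where(y == 1, alpha, 1.0 - alpha)
        if gamma == 0:
            dl_dpt = -at / pt
        else:
            dl_dpt = at * (
                gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt)
                - (1.0 - pt) ** gamma / pt
            )
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(y)), y] = 1.0
        dz = dl_dpt[:, None] * pt[:, None] * (onehot - probs) / len(y)
        dz = dz.astype(np.float32)

        grad = dz
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def make_optimizer(self, cfg: TrainConfig) -> _Adam:
        return _Adam(self.params(), cfg.learning_rate, cfg.beta1, cfg.beta2)

    # -- serialization -------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError("weight shapes do not match architecture")
            p[...] = w


def build_network(
    spec: NetworkSpec = NetworkSpec(),
    input_shape: tuple[int, int] = (64, 64),
    seed: int = 0,
) -> Network:
    """Construct an untrained classifier for ``input_shape`` frames."""
    if input_shape[0] < 1 or input_shape[1] < 1:
        raise ValueError("input shape must be positive")
    return Network(spec, tuple(input_shape), seed)
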