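"""A small 2D U-Net for binary segmentation, in pure NumPy.

The network is the classic encoder/decoder with skip connections:
``depth`` encoder blocks (two 3x3 conv + ReLU, then 2x2 max-pool), a
bottleneck block, and ``depth`` decoder blocks (nearest-neighbour x2
upsample followed by a 3x3 "up-convolution", concatenation with the skip
tensor, then two 3x3 conv + ReLU).  A 1x1 convolution produces one logit
per pixel; the sigmoid lives in the loss / prediction code.

Everything — forward pass, backward pass — is explicit NumPy so that
training is bit-reproducible on a single CPU thread: no framework,
no nondeterministic kernels.  Convolutions are im2col + matmul.

Parameters are kept as an ordered ``{name: array}`` mapping whose order
defines the weight-set manifest for federated exchange.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the segmentation network and its local training.

    ``input_shape`` (H, W) must be divisible by ``2**depth`` so that the
    pooling / upsampling ladder closes exactly.
    """

    depth: int = 2
    base_filters: int = 8
    input_shape: tuple[int, int] = (64, 64)
    learning_rate: float = 3e-3
    batch_size: int = 4
    # bce_dice keeps gradients alive when the prediction collapses towards
    # all-background, where pure soft-Dice cannot recover
    loss_name: str = "bce_dice"

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_filters < 1:
            raise ConfigurationError("base_filters must be >= 1")
        h, w = self.input_shape
        f = 2**self.depth
        if h % f or w % f:
            raise ConfigurationError(
                f"input_shape {self.input_shape} not divisible by 2**depth = {f}"
            )
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.loss_name not in ("dice_loss", "bce_dice"):
            raise ConfigurationError(f"unknown loss {self.loss_name!r}")


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,Hp,Wp) padded input -> (N, C*k*k, H*W) patch matrix."""
    n, c = x.shape[:2]
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    h, w = win.shape[2], win.shape[3]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w), h, w


def _col2im(dcols: np.ndarray, n: int, c: int, h: int, w: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` with 'same' zero padding."""
    p = k // 2
    dx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, k, k, h, w)
    for a in range(k):
        for b in range(k):
            dx[:, :, a : a + h, b : b + w] += d6[:, :, a, b]
    return dx[:, :, p : p + h, p : p + w] if p else dx


def conv2d_forward(x, w, b):
    """'Same' convolution (odd kernel). x:(N,Cin,H,W), w:(Cout,Cin,k,k)."""
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    cols, h, ww = _im2col(xp, k)
    wmat = w.reshape(w.shape[0], -1)
    y = np.matmul(wmat, cols) + b[:, None]
    y = y.reshape(x.shape[0], w.shape[0], h, ww)
    return y, (cols, x.shape, k)


def conv2d_backward(dy, w, cache):
    cols, x_shape, k = cache
    n, cin, h, ww = x_shape
    cout = w.shape[0]
    dyf = dy.reshape(n, cout, h * ww)
    db = dyf.sum(axis=(0, 2))
    dwmat = np.einsum("nop,ncp->oc", dyf, cols, optimize=True)
    dw = dwmat.reshape(w.shape)
    wmat = w.reshape(cout, -1)
    dcols = np.matmul(wmat.T, dyf)  # (N, Cin*k*k, H*W)
    dx = _col2im(dcols, n, cin, h, ww, k)
    return dx, dw, db


def relu_forward(x):
    return np.maximum(x, 0), x > 0


def relu_backward(dy, mask):
    return dy * mask


def maxpool2_forward(x):
    """2x2 max pooling, stride 2; ties broken towards the first element."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy, cache):
    idx, (n, c, h, w) = cache
    flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
    xr = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return xr.reshape(n, c, h, w)


def upsample2_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet2D:
    """Functional U-Net: parameters live outside the object.

    ``dtype`` defaults to float32 (the exchange dtype); float64 is used by
    the finite-difference gradient checks in the test suite.
    """

    def __init__(self, config: ModelConfig, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)

    # -- architecture plan --------------------------------------------

    def conv_specs(self) -> Iterator[tuple[str, int, int, int]]:
        """Yield (name, c_in, c_out, kernel) for every convolution, in
        parameter order."""
        cfg = self.config
        c_prev = 1
        for i in range(1, cfg.depth + 1):
            c = cfg.base_filters * 2 ** (i - 1)
            yield f"enc{i}.conv1", c_prev, c, 3
            yield f"enc{i}.conv2", c, c, 3
            c_prev = c
        c_bott = cfg.base_filters * 2**cfg.depth
        yield "bottleneck.conv1", c_prev, c_bott, 3
        yield "bottleneck.conv2", c_bott, c_bott, 3
        c_prev = c_bott
        for i in range(cfg.depth, 0, -1):
            c_skip = cfg.base_filters * 2 ** (i - 1)
            yield f"dec{i}.up", c_prev, c_skip, 3
            yield f"dec{i}.conv1", 2 * c_skip, c_skip, 3
            yield f"dec{i}.conv2", c_skip, c_skip, 3
            c_prev = c_skip
        yield "head", c_prev, 1, 1

    def param_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        shapes = []
        for name, cin, cout, k in self.conv_specs():
            shapes.append((f"{name}.w", (cout, cin, k, k)))
            shapes.append((f"{name}.b", (cout,)))
        return shapes

    def n_parameters(self) -> int:
        return sum(int(np.prod(s)) for _, s in self.param_shapes())

    # -- initialization ------------------------------------------------

    def init_params(self, seed: int) -> dict[str, np.ndarray]:
        """He-normal weights, zero biases; deterministic in ``seed``."""
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        for name, cin, cout, k in self.conv_specs():
            fan_in = cin * k * k
            std = np.sqrt(2.0 / fan_in)
            params[f"{name}.w"] = (rng.standard_normal((cout, cin, k, k)) * std).astype(
                self.dtype
            )
            params[f"{name}.b"] = np.zeros(cout, dtype=self.dtype)
        return params

    # -- forward / backward --------------------------------------------

    def _conv_relu(self, params, name, x, cache):
        y, c = conv2d_forward(x, params[f"{name}.w"], params[f"{name}.b"])
        a, m = relu_forward(y)
        cache[name] = (c, m)
        return a

    def forward(self, params: dict, x: np.ndarray):
        """x: (N,1,H,W) -> per-pixel logits (N,1,H,W) plus backward cache."""
        cfg = self.config
        x = np.ascontiguousarray(x, dtype=self.dtype)
        cache: dict = {}
        skips = []
        h = x
        for i in range(1, cfg.depth + 1):
            h = self._conv_relu(params, f"enc{i}.conv1", h, cache)
            h = self._conv_relu(params, f"enc{i}.conv2", h, cache)
            skips.append(h)
            h, pc = maxpool2_forward(h)
            cache[f"pool{i}"] = pc
        h = self._conv_relu(params, "bottleneck.conv1", h, cache)
        h = self._conv_relu(params, "bottleneck.conv2", h, cache)
        for i in range(cfg.depth, 0, -1):
            h = upsample2_forward(h)
            h = self._conv_relu(params, f"dec{i}.up", h, cache)
            skip = skips[i - 1]
            cache[f"cat{i}_channels"] = (skip.shape[1], h.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = self._conv_relu(params, f"dec{i}.conv1", h, cache)
            h = self._conv_relu(params, f"dec{i}.conv2", h, cache)
        logits, hc = conv2d_forward(h, params["head.w"], params["head.b"])
        cache["head"] = hc
        return logits, cache

    def _conv_relu_back(self, params, name, d, cache, grads):
        c, m = cache[name]
        d = relu_backward(d, m)
        dx, dw, db = conv2d_backward(d, params[f"{name}.w"], c)
        grads[f"{name}.w"] = dw
        grads[f"{name}.b"] = db
        return dx

    def backward(self, params: dict, cache: dict, dlogits: np.ndarray):
        """Gradient of the loss w.r.t. every parameter, given d loss/d logits."""
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        d, dw, db = conv2d_backward(
            np.ascontiguousarray(dlogits, dtype=self.dtype),
            params["head.w"],
            cache["head"],
        )
        grads["head.w"] = dw
        grads["head.b"] = db
        dskips = [None] * cfg.depth
        for i in range(1, cfg.depth + 1):
            d = self._conv_relu_back(params, f"dec{i}.conv2", d, cache, grads)
            d = self._conv_relu_back(params, f"dec{i}.conv1", d, cache, grads)
            n_skip, _ = cache[f"cat{i}_channels"]
            dskips[i - 1] = d[:, :n_skip]
            d = d[:, n_skip:]
            d = self._conv_relu_back(params, f"dec{i}.up", d, cache, grads)
            d = upsample2_backward(d)
        d = self._conv_relu_back(params, "bottleneck.conv2", d, cache, grads)
        d = self._conv_relu_back(params, "bottleneck.conv1", d, cache, grads)
        for i in range(cfg.depth, 0, -1):
            d = maxpool2_backward(d, cache[f"pool{i}"])
            d = d + dskips[i - 1]
            d = self._conv_relu_back(params, f"enc{i}.conv2", d, cache, grads)
            d = self._conv_relu_back(params, f"enc{i}.conv1", d, cache, grads)
        return grads
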