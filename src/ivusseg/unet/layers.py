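"""NumPy neural-network layers with hand-derived backpropagation.

All layers operate on NCHW float32 tensors.  Each layer caches what its
backward pass needs during ``forward``; ``backward`` consumes the upstream
gradient and returns the input gradient, storing parameter gradients on the
layer (``dw``/``db``) for the optimizer.  Convolutions use im2col so both
passes reduce to BLAS matmuls; the data gradient of a 3x3 convolution is
itself a 3x3 convolution with the spatially flipped, channel-transposed
kernel, which avoids a slow scatter (col2im).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for a padded 3x3 window."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # windows: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Conv3x3:
    """3x3 convolution, stride 1, 'same' zero padding."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        # He initialization for ReLU networks
        std = np.sqrt(2.0 / (cin * 9))
        self.w = rng.normal(0.0, std, size=(cin * 9, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        out = cols @ self.w + self.b
        if train:
            self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def _flipped_kernel(self) -> np.ndarray:
        """(cout*9, cin) kernel computing the data gradient."""
        w4 = self.w.reshape(self.cin, 3, 3, self.cout)
        wf = w4[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (cout, 3, 3, cin)
        return np.ascontiguousarray(wf.reshape(self.cout * 9, self.cin))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        self.dw = self._cols.T @ dmat
        self.db = dmat.sum(axis=0)
        self._cols = None
        dcols = _im2col3(dout) @ self._flipped_kernel()
        return dcols.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class Conv1x1:
    """1x1 convolution (per-pixel linear map), used for the class logits."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, std, size=(cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xm = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        if train:
            self._x = xm
        out = xm @ self.w + self.b
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.dw = self._x.T @ dmat
        self.db = dmat.sum(axis=0)
        self._x = None
        dx = dmat @ self.w.T
        return dx.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Dropout:
    """Inverted dropout; identity outside training or at rate 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        self._idx = None
        return dx


class Upsample2:
    """2x2 nearest-neighbor upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Per-pixel softmax + categorical cross-entropy.

    Returns (mean loss, dlogits, probabilities).  ``labels`` is (N, H, W)
    int; optional ``class_weights`` reweight each pixel's loss by the weight
    of its true class (normalized so the mean pixel weight is ~1).
    """
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    onehot_idx = labels[:, None, :, :]
    p_true = np.take_along_axis(probs, onehot_idx, axis=1)[:, 0]
    if class_weights is None:
        wpix = np.ones_like(p_true)
    else:
        cw = np.asarray(class_weights, dtype=np.float64)
        wpix = cw[labels]
    denom = wpix.sum()
    loss = float(-(wpix * np.log(np.maximum(p_true, 1e-12))).sum() / denom)
    grad = probs.copy()
    np.put_along_axis(grad, onehot_idx, np.take_along_axis(grad, onehot_idx, axis=1) - 1.0, axis=1)
    grad *= (wpix / denom)[:, None, :, :]
    return loss, grad.astype(np.float32), probs


class Adam:
    """Adam optimizer over a list of (layer, attr) parameter slots."""

    def __init__(self, layers: list, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots = []
        for layer in layers:
            for attr in ("w", "b"):
                if hasattr(layer, attr):
                    self.slots.append((layer, attr))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, a)) for l, a in self.slots]
        self.v = [np.zeros_like(getattr(l, a)) for l, a in self.slots]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (layer, attr) in enumerate(self.slots):
            g = getattr(layer, "d" + attr)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p = getattr(layer, attr)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
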