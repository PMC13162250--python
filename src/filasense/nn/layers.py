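"""Minimal NHWC neural-network layers on NumPy.

Convolutions are evaluated as im2col + GEMM in float32, which keeps a
7-conv-layer network trainable on a single CPU core.  All layers follow the
same contract: ``forward(x, mode)`` caches what ``backward(dy)`` needs;
``backward`` returns the gradient w.r.t. the input and fills ``.grads``
aligned with ``.params``.

``mode`` is one of

* ``"train"`` — batch statistics, dropout active, caches kept;
* ``"eval"``  — running statistics, dropout off, no caches;
* ``"grad"``  — inference semantics but caches kept, so gradients of the
  class score w.r.t. intermediate activations can be taken (Grad-CAM).
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    name: str = ""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _row_cols(x: np.ndarray, k: int) -> np.ndarray:
    """Row-decomposed im2col for same-padding kxk convolution.

    Returns ``cols`` of shape (k, N*H*W, k*C): ``cols[i]`` holds, for every
    output pixel, the k*C contiguous values of padded input row ``h+i`` at
    columns ``w..w+k``.  Assembled with k large slice copies (inner chunks of
    k*C floats) instead of a 4-byte-gather reshape, which is what makes the
    convolution CPU-viable.
    """
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    flat = xp.reshape(n, h + 2 * p, (w + 2 * p) * c)
    s = flat.strides
    win = np.lib.stride_tricks.as_strided(
        flat, shape=(n, h + 2 * p, w, k * c),
        strides=(s[0], s[1], c * flat.itemsize, flat.itemsize))
    cols = np.empty((k, n, h, w, k * c), dtype=x.dtype)
    for i in range(k):
        np.copyto(cols[i], win[:, i:i + h])
    return cols.reshape(k, n * h * w, k * c)


class Conv2D(Layer):
    """kxk same-padding convolution, stride 1, NHWC (k=3 by default).

    Weights are stored flattened as ``(k*k*C, F)`` in (row, col, channel)
    order; each pass is k GEMMs over the row-decomposed im2col buffer.
    Initialisation is uniform fan-in, U(-1/sqrt(fan_in), +1/sqrt(fan_in)).
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, *, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k * k
        bound = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-bound, bound, size=(fan_in, out_ch)).astype(F32)
        b = np.zeros(out_ch, dtype=F32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] = ()

    @property
    def n_params(self) -> int:
        return self.params[0].size + self.params[1].size

    def kernel(self) -> np.ndarray:
        """Weights as (k, k, C, F)."""
        k = self.k
        return self.params[0].reshape(k, k, self.in_ch, self.out_ch)

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        n, h, w, _ = x.shape
        k, kc = self.k, self.k * self.in_ch
        cols = _row_cols(x, k)
        wmat = self.params[0]
        y = cols[0] @ wmat[:kc]
        for i in range(1, k):
            y += cols[i] @ wmat[i * kc:(i + 1) * kc]
        y += self.params[1]
        if mode != "eval":
            self._cols = cols
            self._shape = x.shape
        return y.reshape(n, h, w, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, f = dy.shape
        k, kc = self.k, self.k * self.in_ch
        dyr = dy.reshape(n * h * w, f)
        assert self._cols is not None
        for i in range(k):
            self.grads[0][i * kc:(i + 1) * kc] = self._cols[i].T @ dyr
        self.grads[1][...] = dyr.sum(axis=0)
        self._cols = None  # release im2col memory early
        # dX = full correlation of dy with the flipped kernel, same GEMM scheme:
        # dX[h,w,c] = sum_{u,v,f} dy[h+u-p, w+v-p, f] * K[k-1-u, k-1-v, c, f]
        kern = self.kernel()
        wback = kern[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k, k * f, self.in_ch)
        dycols = _row_cols(dy.astype(F32, copy=False), k)
        dx = dycols[0] @ wback[0]
        for u in range(1, k):
            dx += dycols[u] @ wback[u]
        return dx.reshape(self._shape)


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, H, W); running stats at inference."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        gamma = np.ones(ch, dtype=F32)
        beta = np.zeros(ch, dtype=F32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if mode == "train":
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean) * inv
        y = xhat * self.params[0] + self.params[1]
        if mode != "eval":
            self._cache = (xhat.astype(F32, copy=False), inv, axes, mode)
        return y.astype(F32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes, mode = self._cache
        self._cache = None
        gamma = self.params[0]
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        if mode == "grad":
            # running statistics are constants: the map is affine per channel
            return (dy * gamma * inv).astype(F32, copy=False)
        dxhat = dy * gamma
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) * inv
        return dx.astype(F32, copy=False)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        y = np.maximum(x, 0)
        if mode != "eval":
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first maximum."""

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if mode != "eval":
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        self._cache = None
        n, h, w, c = shape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
        dx = flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dx).reshape(shape)


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] = ()

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(n_in)
        w = rng.uniform(-bound, bound, size=(n_in, n_out)).astype(F32)
        b = np.zeros(n_out, dtype=F32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        if mode != "eval":
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.params[0].T


class Dropout(Layer):
    """Inverted dropout; active only in ``"train"`` mode."""

    def __init__(self, rate: float, *, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, mode: str) -> np.ndarray:
        if mode != "train" or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(F32)


def tune_allocator() -> None:
    """Ask glibc to retain large freed buffers instead of returning them to
    the OS.  Training repeatedly allocates ~hundred-MB im2col buffers; without
    this the allocator round-trips them through mmap/munmap and page faults
    dominate the step time.  Best-effort: silently does nothing off glibc."""
    try:
        import ctypes
        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(-3, 1 << 30)   # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)   # M_TRIM_THRESHOLD
    except Exception:
        pass
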