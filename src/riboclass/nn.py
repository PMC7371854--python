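"""A compact feed-forward / recurrent neural-network engine on numpy.

Implements exactly the layers the sequence classifiers need — one-hot input
expansion with a silent pad code, 1-D convolution, max pooling, inverted
dropout, dense softmax output, and a bidirectional LSTM — together with Adam
optimisation and a mini-batch training loop that records per-epoch training
and validation loss/accuracy.

Everything is deterministic given a :class:`numpy.random.Generator`: weight
initialisation, batch shuffling and dropout masks all draw from the single
generator handed to the model, so refitting with the same seed reproduces
the fitted weights bit-for-bit.

Gradients are hand-derived; ``tests`` verify every layer against central
finite differences.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "OneHot",
    "Conv1D",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "BiLSTM",
    "Sequential",
]


DEFAULT_DTYPE = np.float32


def _glorot(
    rng: np.random.Generator, shape: tuple[int, ...], dtype=DEFAULT_DTYPE
) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(
    rng: np.random.Generator, rows: int, cols: int, dtype=DEFAULT_DTYPE
) -> np.ndarray:
    """Column-block orthogonal init (the standard recurrent-kernel choice)."""
    blocks = []
    for start in range(0, cols, rows):
        a = rng.normal(size=(rows, rows))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        blocks.append(q[:, : min(rows, cols - start)])
    return np.concatenate(blocks, axis=1).astype(dtype)


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, rng: np.random.Generator, dtype=DEFAULT_DTYPE) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class OneHot(Layer):
    """Expand integer base codes (B, L) to one-hot channels (B, L, depth).

    Code 0 is the pad and maps to the all-zero row, so padding contributes no
    signal to downstream layers.
    """

    def __init__(self, depth: int = 4):
        super().__init__()
        self.depth = depth
        self.dtype = DEFAULT_DTYPE

    def build(self, rng, dtype=DEFAULT_DTYPE):
        self.dtype = dtype

    def forward(self, x, train, rng):
        out = np.zeros((*x.shape, self.depth), dtype=self.dtype)
        mask = x > 0
        idx = np.nonzero(mask)
        out[idx[0], idx[1], x[mask] - 1] = 1.0
        return out

    def backward(self, dout):
        return dout  # input is discrete; nothing upstream needs a gradient


class Conv1D(Layer):
    """Valid-mode 1-D convolution with ReLU, stride 1."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int):
        super().__init__()
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        if filters < 1 or kernel_size < 1:
            raise ValueError("filters and kernel size must be positive")

    def build(self, rng, dtype=DEFAULT_DTYPE):
        k, c, f = self.kernel_size, self.in_channels, self.filters
        self.params = {
            "W": _glorot(rng, (k * c, f), dtype),
            "b": np.zeros(f, dtype=dtype),
        }

    def forward(self, x, train, rng):
        b, length, c = x.shape
        k = self.kernel_size
        if length < k:
            raise ValueError(f"input length {length} shorter than kernel {k}")
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        # windows: (B, Lout, C, k) -> cols (B, Lout, k*C) in (k, C) order
        cols = windows.transpose(0, 1, 3, 2).reshape(b, length - k + 1, k * c)
        z = cols @ self.params["W"] + self.params["b"]
        self._cols = cols
        self._mask = z > 0
        self._in_shape = x.shape
        return np.where(self._mask, z, 0.0)

    def backward(self, dout):
        dz = dout * self._mask
        b, lout, _ = dz.shape
        k, c = self.kernel_size, self.in_channels
        self.grads["W"] = np.einsum("blk,blf->kf", self._cols, dz)
        self.grads["b"] = dz.sum(axis=(0, 1))
        dcols = dz @ self.params["W"].T  # (B, Lout, k*C)
        dcols = dcols.reshape(b, lout, k, c)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        for j in range(k):
            dx[:, j : j + lout, :] += dcols[:, :, j, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (remainder dropped)."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        if pool_size < 1:
            raise ValueError("pool size must be positive")
        self.pool_size = pool_size

    def forward(self, x, train, rng):
        b, length, c = x.shape
        p = self.pool_size
        nb = length // p
        blocks = x[:, : nb * p, :].reshape(b, nb, p, c)
        self._argmax = blocks.argmax(axis=2)
        self._in_shape = x.shape
        return blocks.max(axis=2)

    def backward(self, dout):
        b, nb, c = dout.shape
        p = self.pool_size
        dblocks = np.zeros((b, nb, p, c), dtype=dout.dtype)
        bi, ni, ci = np.ogrid[:b, :nb, :c]
        dblocks[bi, ni, self._argmax, ci] = dout
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : nb * p, :] = dblocks.reshape(b, nb * p, c)
        return dx


class Dropout(Layer):
    """Inverted dropout: active during training only."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected linear layer (softmax lives in the loss)."""

    def __init__(self, in_dim: int, out_dim: int):
        super().__init__()
        if out_dim < 1 or in_dim < 1:
            raise ValueError("layer sizes must be positive")
        self.in_dim, self.out_dim = in_dim, out_dim

    def build(self, rng, dtype=DEFAULT_DTYPE):
        self.params = {
            "W": _glorot(rng, (self.in_dim, self.out_dim), dtype),
            "b": np.zeros(self.out_dim, dtype=dtype),
        }

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


try:  # the recurrence dominates training time; jit it when available
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # no-op decorator fallback
        def wrap(fn):
            return fn

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


_POW2 = np.array([2.0**n for n in range(-60, 61)])


@njit(inline="always", fastmath=True)
def _fexp(x):
    """Fast exp: 2**n * exp(r) with |r| <= ln(2)/2 and a degree-6 Taylor
    polynomial (relative error ~1e-7); the 2**n factor is a table lookup so
    the surrounding loops stay SIMD-friendly."""
    x = min(max(x, -30.0), 30.0)
    y = x * 1.4426950408889634
    n = np.floor(y + 0.5)
    t = (y - n) * 0.6931471805599453
    p = 1.0 + t * (
        1.0
        + t * (0.5 + t * (1.0 / 6.0 + t * (1.0 / 24.0 + t * (1.0 / 120.0 + t / 720.0))))
    )
    return p * _POW2[np.int64(n) + 60]


@njit(inline="always", fastmath=True)
def _fsigmoid(x):
    return 1.0 / (1.0 + _fexp(-x))


@njit(inline="always", fastmath=True)
def _ftanh(x):
    return 2.0 / (1.0 + _fexp(-2.0 * x)) - 1.0


@njit(cache=True)
def _lstm_fwd_kernel_exact(xw, U, b, mask):
    """Reference forward recurrence with exact libm activations; used for
    float64 inputs (gradient verification) where the fast-exp seams would
    show up in finite differences."""
    B, T, four_u = xw.shape
    u = four_u // 4
    h = np.zeros((B, u), dtype=xw.dtype)
    c = np.zeros((B, u), dtype=xw.dtype)
    H = np.empty((B, T, u), dtype=xw.dtype)
    I = np.empty((B, T, u), dtype=xw.dtype)
    F = np.empty((B, T, u), dtype=xw.dtype)
    G = np.empty((B, T, u), dtype=xw.dtype)
    O = np.empty((B, T, u), dtype=xw.dtype)
    TC = np.empty((B, T, u), dtype=xw.dtype)
    C = np.empty((B, T, u), dtype=xw.dtype)
    for t in range(T):
        z = xw[:, t] + np.dot(h, U)
        for bi in range(B):
            m = mask[bi, t]
            for j in range(u):
                ig = 1.0 / (1.0 + np.exp(-(z[bi, j] + b[j])))
                fg = 1.0 / (1.0 + np.exp(-(z[bi, u + j] + b[u + j])))
                gg = np.tanh(z[bi, 2 * u + j] + b[2 * u + j])
                og = 1.0 / (1.0 + np.exp(-(z[bi, 3 * u + j] + b[3 * u + j])))
                cn = fg * c[bi, j] + ig * gg
                tc = np.tanh(cn)
                hn = og * tc
                I[bi, t, j] = ig
                F[bi, t, j] = fg
                G[bi, t, j] = gg
                O[bi, t, j] = og
                TC[bi, t, j] = tc
                cv = m * cn + (1.0 - m) * c[bi, j]
                hv = m * hn + (1.0 - m) * h[bi, j]
                C[bi, t, j] = cv
                H[bi, t, j] = hv
                c[bi, j] = cv
                h[bi, j] = hv
    return H, I, F, G, O, TC, C


@njit(cache=True, fastmath=True)
def _lstm_fwd_kernel(xw, U, b, mask):
    B, T, four_u = xw.shape
    u = four_u // 4
    h = np.zeros((B, u), dtype=xw.dtype)
    c = np.zeros((B, u), dtype=xw.dtype)
    H = np.empty((B, T, u), dtype=xw.dtype)
    I = np.empty((B, T, u), dtype=xw.dtype)
    F = np.empty((B, T, u), dtype=xw.dtype)
    G = np.empty((B, T, u), dtype=xw.dtype)
    O = np.empty((B, T, u), dtype=xw.dtype)
    TC = np.empty((B, T, u), dtype=xw.dtype)
    C = np.empty((B, T, u), dtype=xw.dtype)
    for t in range(T):
        z = xw[:, t] + np.dot(h, U)
        for bi in range(B):
            m = mask[bi, t]
            for j in range(u):
                zi = z[bi, j] + b[j]
                zf = z[bi, u + j] + b[u + j]
                zg = z[bi, 2 * u + j] + b[2 * u + j]
                zo = z[bi, 3 * u + j] + b[3 * u + j]
                ig = _fsigmoid(zi)
                fg = _fsigmoid(zf)
                gg = _ftanh(zg)
                og = _fsigmoid(zo)
                cn = fg * c[bi, j] + ig * gg
                tc = _ftanh(cn)
                hn = og * tc
                I[bi, t, j] = ig
                F[bi, t, j] = fg
                G[bi, t, j] = gg
                O[bi, t, j] = og
                TC[bi, t, j] = tc
                cv = m * cn + (1.0 - m) * c[bi, j]
                hv = m * hn + (1.0 - m) * h[bi, j]
                C[bi, t, j] = cv
                H[bi, t, j] = hv
                c[bi, j] = cv
                h[bi, j] = hv
    return H, I, F, G, O, TC, C


@njit(cache=True, fastmath=True)
def _lstm_bwd_kernel(dH, I, F, G, O, TC, C, UT, mask):
    B, T, u = dH.shape
    dxw = np.zeros((B, T, 4 * u), dtype=dH.dtype)
    dh_next = np.zeros((B, u), dtype=dH.dtype)
    dc_next = np.zeros((B, u), dtype=dH.dtype)
    dz = np.empty((B, 4 * u), dtype=dH.dtype)
    for t in range(T - 1, -1, -1):
        for bi in range(B):
            m = mask[bi, t]
            for j in range(u):
                dh = dH[bi, t, j] + dh_next[bi, j]
                dc = dc_next[bi, j]
                dh_pass = dh * (1.0 - m)
                dc_pass = dc * (1.0 - m)
                dh = dh * m
                dc = dc * m
                ig = I[bi, t, j]
                fg = F[bi, t, j]
                gg = G[bi, t, j]
                og = O[bi, t, j]
                tc = TC[bi, t, j]
                c_prev = C[bi, t - 1, j] if t > 0 else 0.0
                do = dh * tc
                dc = dc + dh * og * (1.0 - tc * tc)
                di = dc * gg
                df = dc * c_prev
                dg = dc * ig
                dc_next[bi, j] = dc * fg + dc_pass
                dz[bi, j] = di * ig * (1.0 - ig)
                dz[bi, u + j] = df * fg * (1.0 - fg)
                dz[bi, 2 * u + j] = dg * (1.0 - gg * gg)
                dz[bi, 3 * u + j] = do * og * (1.0 - og)
                dh_next[bi, j] = dh_pass
        dh_rec = np.dot(dz, UT)
        for bi in range(B):
            for j in range(u):
                dh_next[bi, j] += dh_rec[bi, j]
            for j in range(4 * u):
                dxw[bi, t, j] = dz[bi, j]
    return dxw


class _LSTMDirection:
    """One direction of an LSTM over (B, T, D) input, returning all steps."""

    def __init__(self, in_dim: int, units: int):
        self.in_dim, self.units = in_dim, units

    def build(
        self, rng: np.random.Generator, dtype=DEFAULT_DTYPE
    ) -> dict[str, np.ndarray]:
        u = self.units
        params = {
            "W": _glorot(rng, (self.in_dim, 4 * u), dtype),
            "U": _orthogonal(rng, u, 4 * u, dtype),
            "b": np.zeros(4 * u, dtype=dtype),
        }
        params["b"][u : 2 * u] = 1.0  # forget-gate bias
        return params

    def forward(
        self,
        x: np.ndarray,
        params: dict[str, np.ndarray],
        mask: np.ndarray | None = None,
    ) -> np.ndarray:
        """Run the recurrence; where ``mask`` is 0 the state passes through.

        Pass-through masking makes pad positions contribute nothing: the
        carried state is not decayed by runs of padding, so the end state
        summarises exactly the real sequence.
        """
        b, t, _ = x.shape
        xw = np.ascontiguousarray(x @ params["W"])
        if mask is None:
            mask_arr = np.ones((b, t), dtype=x.dtype)
        else:
            mask_arr = np.ascontiguousarray(mask, dtype=x.dtype)
        kernel = (
            _lstm_fwd_kernel_exact
            if xw.dtype == np.float64
            else _lstm_fwd_kernel
        )
        H, I, F, G, O, TC, C = kernel(xw, params["U"], params["b"], mask_arr)
        self._cache = (I, F, G, O, TC, C, H, mask_arr)
        self._x = x
        return H

    def backward(
        self, dh_all: np.ndarray, params: dict[str, np.ndarray]
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        I, F, G, O, TC, C, H, mask_arr = self._cache
        dh_all = np.ascontiguousarray(dh_all, dtype=self._x.dtype)
        dxw = _lstm_bwd_kernel(
            dh_all, I, F, G, O, TC, C,
            np.ascontiguousarray(params["U"].T), mask_arr,
        )
        b, t, d = self._x.shape
        flat_x = self._x.reshape(b * t, d)
        flat_dxw = dxw.reshape(b * t, -1)
        # recurrent grad via one BLAS call: sum_t h_{t-1}^T dz_t
        h_prev = H[:, :-1].reshape(-1, H.shape[2])
        dz_next = dxw[:, 1:].reshape(-1, dxw.shape[2])
        grads = {
            "W": flat_x.T @ flat_dxw,
            "U": h_prev.T @ dz_next,
            "b": flat_dxw.sum(axis=0),
        }
        dx = (flat_dxw @ params["W"].T).reshape(b, t, d)
        return dx, grads


class BiLSTM(Layer):
    """Bidirectional LSTM returning the full sequence of concatenated states.

    Output shape (B, T, 2*units): forward states in the first half of the
    channel axis, reverse-direction states (re-reversed to input order) in
    the second half.
    """

    def __init__(self, in_dim: int, units: int, return_sequences: bool = True):
        super().__init__()
        if units < 1:
            raise ValueError("LSTM units must be positive")
        self.units = units
        self.return_sequences = return_sequences
        self._fwd = _LSTMDirection(in_dim, units)
        self._bwd = _LSTMDirection(in_dim, units)

    def build(self, rng, dtype=DEFAULT_DTYPE):
        fwd = self._fwd.build(rng, dtype)
        bwd = self._bwd.build(rng, dtype)
        self.params = {f"f_{k}": v for k, v in fwd.items()}
        self.params.update({f"b_{k}": v for k, v in bwd.items()})

    def _split(self, prefix: str) -> dict[str, np.ndarray]:
        return {k[2:]: v for k, v in self.params.items() if k.startswith(prefix)}

    def forward(self, x, train, rng, mask=None):
        out_f = self._fwd.forward(x, self._split("f_"), mask=mask)
        rmask = None if mask is None else mask[:, ::-1]
        out_br = self._bwd.forward(x[:, ::-1], self._split("b_"), mask=rmask)
        if self.return_sequences:
            return np.concatenate([out_f, out_br[:, ::-1]], axis=2)
        # final states only: forward's last step, reverse direction's last
        # step (input position 0); with masking these summarise the real
        # sequence regardless of padding
        self._t = x.shape[1]
        return np.concatenate([out_f[:, -1], out_br[:, -1]], axis=1)

    def backward(self, dout):
        u = self.units
        if self.return_sequences:
            dh_f = dout[:, :, :u]
            dh_br = dout[:, ::-1, u:]
        else:
            b = dout.shape[0]
            dh_f = np.zeros((b, self._t, u), dtype=dout.dtype)
            dh_f[:, -1] = dout[:, :u]
            dh_br = np.zeros((b, self._t, u), dtype=dout.dtype)
            dh_br[:, -1] = dout[:, u:]
        dx_f, grads_f = self._fwd.backward(dh_f, self._split("f_"))
        dx_b, grads_b = self._bwd.backward(dh_br, self._split("b_"))
        self.grads = {f"f_{k}": v for k, v in grads_f.items()}
        self.grads.update({f"b_{k}": v for k, v in grads_b.items()})
        return dx_f + dx_b[:, ::-1]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[dict[str, np.ndarray]], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]
        self.v = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]

    def step(
        self,
        params: list[dict[str, np.ndarray]],
        grads: list[dict[str, np.ndarray]],
    ) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            for k in p:
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g[k]
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g[k] ** 2
                p[k] -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)


class Sequential:
    """A stack of layers trained with softmax cross-entropy and Adam."""

    def __init__(self, layers: Sequence[Layer], seed: int = 0, dtype=None):
        self.layers = list(layers)
        self.rng = np.random.default_rng(seed)
        self.dtype = dtype if dtype is not None else DEFAULT_DTYPE
        for layer in self.layers:
            layer.build(self.rng, self.dtype)
        self.history: dict[str, list[float]] = {}

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # integer-coded input: positions coded 0 are pads, masked out of
        # every recurrent layer so padding carries no signal
        mask = (
            (x > 0).astype(self.dtype)
            if np.issubdtype(x.dtype, np.integer)
            else None
        )
        for layer in self.layers:
            if isinstance(layer, BiLSTM):
                x = layer.forward(x, train, self.rng, mask=mask)
            else:
                x = layer.forward(x, train, self.rng)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [
            _softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.vstack(outs)

    # -- training ----------------------------------------------------------
    def _loss_and_acc(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        proba = self.predict_proba(x)
        n = len(y)
        nll = -np.log(np.clip(proba[np.arange(n), y], 1e-12, None)).mean()
        acc = float((proba.argmax(axis=1) == y).mean())
        return float(nll), acc

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 64,
        lr: float = 1e-3,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
        early_stopping_patience: int | None = None,
        clip_norm: float | None = 5.0,
        lr_halve_at: Sequence[int] = (),
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Mini-batch Adam training; returns the per-epoch history.

        History keys: ``loss``, ``accuracy`` and, when validation data is
        given, ``val_loss`` and ``val_accuracy``; each list has one entry per
        epoch actually run (early stopping can end training before
        ``epochs``).  ``lr_halve_at`` lists epoch indices at which the
        learning rate is halved (a coarse step schedule that settles the
        final epochs).
        """
        y = np.asarray(y)
        params = [l.params for l in self.layers if l.params]
        opt = _Adam(params, lr)
        history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        if validation_data is not None:
            history["val_loss"] = []
            history["val_accuracy"] = []
        best_val = np.inf
        stall = 0
        n = len(x)
        for _epoch in range(epochs):
            if _epoch in lr_halve_at:
                opt.lr *= 0.5
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            epoch_correct = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                logits = self.forward(xb, train=True)
                proba = _softmax(logits)
                rows = np.arange(len(yb))
                epoch_loss -= np.log(np.clip(proba[rows, yb], 1e-12, None)).sum()
                epoch_correct += int((proba.argmax(axis=1) == yb).sum())
                dlogits = proba
                dlogits[rows, yb] -= 1.0
                dlogits /= len(yb)
                dout = dlogits
                for layer in reversed(self.layers):
                    dout = layer.backward(dout)
                grads = [l.grads for l in self.layers if l.params]
                if clip_norm is not None:
                    total = np.sqrt(
                        sum(
                            float((g**2).sum())
                            for gd in grads
                            for g in gd.values()
                        )
                    )
                    if total > clip_norm:
                        scale = clip_norm / total
                        for gd in grads:
                            for k in gd:
                                gd[k] = gd[k] * scale
                opt.step(params, grads)
            history["loss"].append(float(epoch_loss / n))
            history["accuracy"].append(epoch_correct / n)
            if validation_data is not None:
                vl, va = self._loss_and_acc(*validation_data)
                history["val_loss"].append(vl)
                history["val_accuracy"].append(va)
                if early_stopping_patience is not None:
                    if vl < best_val - 1e-5:
                        best_val = vl
                        stall = 0
                    else:
                        stall += 1
                        if stall >= early_stopping_patience:
                            break
            if verbose:  # pragma: no cover
                msg = f"epoch {_epoch + 1}: loss={history['loss'][-1]:.4f}"
                if validation_data is not None:
                    msg += f" val_loss={history['val_loss'][-1]:.4f}"
                print(msg)
        self.history = history
        return history

    # -- persistence -------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"layer{i}__{k}"] = v
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                key = f"layer{i}__{k}"
                if key not in weights:
                    raise ValueError(f"missing weight {key} (architecture mismatch)")
                if weights[key].shape != layer.params[k].shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{weights[key].shape} vs {layer.params[k].shape}"
                    )
                layer.params[k] = weights[key].copy()
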