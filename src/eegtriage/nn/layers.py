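"""Layer primitives for the numpy network engine.

Shapes exclude the batch axis (always first at run time) and follow a
channels-first convention: vectors ``(d,)``, sequences ``(C, T)``, images
``(C, H, W)``. Every layer knows its output shape and trainable-parameter
count as pure functions of the input shapes, so architectures can be audited
and counted without instantiation.

Convolutions and pools use 'same' padding throughout, and pools default to
stride 1 when none is stated — one uniform convention for every architecture
in the package. A 1-D convolution applied to an image-shaped input slides
along the last (time) axis only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Return (out_size, pad_left, pad_right) for 'same' padding."""
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


def _window_starts(out: int, stride: int) -> np.ndarray:
    return np.arange(out) * stride


class Layer:
    """Base class; subclasses are lightweight dataclasses."""

    def out_shape(self, in_shapes: list[tuple]) -> tuple:
        raise NotImplementedError

    def n_params(self, in_shapes: list[tuple]) -> int:
        return 0

    def init_params(self, in_shapes: list[tuple], rng: np.random.Generator) -> dict:
        return {}

    def forward(self, xs, params, training=False, rng=None):
        """Return (y, cache)."""
        raise NotImplementedError

    def backward(self, dy, cache, params):
        """Return (list of dx per input, dparams dict)."""
        raise NotImplementedError

    def config(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _single(in_shapes):
    if len(in_shapes) != 1:
        raise ValueError(f"{type(in_shapes)}: layer expects exactly one input")
    return in_shapes[0]


# ---------------------------------------------------------------------------
# dense / normalization / activations
# ---------------------------------------------------------------------------

@dataclass
class Dense(Layer):
    units: int

    def out_shape(self, in_shapes):
        _single(in_shapes)
        return (self.units,)

    def n_params(self, in_shapes):
        d = int(np.prod(_single(in_shapes)))
        return d * self.units + self.units

    def init_params(self, in_shapes, rng):
        d = int(np.prod(_single(in_shapes)))
        scale = np.sqrt(2.0 / d)
        return {
            "W": rng.standard_normal((d, self.units)) * scale,
            "b": np.zeros(self.units),
        }

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        flat = x.reshape(x.shape[0], -1)
        return flat @ params["W"] + params["b"], (flat, x.shape)

    def backward(self, dy, cache, params):
        flat, shape = cache
        dW = flat.T @ dy
        db = dy.sum(axis=0)
        dx = (dy @ params["W"].T).reshape(shape)
        return [dx], {"W": dW, "b": db}


@dataclass
class BatchNorm(Layer):
    """Batch normalization over the batch axis (vector inputs)."""

    momentum: float = 0.9
    eps: float = 1e-5

    def out_shape(self, in_shapes):
        return _single(in_shapes)

    def n_params(self, in_shapes):
        return 2 * int(np.prod(_single(in_shapes)))

    def init_params(self, in_shapes, rng):
        d = int(np.prod(_single(in_shapes)))
        return {
            "gamma": np.ones(d),
            "beta": np.zeros(d),
            # running stats are state, not trainable; kept alongside params
            "_running_mean": np.zeros(d),
            "_running_var": np.ones(d),
        }

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            params["_running_mean"] *= self.momentum
            params["_running_mean"] += (1 - self.momentum) * mean
            params["_running_var"] *= self.momentum
            params["_running_var"] += (1 - self.momentum) * var
        else:
            mean = params["_running_mean"]
            var = params["_running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        return params["gamma"] * xhat + params["beta"], (xhat, inv)

    def backward(self, dy, cache, params):
        xhat, inv = cache
        B = dy.shape[0]
        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dxhat = dy * params["gamma"]
        dx = inv / B * (
            B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return [dx], {"gamma": dgamma, "beta": dbeta}


@dataclass
class Dropout(Layer):
    p: float = 0.5

    def out_shape(self, in_shapes):
        return _single(in_shapes)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        if not training or self.p == 0:
            return x, None
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask, mask

    def backward(self, dy, cache, params):
        return [dy if cache is None else dy * cache], {}


@dataclass
class ReLU(Layer):
    def out_shape(self, in_shapes):
        return _single(in_shapes)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        return np.maximum(x, 0.0), x > 0

    def backward(self, dy, cache, params):
        return [dy * cache], {}


@dataclass
class LeakyReLU(Layer):
    slope: float = 0.01

    def out_shape(self, in_shapes):
        return _single(in_shapes)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        return np.where(x > 0, x, self.slope * x), x > 0

    def backward(self, dy, cache, params):
        return [np.where(cache, dy, self.slope * dy)], {}


@dataclass
class Softmax(Layer):
    def out_shape(self, in_shapes):
        return _single(in_shapes)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        return p, p

    def backward(self, dy, cache, params):
        p = cache
        dx = p * (dy - (dy * p).sum(axis=-1, keepdims=True))
        return [dx], {}


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _conv_windows_1d(x, kernel, stride):
    """x (B, C, T) -> padded windows (B, C, out, kernel) and padded length."""
    T = x.shape[-1]
    out, pl, pr = _same_pad(T, kernel, stride)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pl, pr)])
    win = sliding_window_view(xp, kernel, axis=-1)[..., ::stride, :][..., :out, :]
    return win, xp.shape[-1], out, pl


def _scatter_1d(contrib, T_pad, stride, kernel, out):
    """contrib (..., out, kernel) -> gradient on padded axis (..., T_pad)."""
    lead = contrib.shape[:-2]
    g = np.zeros((T_pad,) + lead)
    idx = _window_starts(out, stride)[:, None] + np.arange(kernel)[None, :]
    moved = np.moveaxis(contrib, (-2, -1), (0, 1))  # (out, kernel, ...)
    np.add.at(g, idx, moved)
    return np.moveaxis(g, 0, -1)


@dataclass
class Conv1D(Layer):
    """Convolution along the last (time) axis; extra spatial axes ride along."""

    filters: int
    kernel: int
    stride: int = 1

    def _in_ch(self, shape):
        return shape[0]

    def out_shape(self, in_shapes):
        shape = _single(in_shapes)
        out, _, _ = _same_pad(shape[-1], self.kernel, self.stride)
        return (self.filters,) + tuple(shape[1:-1]) + (out,)

    def n_params(self, in_shapes):
        c = self._in_ch(_single(in_shapes))
        return c * self.kernel * self.filters + self.filters

    def init_params(self, in_shapes, rng):
        c = self._in_ch(_single(in_shapes))
        scale = np.sqrt(2.0 / (c * self.kernel))
        return {
            "W": rng.standard_normal((self.filters, c, self.kernel)) * scale,
            "b": np.zeros(self.filters),
        }

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]  # (B, C, T) or (B, C, H, T)
        win, T_pad, out, pl = _conv_windows_1d(x, self.kernel, self.stride)
        if x.ndim == 3:
            y = np.einsum("bcok,fck->bfo", win, params["W"]) + params["b"][:, None]
        else:
            y = (
                np.einsum("bchok,fck->bfho", win, params["W"])
                + params["b"][:, None, None]
            )
        return y, (win, x.shape, T_pad, out, pl)

    def backward(self, dy, cache, params):
        win, x_shape, T_pad, out, pl = cache
        W = params["W"]
        if len(x_shape) == 3:
            dW = np.einsum("bcok,bfo->fck", win, dy)
            db = dy.sum(axis=(0, 2))
            contrib = np.einsum("bfo,fck->bcok", dy, W)
        else:
            dW = np.einsum("bchok,bfho->fck", win, dy)
            db = dy.sum(axis=(0, 2, 3))
            contrib = np.einsum("bfho,fck->bchok", dy, W)
        gpad = _scatter_1d(contrib, T_pad, self.stride, self.kernel, out)
        dx = gpad[..., pl : pl + x_shape[-1]]
        return [dx], {"W": dW, "b": db}


def _conv_windows_2d(x, kh, kw, sh, sw):
    B, C, H, W = x.shape
    oh, pt, pb = _same_pad(H, kh, sh)
    ow, plft, prgt = _same_pad(W, kw, sw)
    xp = np.pad(x, [(0, 0), (0, 0), (pt, pb), (plft, prgt)])
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw][:, :, :oh, :ow]
    return win, xp.shape[2], xp.shape[3], oh, ow, pt, plft


def _scatter_2d(contrib, Hp, Wp, sh, sw, kh, kw, oh, ow):
    """contrib (B, C, oh, ow, kh, kw) -> (B, C, Hp, Wp)."""
    B, C = contrib.shape[:2]
    g = np.zeros((Hp * Wp, B, C))
    rows = _window_starts(oh, sh)[:, None] + np.arange(kh)[None, :]  # (oh, kh)
    cols = _window_starts(ow, sw)[:, None] + np.arange(kw)[None, :]  # (ow, kw)
    flat = (
        rows[:, None, :, None] * Wp + cols[None, :, None, :]
    )  # (oh, ow, kh, kw)
    moved = np.moveaxis(contrib, (0, 1), (-2, -1))  # (oh, ow, kh, kw, B, C)
    np.add.at(g, flat, moved)
    return np.moveaxis(g, 0, -1).reshape(B, C, Hp, Wp)


@dataclass
class Conv2D(Layer):
    filters: int
    kernel: tuple[int, int]
    stride: tuple[int, int] = (1, 1)

    def __post_init__(self):
        self.kernel = tuple(self.kernel)
        self.stride = tuple(self.stride)

    def out_shape(self, in_shapes):
        c, h, w = _single(in_shapes)
        oh, _, _ = _same_pad(h, self.kernel[0], self.stride[0])
        ow, _, _ = _same_pad(w, self.kernel[1], self.stride[1])
        return (self.filters, oh, ow)

    def n_params(self, in_shapes):
        c = _single(in_shapes)[0]
        return c * self.kernel[0] * self.kernel[1] * self.filters + self.filters

    def init_params(self, in_shapes, rng):
        c = _single(in_shapes)[0]
        fan_in = c * self.kernel[0] * self.kernel[1]
        scale = np.sqrt(2.0 / fan_in)
        return {
            "W": rng.standard_normal((self.filters, c) + self.kernel) * scale,
            "b": np.zeros(self.filters),
        }

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        win, Hp, Wp, oh, ow, pt, pl = _conv_windows_2d(
            x, *self.kernel, *self.stride
        )
        y = (
            np.einsum("bchwij,fcij->bfhw", win, params["W"])
            + params["b"][:, None, None]
        )
        return y, (win, x.shape, Hp, Wp, oh, ow, pt, pl)

    def backward(self, dy, cache, params):
        win, x_shape, Hp, Wp, oh, ow, pt, pl = cache
        dW = np.einsum("bchwij,bfhw->fcij", win, dy)
        db = dy.sum(axis=(0, 2, 3))
        contrib = np.einsum("bfhw,fcij->bchwij", dy, params["W"])
        gpad = _scatter_2d(
            contrib, Hp, Wp, self.stride[0], self.stride[1],
            self.kernel[0], self.kernel[1], oh, ow,
        )
        dx = gpad[:, :, pt : pt + x_shape[2], pl : pl + x_shape[3]]
        return [dx], {"W": dW, "b": db}


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

@dataclass
class MaxPool1D(Layer):
    pool: int
    stride: int = 1  # MATLAB-style default when no stride is stated

    def out_shape(self, in_shapes):
        shape = _single(in_shapes)
        out, _, _ = _same_pad(shape[-1], self.pool, self.stride)
        return tuple(shape[:-1]) + (out,)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        T = x.shape[-1]
        out, plft, pr = _same_pad(T, self.pool, self.stride)
        xp = np.pad(
            x, [(0, 0)] * (x.ndim - 1) + [(plft, pr)], constant_values=-np.inf
        )
        win = sliding_window_view(xp, self.pool, axis=-1)[..., ::self.stride, :]
        win = win[..., :out, :]
        arg = win.argmax(axis=-1)
        y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        return y, (arg, x.shape, xp.shape[-1], out, plft)

    def backward(self, dy, cache, params):
        arg, x_shape, T_pad, out, plft = cache
        contrib = np.zeros(dy.shape + (self.pool,))
        np.put_along_axis(contrib, arg[..., None], dy[..., None], axis=-1)
        gpad = _scatter_1d(contrib, T_pad, self.stride, self.pool, out)
        return [gpad[..., plft : plft + x_shape[-1]]], {}


@dataclass
class AvgPool1D(Layer):
    """Average pool; zero padding counts toward the denominator."""

    pool: int
    stride: int = 1

    def out_shape(self, in_shapes):
        shape = _single(in_shapes)
        out, _, _ = _same_pad(shape[-1], self.pool, self.stride)
        return tuple(shape[:-1]) + (out,)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        win, T_pad, out, plft = _conv_windows_1d(x, self.pool, self.stride)
        return win.mean(axis=-1), (x.shape, T_pad, out, plft)

    def backward(self, dy, cache, params):
        x_shape, T_pad, out, plft = cache
        contrib = np.repeat(dy[..., None] / self.pool, self.pool, axis=-1)
        gpad = _scatter_1d(contrib, T_pad, self.stride, self.pool, out)
        return [gpad[..., plft : plft + x_shape[-1]]], {}


@dataclass
class MaxPool2D(Layer):
    pool: tuple[int, int]
    stride: tuple[int, int] = (1, 1)

    def __post_init__(self):
        self.pool = tuple(self.pool)
        self.stride = tuple(self.stride)

    def out_shape(self, in_shapes):
        c, h, w = _single(in_shapes)
        oh, _, _ = _same_pad(h, self.pool[0], self.stride[0])
        ow, _, _ = _same_pad(w, self.pool[1], self.stride[1])
        return (c, oh, ow)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        B, C, H, W = x.shape
        oh, pt, pb = _same_pad(H, self.pool[0], self.stride[0])
        ow, plft, prgt = _same_pad(W, self.pool[1], self.stride[1])
        xp = np.pad(
            x, [(0, 0), (0, 0), (pt, pb), (plft, prgt)], constant_values=-np.inf
        )
        win = sliding_window_view(xp, self.pool, axis=(2, 3))
        win = win[:, :, ::self.stride[0], ::self.stride[1]][:, :, :oh, :ow]
        flat = win.reshape(win.shape[:4] + (-1,))
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        return y, (arg, x.shape, xp.shape[2], xp.shape[3], oh, ow, pt, plft)

    def backward(self, dy, cache, params):
        arg, x_shape, Hp, Wp, oh, ow, pt, plft = cache
        kh, kw = self.pool
        contrib_flat = np.zeros(dy.shape + (kh * kw,))
        np.put_along_axis(contrib_flat, arg[..., None], dy[..., None], axis=-1)
        contrib = contrib_flat.reshape(dy.shape + (kh, kw))
        gpad = _scatter_2d(
            contrib, Hp, Wp, self.stride[0], self.stride[1], kh, kw, oh, ow
        )
        return [gpad[:, :, pt : pt + x_shape[2], plft : plft + x_shape[3]]], {}


@dataclass
class GlobalAvgPool(Layer):
    """Average over every non-channel axis: (C, ...) -> (C,)."""

    def out_shape(self, in_shapes):
        return (_single(in_shapes)[0],)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        axes = tuple(range(2, x.ndim))
        return x.mean(axis=axes), x.shape

    def backward(self, dy, cache, params):
        shape = cache
        n = int(np.prod(shape[2:]))
        dx = np.broadcast_to(
            dy.reshape(dy.shape + (1,) * (len(shape) - 2)), shape
        ) / n
        return [np.ascontiguousarray(dx)], {}


# ---------------------------------------------------------------------------
# structural layers
# ---------------------------------------------------------------------------

@dataclass
class Flatten(Layer):
    """Collapse all axes except the last into the channel axis:
    (C, H, T) -> (C*H, T); a sequence passes through unchanged."""

    def out_shape(self, in_shapes):
        shape = _single(in_shapes)
        if len(shape) <= 2:
            return shape
        return (int(np.prod(shape[:-1])), shape[-1])

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]
        y = x.reshape(x.shape[0], -1, x.shape[-1]) if x.ndim > 3 else x
        return y, x.shape

    def backward(self, dy, cache, params):
        return [dy.reshape(cache)], {}


@dataclass
class Concat(Layer):
    """Concatenate along the channel axis; trailing axes must agree."""

    def out_shape(self, in_shapes):
        tails = {tuple(s[1:]) for s in in_shapes}
        if len(tails) != 1:
            raise ValueError(f"concat inputs disagree beyond channels: {in_shapes}")
        return (sum(s[0] for s in in_shapes),) + in_shapes[0][1:]

    def forward(self, xs, params, training=False, rng=None):
        return np.concatenate(xs, axis=1), [x.shape[1] for x in xs]

    def backward(self, dy, cache, params):
        splits = np.cumsum(cache)[:-1]
        return list(np.split(dy, splits, axis=1)), {}


@dataclass
class Subtract(Layer):
    """Elementwise difference of two inputs (bipolar montage pairing)."""

    def out_shape(self, in_shapes):
        if len(in_shapes) != 2 or in_shapes[0] != in_shapes[1]:
            raise ValueError(f"subtract requires two identical shapes: {in_shapes}")
        return in_shapes[0]

    def forward(self, xs, params, training=False, rng=None):
        return xs[0] - xs[1], None

    def backward(self, dy, cache, params):
        return [dy, -dy], {}


@dataclass
class ChannelSelect(Layer):
    """Select a subset of channels (routing for the sensor-fusion paths)."""

    indices: tuple[int, ...]

    def __post_init__(self):
        self.indices = tuple(int(i) for i in self.indices)

    def out_shape(self, in_shapes):
        shape = _single(in_shapes)
        if max(self.indices) >= shape[0]:
            raise ValueError("channel index out of range")
        return (len(self.indices),) + tuple(shape[1:])

    def forward(self, xs, params, training=False, rng=None):
        return xs[0][:, list(self.indices)], xs[0].shape

    def backward(self, dy, cache, params):
        dx = np.zeros(cache)
        dx[:, list(self.indices)] = dy
        return [dx], {}


@dataclass
class STFTLayer(Layer):
    """One-sided short-time Fourier transform of each channel.

    (C, T) -> (2C, nbins, frames): real parts of all channels, then imaginary
    parts, stacked along the channel axis. Periodic Hann analysis window;
    'valid' framing (frames = floor((T - window)/hop) + 1).
    """

    window: int = 128
    hop: int = 32
    nfft: int = 256

    def out_shape(self, in_shapes):
        c, t = _single(in_shapes)
        if t < self.window:
            raise ValueError("input shorter than the analysis window")
        frames = (t - self.window) // self.hop + 1
        return (2 * c, self.nfft // 2 + 1, frames)

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]  # (B, C, T)
        win = sliding_window_view(x, self.window, axis=-1)[:, :, :: self.hop]
        frames = (x.shape[-1] - self.window) // self.hop + 1
        win = win[:, :, :frames]
        taper = hann(self.window, sym=False)
        spec = np.fft.rfft(win * taper, n=self.nfft, axis=-1)
        spec = np.swapaxes(spec, -1, -2)  # (B, C, nbins, frames)
        y = np.concatenate([spec.real, spec.imag], axis=1)
        return y, None

    def backward(self, dy, cache, params):
        raise NotImplementedError(
            "the STFT stage is a fixed transform; place trainable layers "
            "downstream of it"
        )


LAYER_TYPES: dict[str, type] = {
    cls.__name__: cls
    for cls in (
        Dense, BatchNorm, Dropout, ReLU, LeakyReLU, Softmax,
        Conv1D, Conv2D, MaxPool1D, AvgPool1D, MaxPool2D,
        GlobalAvgPool, Flatten, Concat, Subtract, ChannelSelect, STFTLayer,
    )
}
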