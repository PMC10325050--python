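"""LSTM layer (last-output mode) with full backpropagation through time."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import LAYER_TYPES, Layer, _single


@dataclass
class LSTM(Layer):
    """(C, T) sequence -> (units,) final hidden state.

    Gate order i, f, g, o; sigmoid gates, tanh cell candidate; forget-gate
    bias initialized to 1 (standard stabilization).
    """

    units: int

    def out_shape(self, in_shapes):
        c, t = _single(in_shapes)
        return (self.units,)

    def n_params(self, in_shapes):
        c, _ = _single(in_shapes)
        h = self.units
        return 4 * (c * h + h * h + h)

    def init_params(self, in_shapes, rng):
        c, _ = _single(in_shapes)
        h = self.units
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget gate
        return {
            "Wx": rng.standard_normal((c, 4 * h)) / np.sqrt(c),
            "Wh": rng.standard_normal((h, 4 * h)) / np.sqrt(h),
            "b": b,
        }

    def forward(self, xs, params, training=False, rng=None):
        x = xs[0]  # (B, C, T)
        B, C, T = x.shape
        H = self.units
        Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            xt = x[:, :, t]
            z = xt @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            steps.append((xt, h_prev, c_prev, i, f, g, o, tc))
        return h, (steps, x.shape)

    def backward(self, dy, cache, params):
        steps, x_shape = cache
        B, C, T = x_shape
        H = self.units
        Wx, Wh = params["Wx"], params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.zeros(x_shape)
        dh = dy
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += xt.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, :, t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        return [dx], {"Wx": dWx, "Wh": dWh, "b": db}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


LAYER_TYPES["LSTM"] = LSTM
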