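"""Grad-CAM temporal attribution for convolutional classifiers.

For a chosen class, the gradient of the (pre-softmax) class score with
respect to the last convolutional feature map is averaged into per-filter
weights; the weighted, rectified combination of the feature map is collapsed
onto the time axis, upsampled to the input sampling grid and smoothed with a
centred 1-second moving average. The result is a nonnegative importance
trace aligned sample-for-sample with the input segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.network import Model


@dataclass
class AttributionTrace:
    importance: np.ndarray  # one value per input time sample, >= 0
    target_class: int
    smooth_s: float
    fs: float

    def normalized(self) -> np.ndarray:
        m = self.importance.max()
        return self.importance / m if m > 0 else self.importance


def grad_cam_temporal(
    model: Model,
    x: np.ndarray,
    target_class: int,
    fs: float = 100.0,
    smooth_s: float = 1.0,
    target_node: str | None = None,
) -> AttributionTrace:
    """Temporal Grad-CAM for one input (shape = network input shape).

    ``target_node`` defaults to the topologically last convolutional layer;
    a model without convolutions is rejected.
    """
    node = target_node or model.last_conv_node()
    if node is None:
        raise ValueError(
            "Grad-CAM requires a convolutional layer; this architecture has none"
        )
    x = np.asarray(x, dtype=float)[None]  # add batch axis
    n_time = x.shape[-1]
    out, acts = model.forward(x, training=False, keep_caches=True)
    n_classes = out.shape[-1]
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class must lie in [0, {n_classes})")
    logits_node = model.softmax_input()
    seed = np.zeros_like(acts[logits_node])
    seed[0, target_class] = 1.0
    _, dacts = model.backward(acts, logits_node, seed)
    if node not in dacts:
        raise ValueError(
            f"no gradient reaches node {node!r}; choose a layer on the "
            "path to the output"
        )
    fmap = acts[node][0]      # (F, ..., T')
    grad = dacts[node][0]
    # global-average the gradient into one weight per filter
    axes = tuple(range(1, grad.ndim))
    weights = grad.mean(axis=axes)
    cam = np.tensordot(weights, fmap, axes=([0], [0]))  # (..., T')
    cam = np.maximum(cam, 0.0)
    while cam.ndim > 1:  # collapse residual non-time axes
        cam = cam.mean(axis=0)
    # upsample to the input time axis
    if cam.size == 1:
        trace = np.full(n_time, float(cam))
    else:
        src = np.linspace(0.0, n_time - 1, cam.size)
        trace = np.interp(np.arange(n_time), src, cam)
    trace = moving_average(trace, max(int(round(smooth_s * fs)), 1))
    return AttributionTrace(
        importance=trace, target_class=target_class, smooth_s=smooth_s, fs=fs
    )


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges (preserves
    length and nonnegativity; conserves the mean up to edge handling)."""
    if width <= 1:
        return x
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
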