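"""The five classifier architectures, declared as NetworkSpecs.

* Feature Network — fully connected stack over a (selected) feature vector.
* Topographic Map Network (TMN) — 2-D CNN over six 134x134 band-power maps.
* STFT Network — spectro-temporal CNN over the one-sided STFT of all
  19 channels (128-pt window, hop 32, 256-pt FFT: 129 bins x 559 frames,
  real+imaginary stacked into 38 channels).
* LSTM Network — temporal convolutions feeding a 256-unit LSTM.
* Sensor Fusion Network (SFN) — 20 parallel paths (one per channel plus the
  full signal), each an STFT subpath and a raw time-series subpath, with
  path outputs differenced along the bipolar longitudinal montage.

Featureless networks take 3-minute segments downsampled to 100 Hz
(19 x 18000 samples). Convolutions/pools use the package-wide 'same'
padding convention; pools default to stride 1 where none is stated.
"""

from __future__ import annotations

import numpy as np

from ..channels import CANONICAL_19, DOUBLE_BANANA, SCALP_POSITIONS
from .layers import (
    AvgPool1D, BatchNorm, ChannelSelect, Concat, Conv1D, Conv2D, Dense,
    Dropout, Flatten, GlobalAvgPool, LeakyReLU, MaxPool1D, MaxPool2D, ReLU,
    Softmax, STFTLayer, Subtract,
)
from .network import NetworkSpec

SEGMENT_SAMPLES_100HZ = 18000  # 180 s at 100 Hz
STFT_WINDOW, STFT_HOP, STFT_NFFT = 128, 32, 256
TOPOMAP_SIZE = 134


def build_feature_network(input_dim: int) -> NetworkSpec:
    """Dropout -> FC(500) -> BN -> LeakyReLU(0.01) -> Dropout -> FC(100)
    -> BN -> ReLU -> FC(3) -> softmax."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    spec = NetworkSpec(input_shape=(input_dim,))
    spec.add("drop1", Dropout(0.5))
    spec.add("fc500", Dense(500))
    spec.add("bn1", BatchNorm())
    spec.add("lrelu", LeakyReLU(0.01))
    spec.add("drop2", Dropout(0.5))
    spec.add("fc100", Dense(100))
    spec.add("bn2", BatchNorm())
    spec.add("relu", ReLU())
    spec.add("fc3", Dense(3))
    spec.add("softmax", Softmax())
    return spec


def build_tmn() -> NetworkSpec:
    """2-D CNN over the 134x134x6 topographic band-power tensor."""
    spec = NetworkSpec(input_shape=(6, TOPOMAP_SIZE, TOPOMAP_SIZE))
    spec.add("conv1", Conv2D(64, (1, 1)))
    spec.add("relu1", ReLU())
    spec.add("pool1", MaxPool2D((3, 3), (2, 2)))
    spec.add("conv2", Conv2D(64, (1, 1)))
    spec.add("drop1", Dropout(0.5))
    spec.add("relu2", ReLU())
    spec.add("pool2", MaxPool2D((5, 5), (2, 2)))
    spec.add("conv3", Conv2D(128, (3, 3)))
    spec.add("relu3", ReLU())
    spec.add("pool3", MaxPool2D((5, 5), (2, 2)))
    spec.add("fc100", Dense(100))
    spec.add("drop2", Dropout(0.5))
    spec.add("fc3", Dense(3))
    spec.add("softmax", Softmax())
    return spec


def build_stft_network() -> NetworkSpec:
    """Parallel 1-D / 2-D / flattened convolution branches over the STFT.

    The STFT stage emits 38 channels (19 x real+imag) of 129 bins x 559
    frames; the 1-D(32, k=1) and 2-D(32, 1x1) branches are concatenated and
    flattened (64 x 129 = 8256 channels), the flattened-STFT branch adds 64,
    giving the 8320-channel sequence that feeds ReLU -> global average pool
    -> FC(100) -> ReLU -> FC(3) -> softmax.
    """
    spec = NetworkSpec(input_shape=(19, SEGMENT_SAMPLES_100HZ))
    spec.add("stft", STFTLayer(STFT_WINDOW, STFT_HOP, STFT_NFFT))
    spec.add("conv1d_a", Conv1D(32, 1), "stft")
    spec.add("conv2d_b", Conv2D(32, (1, 1)), "stft")
    spec.add("cat_ab", Concat(), ["conv1d_a", "conv2d_b"])
    spec.add("flat_ab", Flatten(), "cat_ab")
    spec.add("flat_stft", Flatten(), "stft")
    spec.add("conv1d_c", Conv1D(64, 1), "flat_stft")
    spec.add("cat_all", Concat(), ["flat_ab", "conv1d_c"])
    spec.add("relu1", ReLU())
    spec.add("gap", GlobalAvgPool())
    spec.add("fc100", Dense(100))
    spec.add("relu2", ReLU())
    spec.add("fc3", Dense(3))
    spec.add("softmax", Softmax())
    return spec


def build_lstm_network() -> NetworkSpec:
    """Three (conv1d, avgpool) blocks feeding an LSTM(256) classifier."""
    from .layers_lstm import LSTM

    spec = NetworkSpec(input_shape=(19, SEGMENT_SAMPLES_100HZ))
    spec.add("conv1", Conv1D(32, 3))
    spec.add("pool1", AvgPool1D(20, 2))
    spec.add("conv2", Conv1D(64, 3))
    spec.add("pool2", AvgPool1D(20, 2))
    spec.add("conv3", Conv1D(64, 3))
    spec.add("pool3", AvgPool1D(20, 2))
    spec.add("lstm", LSTM(256))
    spec.add("drop", Dropout(0.5))
    spec.add("fc3", Dense(3))
    spec.add("softmax", Softmax())
    return spec


def build_sfn(
    montage_pairs: tuple[tuple[str, str], ...] = DOUBLE_BANANA,
) -> NetworkSpec:
    """Sensor Fusion Network: 20 parallel per-channel/full-signal paths.

    Each path runs an STFT subpath (two strided 3x3 convs, max pool, flatten,
    global pool, FC(128)) and a time subpath (three strided k=10 convs with
    max pools and a global pool), concatenated to a 256-vector. Channel-path
    outputs are differenced along ``montage_pairs`` (default: the 18 bipolar
    longitudinal pairs) and concatenated with the full-signal path before
    FC(3) -> softmax.
    """
    name_to_idx = {ch: i for i, ch in enumerate(CANONICAL_19)}
    for a, b in montage_pairs:
        if a not in name_to_idx or b not in name_to_idx:
            raise ValueError(f"montage pair ({a}, {b}) references unknown channel")

    spec = NetworkSpec(input_shape=(19, SEGMENT_SAMPLES_100HZ))

    def add_path(tag: str, select: ChannelSelect | None) -> str:
        src = "input"
        if select is not None:
            src = spec.add(f"{tag}.sel", select, "input")
        # STFT subpath
        s = spec.add(f"{tag}.stft", STFTLayer(STFT_WINDOW, STFT_HOP, STFT_NFFT), src)
        s = spec.add(f"{tag}.s_conv1", Conv2D(32, (3, 3), (2, 2)), s)
        s = spec.add(f"{tag}.s_relu1", ReLU(), s)
        s = spec.add(f"{tag}.s_pool", MaxPool2D((5, 5)), s)
        s = spec.add(f"{tag}.s_conv2", Conv2D(64, (3, 3), (2, 2)), s)
        s = spec.add(f"{tag}.s_relu2", ReLU(), s)
        s = spec.add(f"{tag}.s_flat", Flatten(), s)
        s = spec.add(f"{tag}.s_gap", GlobalAvgPool(), s)
        s = spec.add(f"{tag}.s_fc", Dense(128), s)
        # time subpath
        t = spec.add(f"{tag}.t_conv1", Conv1D(32, 10, 5), src)
        t = spec.add(f"{tag}.t_relu1", ReLU(), t)
        t = spec.add(f"{tag}.t_pool1", MaxPool1D(5), t)
        t = spec.add(f"{tag}.t_conv2", Conv1D(64, 10, 5), t)
        t = spec.add(f"{tag}.t_relu2", ReLU(), t)
        t = spec.add(f"{tag}.t_pool2", MaxPool1D(5), t)
        t = spec.add(f"{tag}.t_conv3", Conv1D(128, 10, 5), t)
        t = spec.add(f"{tag}.t_relu3", ReLU(), t)
        t = spec.add(f"{tag}.t_gap", GlobalAvgPool(), t)
        return spec.add(f"{tag}.cat", Concat(), [s, t])

    path_out: dict[str, str] = {}
    for ch in CANONICAL_19:
        path_out[ch] = add_path(ch, ChannelSelect((name_to_idx[ch],)))
    full_out = add_path("full", None)

    diff_nodes = []
    for a, b in montage_pairs:
        diff_nodes.append(
            spec.add(f"diff.{a}-{b}", Subtract(), [path_out[a], path_out[b]])
        )
    spec.add("cat_paths", Concat(), diff_nodes + [full_out])
    spec.add("fc3", Dense(3))
    spec.add("softmax", Softmax())
    return spec


BUILDERS = {
    "feature": build_feature_network,
    "tmn": build_tmn,
    "stft": build_stft_network,
    "lstm": build_lstm_network,
    "sfn": build_sfn,
}


# ---------------------------------------------------------------------------
# topographic maps
# ---------------------------------------------------------------------------

def compute_topographic_maps(
    segment,
    positions: dict[str, tuple[float, float]] | None = None,
    size: int = TOPOMAP_SIZE,
) -> np.ndarray:
    """Interpolate per-band relative power onto a ``size x size`` scalp grid.

    Returns a (size, size, 6) tensor; pixels outside the unit scalp disc are
    zero, and the pixel at each electrode site equals that channel's relative
    band power up to interpolation tolerance (thin-plate-spline interpolation
    is exact at the nodes).
    """
    from scipy.interpolate import RBFInterpolator

    from ..features import band_psd_array

    positions = positions or SCALP_POSITIONS
    pts = np.array([positions[ch] for ch in CANONICAL_19], dtype=float)
    if len(np.unique(np.round(pts, 9), axis=0)) != len(pts):
        raise ValueError("coincident electrode positions")
    _, relative = band_psd_array(segment.data, segment.fs)  # (19, 6)

    grid = np.linspace(-1.0, 1.0, size)
    gx, gy = np.meshgrid(grid, grid)
    flat = np.column_stack([gx.ravel(), gy.ravel()])
    interp = RBFInterpolator(pts, relative, kernel="thin_plate_spline")
    maps = interp(flat).reshape(size, size, relative.shape[1])
    outside = gx**2 + gy**2 > 1.0
    maps[outside] = 0.0
    return maps


def topomap_to_network_input(maps: np.ndarray) -> np.ndarray:
    """(H, W, 6) -> channels-first (6, H, W) for the TMN."""
    return np.moveaxis(maps, -1, 0)
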