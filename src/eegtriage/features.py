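"""The 1406-dimensional feature engine.

Per 3-minute segment: absolute and relative band power (19 channels x 6
bands, twice), spectral entropy (19), band-averaged magnitude-squared
coherence for all 171 channel pairs x 6 bands (1026), phase-amplitude
coupling for three low-frequency-phase -> gamma-amplitude couplings (57),
and four time-domain statistics per channel (76): 114+114+19+1026+57+76 =
1406 values in a fixed, named registry order.

Spectral estimates use Welch's method with 2-s Hann windows and 50% overlap;
band powers integrate the density over the band bins; the relative-power and
entropy denominators run over the preprocessed 1-100 Hz support. The band
edges intentionally leave 20-25 Hz and 40-100 Hz uncovered, so the six
relative powers do not sum to 1 on broadband signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal

from .channels import CANONICAL_19, N_CHANNELS
from .recording import Segment


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float


BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("mu", 12.0, 16.0),
    Band("beta", 16.0, 20.0),
    Band("gamma", 25.0, 40.0),
)

TOTAL_BAND = (1.0, 100.0)  # support of the preprocessing bandpass

PAC_COUPLINGS: tuple[tuple[str, str], ...] = (
    ("delta", "gamma"),
    ("theta", "gamma"),
    ("alpha", "gamma"),
)

CHANNEL_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(N_CHANNELS), 2))

STAT_NAMES: tuple[str, ...] = ("mean", "max", "min", "std")

N_FEATURES = 1406

# Welch settings (seconds / fraction); exposed for the config layer.
WELCH_WINDOW_S = 2.0
WELCH_OVERLAP = 0.5


def _welch_params(fs: float) -> dict:
    nperseg = int(round(WELCH_WINDOW_S * fs))
    return dict(
        fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * WELCH_OVERLAP), detrend="constant",
    )


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # half-open bins so adjacent bands share no bin; total band closes at 100
    return (freqs >= lo) & (freqs < hi)


def _check_degenerate(total_power: np.ndarray) -> None:
    bad = np.flatnonzero(total_power <= 0)
    if bad.size:
        names = [CANONICAL_19[i] if i < N_CHANNELS else str(i) for i in bad]
        raise ValueError(
            f"degenerate channel(s) with zero power in 1-100 Hz: {names}; "
            "power normalization undefined"
        )


# ---------------------------------------------------------------------------
# array-level engine (channels x samples, any duration); Segment wrappers below
# ---------------------------------------------------------------------------

def band_psd_array(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Absolute (uV^2) and relative band power, shape (channels, 6) each."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    freqs, psd = signal.welch(data, **_welch_params(fs))
    df = freqs[1] - freqs[0]
    total_mask = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
    total = psd[:, total_mask].sum(axis=1) * df
    _check_degenerate(total)
    absolute = np.empty((data.shape[0], len(BANDS)))
    for j, band in enumerate(BANDS):
        absolute[:, j] = psd[:, _band_mask(freqs, band.lo, band.hi)].sum(axis=1) * df
    relative = absolute / total[:, None]
    return absolute, relative


def spectral_entropy_array(data: np.ndarray, fs: float) -> np.ndarray:
    """Shannon entropy of the normalized 1-100 Hz spectrum, scaled to [0, 1]."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    freqs, psd = signal.welch(data, **_welch_params(fs))
    mask = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
    p = psd[:, mask]
    total = p.sum(axis=1)
    _check_degenerate(total)
    p = p / total[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return h / np.log(mask.sum())


def _welch_ffts(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered, mean-detrended, 50%-overlap windowed rFFTs.

    Returns (freqs, Z) with Z of shape (channels, windows, bins) — the
    common ingredient of the Welch auto- and cross-spectra, computed once so
    all 171 pair cross-spectra come from a single pass over the data.
    """
    params = _welch_params(fs)
    nperseg, noverlap = params["nperseg"], params["noverlap"]
    step = nperseg - noverlap
    win = signal.get_window("hann", nperseg)
    n_win = (data.shape[-1] - noverlap) // step
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_win)[:, None]
    frames = data[:, idx]  # (channels, windows, nperseg)
    frames = frames - frames.mean(axis=-1, keepdims=True)
    Z = np.fft.rfft(frames * win, axis=-1)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, Z


def coherence_array(
    data: np.ndarray, fs: float, pairs: tuple[tuple[int, int], ...] | None = None
) -> np.ndarray:
    """Band-averaged magnitude-squared coherence, shape (n_pairs, 6).

    MSC = |mean_k Za Zb*|^2 / (mean_k |Za|^2 mean_k |Zb|^2) over Welch
    windows k (the density scaling cancels).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if pairs is None:
        pairs = tuple(combinations(range(data.shape[0]), 2))
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    freqs, Z = _welch_ffts(data, fs)
    pxx = (Z.real**2 + Z.imag**2).mean(axis=1)  # (channels, bins)
    _check_degenerate(pxx.sum(axis=1))
    cross = np.einsum("awf,bwf->abf", Z, Z.conj()) / Z.shape[1]
    pxy = cross[ia, ib]  # (pairs, bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(pxy) ** 2 / (pxx[ia] * pxx[ib])
    out = np.empty((len(pairs), len(BANDS)))
    for j, band in enumerate(BANDS):
        out[:, j] = msc[:, _band_mask(freqs, band.lo, band.hi)].mean(axis=1)
    return out


def _bandpass(data: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def pac_array(data: np.ndarray, fs: float) -> np.ndarray:
    """Mean-vector-length phase-amplitude coupling, shape (channels, 3).

    For each coupling (low band -> gamma): phase from the analytic signal of
    the low-band-filtered trace, amplitude envelope from the analytic signal
    of the gamma-filtered trace; modulation index
    MI = |mean(A * exp(i*phi))| / mean(A), in [0, 1].
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    by_name = {b.name: b for b in BANDS}
    out = np.empty((data.shape[0], len(PAC_COUPLINGS)))
    gamma = by_name["gamma"]
    amp = np.abs(signal.hilbert(_bandpass(data, fs, gamma.lo, gamma.hi), axis=-1))
    mean_amp = amp.mean(axis=1)
    for j, (lo_name, _) in enumerate(PAC_COUPLINGS):
        low = by_name[lo_name]
        phase = np.angle(signal.hilbert(_bandpass(data, fs, low.lo, low.hi), axis=-1))
        mvl = np.abs((amp * np.exp(1j * phase)).mean(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, j] = np.where(mean_amp > 0, mvl / mean_amp, 0.0)
    return out


def channel_stats_array(data: np.ndarray) -> np.ndarray:
    """Per-channel (mean, max, min, std), shape (channels, 4)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return np.column_stack(
        [data.mean(axis=1), data.max(axis=1), data.min(axis=1), data.std(axis=1)]
    )


# ---------------------------------------------------------------------------
# registry and Segment-level interface
# ---------------------------------------------------------------------------

def registry_names() -> list[str]:
    """The fixed total order of the 1406 feature names.

    Grammar: ``<family>.<band>.<ch>``, ``coh.<band>.<chA>-<chB>``,
    ``se.<ch>``, ``pac.<low>_gamma.<ch>``, ``stat.<stat>.<ch>``; pairs are
    enumerated lexicographically by canonical channel index.
    """
    names: list[str] = []
    for family in ("abs", "rel"):
        for band in BANDS:
            names += [f"{family}.{band.name}.{ch}" for ch in CANONICAL_19]
    names += [f"se.{ch}" for ch in CANONICAL_19]
    for band in BANDS:
        names += [
            f"coh.{band.name}.{CANONICAL_19[a]}-{CANONICAL_19[b]}"
            for a, b in CHANNEL_PAIRS
        ]
    for lo, hi in PAC_COUPLINGS:
        names += [f"pac.{lo}_{hi}.{ch}" for ch in CANONICAL_19]
    for stat in STAT_NAMES:
        names += [f"stat.{stat}.{ch}" for ch in CANONICAL_19]
    assert len(names) == N_FEATURES
    return names


REGISTRY: tuple[str, ...] = tuple(registry_names())


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values/names length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def band_psd(segment: Segment) -> tuple[np.ndarray, np.ndarray]:
    return band_psd_array(segment.data, segment.fs)


def spectral_entropy(segment: Segment) -> np.ndarray:
    return spectral_entropy_array(segment.data, segment.fs)


def cross_coherence(segment: Segment) -> np.ndarray:
    return coherence_array(segment.data, segment.fs, CHANNEL_PAIRS)


def pac(segment: Segment) -> np.ndarray:
    return pac_array(segment.data, segment.fs)


def channel_stats(segment: Segment) -> np.ndarray:
    return channel_stats_array(segment.data)


def feature_vector(segment: Segment) -> FeatureVector:
    """Concatenate all families in registry order: length exactly 1406."""
    absolute, relative = band_psd(segment)
    se = spectral_entropy(segment)
    coh = cross_coherence(segment)
    p = pac(segment)
    st = channel_stats(segment)
    values = np.concatenate([
        absolute.T.ravel(),   # band-major, channel-minor
        relative.T.ravel(),
        se,
        coh.T.ravel(),        # band-major, pair-minor
        p.T.ravel(),          # coupling-major
        st.T.ravel(),         # stat-major
    ])
    if not np.all(np.isfinite(values)):
        bad = [REGISTRY[i] for i in np.flatnonzero(~np.isfinite(values))[:5]]
        raise ValueError(f"non-finite feature values, first offenders: {bad}")
    return FeatureVector(values=values, names=REGISTRY, segment_id=segment.segment_id)


def feature_matrix(segments: list[Segment]) -> tuple[np.ndarray, list[str]]:
    """Stack feature vectors for a list of segments; returns (X, segment_ids)."""
    vecs = [feature_vector(s) for s in segments]
    return np.vstack([v.values for v in vecs]), [v.segment_id for v in vecs]
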