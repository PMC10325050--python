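"""Standardization, filtering, re-referencing, artifact removal, segmentation.

The preprocessing chain mirrors standard clinical-EEG practice: conform every
recording to the 19 canonical 10-20 channels at a common rate, bandpass
1-100 Hz, re-reference to the common average, optionally reconstruct only the
brain-labeled independent components of an externally supplied decomposition,
then concatenate a session's files, discard the first minute, and cut
3-minute segments.

Filtering uses a zero-phase forward-backward 4th-order Butterworth per pass:
zero phase preserves waveform timing, which the Grad-CAM overlays rely on.
Filtering happens at the native rate; any resampling (polyphase) follows, so
the 100 Hz band edge is never aliased.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal

from .channels import CANONICAL_19, normalize_name
from .recording import (
    DISCARD_SECONDS,
    SEGMENT_SECONDS,
    ComponentLabeling,
    Recording,
    Segment,
)

logger = logging.getLogger(__name__)

BANDPASS = (1.0, 100.0)
TARGET_FS = 250.0


def standardize(recording: Recording, target_fs: float = TARGET_FS) -> Recording:
    """Conform to the canonical 19 channels (order included) and target rate.

    Extra channels are dropped; a missing canonical channel is an error.
    Resampling is polyphase at the exact rational rate ratio.
    """
    names = [normalize_name(ch) for ch in recording.channel_names]
    missing = [ch for ch in CANONICAL_19 if ch not in names]
    if missing:
        raise ValueError(f"missing required channel(s): {', '.join(missing)}")
    order = [names.index(ch) for ch in CANONICAL_19]
    data = recording.data[order]

    fs = recording.fs
    if not np.isclose(fs, target_fs):
        ratio = Fraction(int(round(target_fs * 1000)), int(round(fs * 1000)))
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
        fs = float(target_fs)
    return recording.copy_with(data=data, fs=fs, channel_names=list(CANONICAL_19))


def bandpass_filter(
    data: np.ndarray, fs: float, band: tuple[float, float] = BANDPASS
) -> np.ndarray:
    if fs < 2 * band[1]:
        raise ValueError(
            f"sampling rate {fs:g} Hz cannot represent the {band[1]:g} Hz band "
            "edge; run the bandpass before downsampling"
        )
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=1)


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous cross-channel mean from every channel."""
    return data - data.mean(axis=0, keepdims=True)


def preprocess(recording: Recording) -> Recording:
    """1-100 Hz bandpass, then common-average re-reference.

    After re-referencing, the per-sample mean across the 19 channels is zero
    to numerical precision.
    """
    data = bandpass_filter(recording.data, recording.fs)
    data = common_average_reference(data)
    return recording.copy_with(data=data)


def remove_components(
    recording: Recording, labeling: ComponentLabeling | None
) -> Recording:
    """Reconstruct the signal from brain-labeled components only.

    Component classification itself is external (e.g. ICLabel); absent a
    labeling, the recording passes through unchanged with a logged notice.
    """
    if labeling is None:
        logger.info(
            "no component labeling for %s: artifact removal skipped",
            recording.recording_id,
        )
        return recording
    n_ch = recording.data.shape[0]
    if labeling.unmixing.shape[1] != n_ch or labeling.mixing.shape[0] != n_ch:
        raise ValueError(
            f"labeling transforms are for {labeling.mixing.shape[0]} channels, "
            f"recording has {n_ch}"
        )
    sources = labeling.unmixing @ recording.data
    keep = np.array([lab == "brain" for lab in labeling.labels], dtype=bool)
    sources[~keep] = 0.0
    return recording.copy_with(data=labeling.mixing @ sources)


def concatenate_and_segment(
    recordings: list[Recording],
    discard_s: float = DISCARD_SECONDS,
    segment_s: float = SEGMENT_SECONDS,
) -> list[Segment]:
    """Concatenate a session's files, drop the first ``discard_s`` seconds
    once, and return the full 3-minute segments (1-based indices; partial
    tail discarded). Too little data yields an empty list, not an error.
    """
    if not recordings:
        return []
    fs = recordings[0].fs
    names = list(recordings[0].channel_names)
    for rec in recordings[1:]:
        if not np.isclose(rec.fs, fs):
            raise ValueError("all recordings must share a sampling rate")
        if list(rec.channel_names) != names:
            raise ValueError("all recordings must share channel order")
    data = np.concatenate([rec.data for rec in recordings], axis=1)
    first = recordings[0]
    start = int(round(discard_s * fs))
    seg_len = int(round(segment_s * fs))
    usable = data.shape[1] - start
    n_segments = max(usable // seg_len, 0) if usable > 0 else 0
    if n_segments == 0:
        logger.info("recording %s yields 0 segments", first.recording_id)
        return []
    segments = []
    for i in range(int(n_segments)):
        chunk = data[:, start + i * seg_len : start + (i + 1) * seg_len]
        segments.append(
            Segment(
                data=chunk,
                fs=fs,
                segment_index=i + 1,
                recording_id=first.recording_id,
                label=first.label,
                demographics=first.demographics,
            )
        )
    return segments


def downsample_segment(segment: Segment, target_fs: float = 100.0) -> Segment:
    """Resample a segment (e.g. 250 -> 100 Hz for the featureless networks)."""
    if np.isclose(segment.fs, target_fs):
        return segment
    ratio = Fraction(int(round(target_fs * 1000)), int(round(segment.fs * 1000)))
    data = signal.resample_poly(segment.data, ratio.numerator, ratio.denominator, axis=1)
    expected = int(round(SEGMENT_SECONDS * target_fs))
    data = data[:, :expected]
    return Segment(
        data=data,
        fs=float(target_fs),
        segment_index=segment.segment_index,
        recording_id=segment.recording_id,
        label=segment.label,
        demographics=segment.demographics,
    )
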