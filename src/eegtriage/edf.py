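"""EDF input/output.

Reading goes through ``mne.io.read_raw_edf``; only continuous files (EDF and
EDF+C) are accepted — the concatenate-and-segment semantics downstream assume
continuity, so discontinuous EDF+D files are rejected at the door. Writing is
a minimal plain-EDF encoder (16-bit, 1-second data records) sufficient for
round-tripping the synthetic cohorts and any standardized recording.

Demographics (age, sex) and the class label ride along in the EDF patient /
recording identification fields so a cohort can round-trip through files.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .channels import normalize_name, CANONICAL_19
from .recording import Demographics, Recording


class EDFFormatError(ValueError):
    pass


class ChannelError(ValueError):
    pass


def _header_reserved(path: Path) -> str:
    with open(path, "rb") as f:
        header = f.read(256)
    if len(header) < 256:
        raise EDFFormatError(f"{path}: truncated EDF header")
    return header[192:236].decode("ascii", errors="replace").strip()


def read_recording(path: str | Path, require_canonical: bool = True) -> Recording:
    """Read an EDF file into a Recording (amplitudes in microvolts).

    Channel names are normalized (case, clinical prefixes/suffixes, and the
    legacy T3/T4/T5/T6 aliases mapped to T7/T8/P7/P8). With
    ``require_canonical`` (default), a file missing any of the 19 canonical
    electrodes raises a ChannelError naming the absentees.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reserved = _header_reserved(path)
    if reserved.startswith("EDF+D"):
        raise EDFFormatError(
            f"{path}: EDF+D (discontinuous) files are not supported; "
            "concatenation semantics require continuous recordings"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise EDFFormatError(f"{path}: not parseable as EDF ({exc})") from exc

    names = [normalize_name(ch) for ch in raw.ch_names]
    if require_canonical:
        missing = [ch for ch in CANONICAL_19 if ch not in names]
        if missing:
            raise ChannelError(
                f"{path}: missing required channel(s): {', '.join(missing)}"
            )
    data = raw.get_data() * 1e6  # volts -> microvolts

    demographics, label = _parse_subject_fields(path)
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        demographics=demographics,
        label=label,
        recording_id=path.stem,
    )


def _parse_subject_fields(path: Path) -> tuple[Demographics, str | None]:
    with open(path, "rb") as f:
        header = f.read(256)
    patient = header[8:88].decode("ascii", errors="replace")
    rec_field = header[88:168].decode("ascii", errors="replace")
    sex = None
    m = re.search(r"\b([MF])\b", patient)
    if m:
        sex = m.group(1)
    age = None
    m = re.search(r"age_([0-9.]+)", patient)
    if m:
        age = float(m.group(1))
    label = None
    m = re.search(r"class_(\w+)", rec_field)
    if m:
        label = m.group(1)
    return Demographics(age=age, sex=sex), label


def _fixed(text: str, width: int) -> bytes:
    s = text[:width]
    return s.ljust(width).encode("ascii")


def _num8(v: float) -> str:
    """Format a number into at most 8 ASCII characters without truncation."""
    for prec in range(6, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def write_recording(path: str | Path, recording: Recording) -> Path:
    """Write a Recording as a plain EDF file (16-bit, 1-s data records).

    The sampling rate must be an integer (samples per 1-s record); the tail
    partial second is zero-padded.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per channel
    data = recording.data
    n_ch, n_samp = data.shape
    n_records = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = data

    # physical scaling per channel, symmetric around 0
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    d = recording.demographics
    sex = d.sex if d.sex in ("M", "F") else "X"
    age = f"age_{d.age:g}" if d.age is not None else "X"
    patient = f"X {sex} X {age}"
    rec_id = "Startdate 01-JAN-2000 X X X"
    if recording.label:
        rec_id += f" class_{recording.label}"

    header = b"".join([
        _fixed("0", 8),
        _fixed(patient, 80),
        _fixed(rec_id, 80),
        _fixed("01.01.00", 8),
        _fixed("00.00.00", 8),
        _fixed(str(256 * (1 + n_ch)), 8),
        _fixed("EDF+C", 44),
        _fixed(str(n_records), 8),
        _fixed("1", 8),  # record duration, seconds
        _fixed(str(n_ch), 4),
    ])
    signal_header = b"".join([
        b"".join(_fixed(ch, 16) for ch in recording.channel_names),
        _fixed("EEG", 80) * n_ch,
        _fixed("uV", 8) * n_ch,
        b"".join(_fixed(_num8(-m), 8) for m in phys_max),
        b"".join(_fixed(_num8(m), 8) for m in phys_max),
        _fixed(str(dig_min), 8) * n_ch,
        _fixed(str(dig_max), 8) * n_ch,
        _fixed("", 80) * n_ch,
        _fixed(str(spr), 8) * n_ch,
        _fixed("", 32) * n_ch,
    ])

    # digitize: value -> dig, per channel
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.rint((padded + phys_max[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(signal_header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            f.write(block.tobytes())
    return path
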