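"""Core containers: Recording, Segment, Demographics, ComponentLabeling."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .channels import CANONICAL_19, N_CHANNELS

CLASSES: tuple[str, ...] = ("Normal", "TBI", "Stroke")

SEGMENT_SECONDS = 180.0
DISCARD_SECONDS = 60.0


@dataclass
class Demographics:
    age: Optional[float] = None  # years
    sex: Optional[str] = None    # "M" / "F"


@dataclass
class Recording:
    """A multichannel EEG recording.

    data is a channels x samples matrix in microvolts; ``channel_names`` has
    one entry per row of ``data``.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    demographics: Demographics = field(default_factory=Demographics)
    label: Optional[str] = None
    session_id: str = ""
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be a 2-D channels x samples matrix")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class Segment:
    """A fixed 3-minute window of a standardized recording.

    ``segment_index`` is 1-based: segment #1 covers minutes 1-4 of the
    concatenated recording (the first minute having been discarded).
    """

    data: np.ndarray
    fs: float
    segment_index: int
    recording_id: str = ""
    label: Optional[str] = None
    demographics: Demographics = field(default_factory=Demographics)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != N_CHANNELS:
            raise ValueError(
                f"Segment requires exactly {N_CHANNELS} channels in canonical "
                f"order {CANONICAL_19[:3]}..., got {self.data.shape[0]}"
            )
        expected = int(round(SEGMENT_SECONDS * self.fs))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"Segment duration must be exactly {SEGMENT_SECONDS:.0f} s "
                f"({expected} samples at {self.fs:g} Hz), got {self.data.shape[1]}"
            )
        if self.segment_index < 1:
            raise ValueError("segment_index is 1-based")

    @property
    def segment_id(self) -> str:
        return f"{self.recording_id}#{self.segment_index}"


@dataclass
class ComponentLabeling:
    """An external independent-component decomposition plus per-component labels.

    The package does not run ICA itself; this is the hook through which an
    external decomposition (e.g. ICLabel output) enters the cleaning step.
    ``mixing`` maps component activations back to channels, ``unmixing`` maps
    channel data to component activations.
    """

    labels: Sequence[str]
    mixing: np.ndarray
    unmixing: np.ndarray

    VALID = frozenset(
        {"brain", "muscle", "eye", "heart", "line noise", "channel noise", "other"}
    )

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.unmixing = np.asarray(self.unmixing, dtype=float)
        bad = set(self.labels) - self.VALID
        if bad:
            raise ValueError(f"invalid component labels: {sorted(bad)}")
        n_comp = len(self.labels)
        if self.mixing.shape[1] != n_comp or self.unmixing.shape[0] != n_comp:
            raise ValueError("label count inconsistent with transform shapes")
        ident = self.mixing @ self.unmixing
        if not np.allclose(ident, np.eye(ident.shape[0]), atol=1e-6):
            raise ValueError("mixing and unmixing transforms are not mutually inverse")
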