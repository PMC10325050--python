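import numpy as np
import pytest

from eegtriage.preprocess import concatenate_and_segment, preprocess
from eegtriage.recording import Segment
from eegtriage.synth import DEFAULT_PROFILES, generate_recording

FS = 250.0
SEG_SAMPLES = int(180 * FS)


def make_segment(data: np.ndarray, fs: float = FS, index: int = 1, **kw) -> Segment:
    return Segment(data=data, fs=fs, segment_index=index, **kw)


@pytest.fixture(scope="session")
def normal_segment() -> Segment:
    """One preprocessed 3-minute segment of a Normal-profile recording."""
    rec = preprocess(generate_recording(DEFAULT_PROFILES["Normal"], 240.0, seed=11))
    return concatenate_and_segment([rec])[0]


@pytest.fixture(scope="session")
def stroke_recording():
    return generate_recording(DEFAULT_PROFILES["Stroke"], 240.0, seed=12)


@pytest.fixture(scope="session")
def tone_segment() -> Segment:
    """All channels a pure 10 Hz tone (plus rounding-level noise floor)."""
    t = np.arange(SEG_SAMPLES) / FS
    data = np.tile(np.sin(2 * np.pi * 10.0 * t), (19, 1)) * 20.0
    return make_segment(data)


@pytest.fixture(scope="session")
def white_segment() -> Segment:
    rng = np.random.default_rng(42)
    return make_segment(rng.standard_normal((19, SEG_SAMPLES)) * 10.0)
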