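"""Synthetic EEG generator.

Produces 19-channel recordings with the statistical structure the triage
pipeline discriminates on: class-specific band-power profiles (post-injury
slowing raises delta/theta at the expense of alpha), hemispheric amplitude
asymmetry (stroke-like lateralization), inter-channel coherence within a
chosen band, and a broadband noise floor. The signal model is a sum of
band-limited Gaussian noise processes — one per frequency band, variance
proportional to the band weight — plus white noise; coherence is injected by
mixing a shared latent band-limited source into every channel. No claim of
physiological realism is made beyond these spectral/spatial properties.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .channels import CANONICAL_19, LEFT_HEMISPHERE, N_CHANNELS
from .features import BANDS
from .recording import CLASSES, Demographics, Recording

MIN_DURATION_S = 240.0  # first minute is discarded and one 3-min segment must survive


@dataclass
class ClassProfile:
    """Spectral/spatial recipe for one diagnostic class."""

    label: str
    band_power_weights: tuple[float, ...]  # over (delta, theta, alpha, mu, beta, gamma)
    asymmetry: float = 0.0        # >0 boosts left-hemisphere amplitude vs right
    coherence_level: float = 0.0  # target pairwise magnitude-squared coherence
    coherence_band: str = "alpha"
    noise_floor: float = 0.15     # broadband noise std relative to signal scale

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}")
        w = np.asarray(self.band_power_weights, dtype=float)
        if w.shape != (len(BANDS),) or np.any(w < 0):
            raise ValueError("band_power_weights must be six non-negative weights")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("band_power_weights must sum to 1")
        if not -1.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [-1, 1]")
        if not 0.0 <= self.coherence_level <= 1.0:
            raise ValueError("coherence_level must lie in [0, 1]")
        if self.coherence_band not in {b.name for b in BANDS}:
            raise ValueError(f"unknown coherence_band {self.coherence_band!r}")


# Default study profiles. Normal: alpha-dominant resting EEG. TBI: diffuse
# slowing (delta/theta up, alpha suppressed). Stroke: slowing plus a marked
# left-right amplitude asymmetry.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "Normal": ClassProfile(
        label="Normal",
        band_power_weights=(0.25, 0.15, 0.35, 0.08, 0.12, 0.05),
        asymmetry=0.0, coherence_level=0.3,
    ),
    "TBI": ClassProfile(
        label="TBI",
        band_power_weights=(0.45, 0.25, 0.12, 0.06, 0.08, 0.04),
        asymmetry=0.0, coherence_level=0.2,
    ),
    "Stroke": ClassProfile(
        label="Stroke",
        band_power_weights=(0.40, 0.22, 0.18, 0.07, 0.09, 0.04),
        asymmetry=0.35, coherence_level=0.25,
    ),
}


@dataclass
class CohortSpec:
    """Demographic recipe for a synthetic cohort."""

    n_per_class: int
    age_mean: float = 42.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_ratio_male: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(
    profile: ClassProfile,
    duration_s: float = 600.0,
    fs: float = 250.0,
    seed: int = 0,
    recording_id: str = "",
    amplitude_uv: float = 30.0,
) -> Recording:
    """Synthesize one 19-channel recording following a class profile.

    The per-band processes are independent across channels except in the
    profile's coherence band, where every channel receives a shared latent
    source with mixing weight sqrt(coherence_level) (the magnitude-squared
    coherence between two channels then approaches coherence_level).
    Left-hemisphere channels are scaled by (1 + asymmetry).
    """
    if duration_s < MIN_DURATION_S:
        raise ValueError(
            f"duration_s must be >= {MIN_DURATION_S:.0f} s so that at least one "
            "3-minute segment survives the first-minute discard"
        )
    if fs not in (100.0, 250.0, 100, 250):
        raise ValueError("fs must be 100 or 250 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    weights = np.asarray(profile.band_power_weights, dtype=float)
    amps = np.sqrt(weights)  # amplitude scale per band: power proportional to weight

    data = np.zeros((N_CHANNELS, n))
    shared_mix = np.sqrt(profile.coherence_level)
    for band, amp in zip(BANDS, amps):
        if amp == 0:
            continue
        if band.name == profile.coherence_band and shared_mix > 0:
            latent = _band_limited_noise(rng, n, fs, band.lo, band.hi)
            own = np.sqrt(1.0 - profile.coherence_level)
            for ch in range(N_CHANNELS):
                indep = _band_limited_noise(rng, n, fs, band.lo, band.hi)
                data[ch] += amp * (shared_mix * latent + own * indep)
        else:
            for ch in range(N_CHANNELS):
                data[ch] += amp * _band_limited_noise(rng, n, fs, band.lo, band.hi)

    if profile.noise_floor > 0:
        data += profile.noise_floor * rng.standard_normal((N_CHANNELS, n))

    if profile.asymmetry != 0.0:
        left = [i for i, name in enumerate(CANONICAL_19) if name in LEFT_HEMISPHERE]
        data[left] *= 1.0 + profile.asymmetry

    data *= amplitude_uv
    return Recording(
        data=data,
        fs=float(fs),
        channel_names=list(CANONICAL_19),
        label=profile.label,
        recording_id=recording_id or f"{profile.label.lower()}-{seed}",
    )


def generate_cohort(
    spec: CohortSpec,
    profiles: list[ClassProfile] | None = None,
    duration_s: float = 600.0,
    fs: float = 250.0,
) -> list[Recording]:
    """Generate n_per_class recordings per profile with seeded demographics."""
    if profiles is None:
        profiles = list(DEFAULT_PROFILES.values())
    if not profiles:
        raise ValueError("profiles must be a non-empty list")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    recs: list[Recording] = []
    for profile in profiles:
        for i in range(spec.n_per_class):
            if spec.age_sd == 0:
                age = float(np.clip(spec.age_mean, lo, hi))
            else:
                a = (lo - spec.age_mean) / spec.age_sd
                b = (hi - spec.age_mean) / spec.age_sd
                age = float(
                    stats.truncnorm.rvs(
                        a, b, loc=spec.age_mean, scale=spec.age_sd, random_state=rng
                    )
                )
            sex = "M" if rng.random() < spec.sex_ratio_male else "F"
            rec_seed = int(rng.integers(0, 2**31 - 1))
            suffix = "".join(rng.choice(list(string.ascii_lowercase), 4))
            rec = generate_recording(
                profile, duration_s=duration_s, fs=fs, seed=rec_seed,
                recording_id=f"{profile.label.lower()}-{i:03d}-{suffix}",
            )
            rec.demographics = Demographics(age=age, sex=sex)
            recs.append(rec)
    return recs


def generate_scored_records(
    n: int,
    class_separation: float,
    seed: int = 0,
    prevalence: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize (confidence score, in-category label) pairs.

    Scores are logistic transforms of Gaussian decision values whose means
    differ by ``class_separation`` between in- and out-of-category records;
    at separation 0 the scores carry no information.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < prevalence).astype(int)
    z = rng.standard_normal(n) + class_separation * (labels - 0.5)
    scores = 1.0 / (1.0 + np.exp(-z))
    return scores, labels
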