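"""Feature engine: registry contract, closed-form oracles, equivariance."""

import numpy as np
import pytest

from eegtriage.channels import CANONICAL_19
from eegtriage.features import (
    BANDS,
    CHANNEL_PAIRS,
    N_FEATURES,
    REGISTRY,
    band_psd_array,
    channel_stats_array,
    coherence_array,
    feature_vector,
    pac_array,
    registry_names,
    spectral_entropy_array,
)
from tests.conftest import FS, SEG_SAMPLES, make_segment


# ---------------------------------------------------------------------------
# independent Welch oracle: direct FFT cross-spectra, written from the
# definition (hann taper, mean detrend per window, 50% overlap)
# ---------------------------------------------------------------------------

def oracle_welch_cross(x, y, fs, nperseg):
    step = nperseg // 2
    win = np.hanning(nperseg + 1)[:-1]  # periodic hann, matches scipy's
    spectra = []
    for start in range(0, x.size - nperseg + 1, step):
        fx = x[start : start + nperseg]
        fy = y[start : start + nperseg]
        Fx = np.fft.rfft((fx - fx.mean()) * win)
        Fy = np.fft.rfft((fy - fy.mean()) * win)
        spectra.append(Fx * np.conj(Fy))
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, np.mean(spectra, axis=0)


def oracle_psd_density(x, fs, nperseg):
    freqs, sxx = oracle_welch_cross(x, x, fs, nperseg)
    win = np.hanning(nperseg + 1)[:-1]
    scale = 1.0 / (fs * (win**2).sum())
    psd = sxx.real * scale
    psd[1:-1] *= 2.0  # one-sided
    return freqs, psd


class TestWelchOracles:
    """Coherence and PSD agree with direct FFT definitions on 10-s toys."""

    def test_band_psd_matches_oracle(self):
        rng = np.random.default_rng(0)
        fs, n = 250.0, 2500
        x = rng.standard_normal(n) + np.sin(2 * np.pi * 11 * np.arange(n) / fs)
        freqs, psd = oracle_psd_density(x, fs, nperseg=500)
        df = freqs[1] - freqs[0]
        absolute, _ = band_psd_array(x, fs)
        for j, band in enumerate(BANDS):
            mask = (freqs >= band.lo) & (freqs < band.hi)
            assert abs(absolute[0, j] - psd[mask].sum() * df) < 1e-6

    def test_coherence_matches_oracle(self):
        rng = np.random.default_rng(1)
        fs, n = 250.0, 2500
        shared = rng.standard_normal(n)
        x = shared + 0.5 * rng.standard_normal(n)
        y = shared + 0.5 * rng.standard_normal(n)
        freqs, sxy = oracle_welch_cross(x, y, fs, 500)
        _, sxx = oracle_welch_cross(x, x, fs, 500)
        _, syy = oracle_welch_cross(y, y, fs, 500)
        msc = np.abs(sxy) ** 2 / (sxx.real * syy.real)
        mine = coherence_array(np.vstack([x, y]), fs, ((0, 1),))
        for j, band in enumerate(BANDS):
            mask = (freqs >= band.lo) & (freqs < band.hi)
            assert abs(mine[0, j] - msc[mask].mean()) < 1e-6


class TestBandPSD:
    def test_pure_tone_concentrates_in_alpha(self, tone_segment):
        _, rel = band_psd_array(tone_segment.data, FS)
        assert rel[:, 2].min() > 0.99

    def test_white_noise_relative_power_tracks_bandwidth(self, white_segment):
        _, rel = band_psd_array(white_segment.data, FS)
        for j, band in enumerate(BANDS):
            expected = (band.hi - band.lo) / 99.0
            assert abs(rel[:, j].mean() - expected) / expected < 0.10

    def test_relative_bands_do_not_cover_everything(self, white_segment):
        _, rel = band_psd_array(white_segment.data, FS)
        assert rel.sum(axis=1).max() < 1.0  # 20-25 and 40-100 Hz uncovered

    def test_zero_channel_is_degenerate(self):
        data = np.zeros((19, SEG_SAMPLES))
        data[1:] = np.random.default_rng(0).standard_normal((18, SEG_SAMPLES))
        with pytest.raises(ValueError, match="degenerate"):
            band_psd_array(data, FS)


class TestSpectralEntropy:
    def test_tone_low_noise_high(self, tone_segment, white_segment):
        se_tone = spectral_entropy_array(tone_segment.data, FS)
        se_noise = spectral_entropy_array(white_segment.data, FS)
        assert se_tone.max() < 0.25
        assert se_noise.min() > 0.95

    def test_doubling_the_atoms_adds_log2(self):
        """Two equal tones carry log(2)/log(Nbins) more entropy than one
        (exact for atoms; leakage shifts both identically)."""
        t = np.arange(SEG_SAMPLES) / FS
        one = np.sin(2 * np.pi * 10 * t)
        two = one + np.sin(2 * np.pi * 30 * t)
        se1 = spectral_entropy_array(one, FS)[0]
        se2 = spectral_entropy_array(two, FS)[0]
        n_bins = 199  # 1.0 .. 100.0 Hz inclusive at df = 0.5
        assert abs((se2 - se1) - np.log(2) / np.log(n_bins)) < 0.02


class TestCoherence:
    def test_identical_channels_fully_coherent(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(SEG_SAMPLES)
        coh = coherence_array(np.vstack([x, x]), FS, ((0, 1),))
        assert np.allclose(coh, 1.0)

    def test_independent_channels_near_bias_floor(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, SEG_SAMPLES))
        coh = coherence_array(data, FS, ((0, 1),))
        k = 179  # Welch windows in 180 s at 2-s / 50% overlap
        assert abs(coh.mean() - 1.0 / k) < 3.0 / k

    def test_pair_count_is_171_by_6(self, white_segment):
        coh = coherence_array(white_segment.data, FS)
        assert coh.shape == (171, 6)
        assert len(CHANNEL_PAIRS) == 171


class TestPAC:
    def test_theta_modulated_gamma_detected(self):
        t = np.arange(SEG_SAMPLES) / FS
        rng = np.random.default_rng(4)
        theta = np.sin(2 * np.pi * 6 * t)
        x = (1 + 0.9 * theta) * np.sin(2 * np.pi * 32 * t) + theta
        x = x + 0.05 * rng.standard_normal(t.size)
        mi = pac_array(x, FS)[0]  # (delta->g, theta->g, alpha->g)
        assert mi[1] > mi[0] and mi[1] > mi[2]

    def test_white_noise_pac_near_zero_vs_surrogate(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(SEG_SAMPLES)
        mi = pac_array(x, FS)[0]
        # phase-shuffled surrogate distribution (circular shifts)
        surrogates = [
            pac_array(np.roll(x, s), FS)[0] for s in (5000, 15000, 30000)
        ]
        assert mi.max() < 5 * np.max(surrogates)
        assert mi.max() < 0.05

    def test_stationary_sinusoid_uncoupled(self):
        t = np.arange(SEG_SAMPLES) / FS
        mi = pac_array(np.sin(2 * np.pi * 32 * t), FS)[0]
        assert mi.max() < 0.02


class TestChannelStats:
    def test_constant_and_alternating_channels(self):
        data = np.zeros((2, 100))
        data[0] = 3.5
        data[1, ::2], data[1, 1::2] = -1.0, 1.0
        st = channel_stats_array(data)
        assert np.allclose(st[0], [3.5, 3.5, 3.5, 0.0])
        assert st[1, 0] == 0.0 and st[1, 1] == 1.0 and st[1, 2] == -1.0

    def test_order_statistics_invariant(self, white_segment):
        st = channel_stats_array(white_segment.data)
        assert np.all(st[:, 2] <= st[:, 0]) and np.all(st[:, 0] <= st[:, 1])
        assert np.all(st[:, 3] >= 0)


class TestFeatureVector:
    def test_length_and_family_arithmetic(self, normal_segment):
        fv = feature_vector(normal_segment)
        assert len(fv.values) == N_FEATURES == 1406
        fams = [n.split(".")[0] for n in fv.names]
        counts = {f: fams.count(f) for f in set(fams)}
        assert counts == {
            "abs": 114, "rel": 114, "se": 19, "coh": 1026, "pac": 57,
            "stat": 76,
        }

    def test_registry_is_stable_and_deterministic(self, normal_segment):
        assert tuple(registry_names()) == REGISTRY
        a = feature_vector(normal_segment)
        b = feature_vector(normal_segment)
        assert np.array_equal(a.values, b.values)

    def test_channel_equivariance(self, normal_segment):
        """Permuting input channels and un-permuting the registry gives the
        same values."""
        fv = feature_vector(normal_segment)
        perm = np.random.default_rng(6).permutation(19)
        permuted = make_segment(
            normal_segment.data[perm], index=normal_segment.segment_index
        )
        fv_p = feature_vector(permuted)
        base = dict(zip(fv.names, fv.values))
        # permuted channel i carries the data originally named CANONICAL_19[perm[i]]
        rename = {CANONICAL_19[i]: CANONICAL_19[perm[i]] for i in range(19)}

        def undo(name: str) -> str:
            fam, *rest = name.split(".")
            if fam == "coh":
                band, pair = rest
                a, b = (rename[c] for c in pair.split("-"))
                ia, ib = CANONICAL_19.index(a), CANONICAL_19.index(b)
                (ia, ib) = sorted((ia, ib))
                return f"coh.{band}.{CANONICAL_19[ia]}-{CANONICAL_19[ib]}"
            rest[-1] = rename[rest[-1]]
            return ".".join([fam] + rest)

        for name, value in zip(fv_p.names, fv_p.values):
            assert base[undo(name)] == pytest.approx(value, abs=1e-9)
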