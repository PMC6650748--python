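import numpy as np
import pytest

from sounddissim import features as ft
from sounddissim.stimuli import AudioClip, synth_instrument, synth_vowel


SR = 44100


def _clip(samples, label="test"):
    return AudioClip(np.asarray(samples, float), SR, label, "environmental", "x")


def _tone(freq, dur=0.25, amp=0.1):
    t = np.arange(int(dur * SR)) / SR
    return _clip(amp * np.sin(2 * np.pi * freq * t))


def _noise(dur=0.25, amp=0.1, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(dur * SR))
    return _clip(amp * x / np.max(np.abs(x)))


class TestCochleagram:
    def test_tone_peaks_at_matching_channel(self):
        coch = ft.erb_cochleagram(_tone(1000))
        total = coch.energy.sum(axis=1)
        peak = np.argmax(total)
        cf = coch.center_frequencies
        spacing = cf[peak + 1] - cf[peak - 1]
        assert abs(cf[peak] - 1000) < spacing

    def test_silence_gives_zero_energy(self):
        coch = ft.erb_cochleagram(_clip(np.zeros(11025)))
        assert np.allclose(coch.energy, 0)

    def test_noise_spreads_energy_over_more_channels(self):
        def active_channels(clip):
            e = ft.erb_cochleagram(clip).energy.sum(axis=1)
            return (e > 0.1 * e.max()).sum()
        assert active_channels(_noise()) >= 10 * active_channels(_tone(1000))

    def test_default_geometry(self):
        coch = ft.erb_cochleagram(_tone(500))
        assert coch.energy.shape[0] == 77
        assert coch.center_frequencies[0] == pytest.approx(30, rel=1e-6)
        assert coch.center_frequencies[-1] == pytest.approx(16000, rel=1e-6)

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(ft.FeatureError):
            ft.erb_cochleagram(_tone(500), fmax=30000)


class TestSpectralStats:
    def _coch(self, energy, cfs=None):
        energy = np.asarray(energy, float)
        cfs = cfs if cfs is not None else np.linspace(100, 2000, energy.shape[0])
        times = np.arange(energy.shape[1]) * 0.005
        return ft.Cochleagram(energy, np.asarray(cfs, float), times)

    def test_single_channel_centroid(self):
        E = np.zeros((3, 4))
        E[1] = 1.0
        c, f = ft.spectral_frame_stats(self._coch(E, [500, 1000, 1500]))
        assert np.allclose(c, 1000)
        assert np.all(f < 0.01)  # near the floor-limited minimum

    def test_two_channel_symmetry(self):
        E = np.zeros((3, 2))
        E[0] = E[2] = 1.0
        c, _ = ft.spectral_frame_stats(self._coch(E, [500, 1000, 1500]))
        assert np.allclose(c, 1000)

    def test_flat_spectrum_gives_flatness_one(self):
        E = np.full((10, 5), 3.0)
        _, f = ft.spectral_frame_stats(self._coch(E))
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_zero_frame_excluded(self):
        E = np.ones((4, 3))
        E[:, 1] = 0.0
        c, f = ft.spectral_frame_stats(self._coch(E))
        assert np.isnan(c[1]) and np.isnan(f[1])
        assert np.isfinite(c[[0, 2]]).all()

    def test_variability_identical_frames(self):
        E = np.tile(np.arange(1.0, 6.0)[:, None], (1, 4))
        v = ft.spectral_variability(self._coch(E))
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_variability_anticorrelated_frames(self):
        a = np.arange(1.0, 6.0)
        b = a.mean() - (a - a.mean())  # negation about the mean
        E = np.stack([a, b], axis=1)
        v = ft.spectral_variability(self._coch(E))
        assert v[0] == pytest.approx(2.0)

    def test_variability_independent_noise_near_one(self):
        rng = np.random.default_rng(0)
        E = rng.random((40, 200))
        v = ft.spectral_variability(self._coch(E))
        assert abs(np.nanmedian(v) - 1.0) < 0.15

    def test_variability_needs_two_frames(self):
        with pytest.raises(ft.FeatureError):
            ft.spectral_variability(self._coch(np.ones((3, 1))))


class TestYin:
    @pytest.mark.parametrize("f0", [99.16, 130.81, 164.81, 220.0, 251.38])
    def test_harmonic_complex_recovered(self, f0):
        t = np.arange(11025) / SR
        x = sum(np.sin(2 * np.pi * k * f0 * t) / k for k in range(1, 6))
        clip = _clip(0.1 * x / np.max(np.abs(x)))
        f, ap = ft.yin_track(clip)
        assert abs(np.median(f) - f0) < 1.0
        assert np.median(ap) < 0.05

    def test_pure_sine_precision(self):
        f, _ = ft.yin_track(_tone(164.81))
        assert abs(np.median(f) - 164.81) < 0.5

    def test_noise_is_aperiodic_with_unstable_track(self):
        f, ap = ft.yin_track(_noise())
        assert np.median(ap) > 0.2
        iqr = np.percentile(f, 75) - np.percentile(f, 25)
        f_tone, _ = ft.yin_track(_tone(164.81))
        iqr_tone = np.percentile(f_tone, 75) - np.percentile(f_tone, 25)
        assert iqr > 100 * max(iqr_tone, 0.01)

    def test_short_clip_rejected(self):
        with pytest.raises(ft.FeatureError):
            ft.yin_track(_clip(np.ones(500)))

    def test_window_precondition(self):
        with pytest.raises(ft.FeatureError):
            ft.yin_track(_tone(200), fmin_search=40, window=0.025)


class TestTemporal:
    def test_constant_envelope_centroid(self):
        clip = _tone(1000, dur=0.25)
        _, tc = ft.temporal_features(clip)
        assert tc == pytest.approx(0.125, abs=0.005)

    def test_linear_ramp_centroid(self):
        # envelope rising linearly over [0, T]: centroid at 2T/3
        T = 0.25
        t = np.arange(int(T * SR)) / SR
        clip = _clip((t / T) * 0.5 * np.sin(2 * np.pi * 2000 * t))
        _, tc = ft.temporal_features(clip)
        assert tc == pytest.approx(2 * T / 3, abs=0.01)

    def test_attack_time_ratio(self):
        fast = synth_instrument(164.81, attack=5, duration=0.3)
        slow = synth_instrument(164.81, attack=100, duration=0.3)
        lat_fast, _ = ft.temporal_features(fast)
        lat_slow, _ = ft.temporal_features(slow)
        # 10%-90% rise scales with attack: difference approx log10(100/5)
        assert lat_slow - lat_fast == pytest.approx(np.log10(100 / 5), abs=0.35)

    def test_silent_clip_rejected(self):
        with pytest.raises(ft.FeatureError):
            ft.temporal_features(_clip(np.zeros(11025)))


class TestMPS:
    def test_am_noise_peaks_at_modulation_rate(self):
        rng = np.random.default_rng(0)
        dur = 1.0
        t = np.arange(int(dur * SR)) / SR
        x = rng.standard_normal(t.size) * (1 + 0.95 * np.sin(2 * np.pi * 8 * t))
        clip = _clip(0.2 * x / np.max(np.abs(x)))
        mps = ft.modulation_power_spectrum(clip)
        marg = mps.power.sum(axis=0)
        pos = mps.temporal_axis > 2.0
        peak = mps.temporal_axis[pos][np.argmax(marg[pos])]
        step = np.diff(mps.temporal_axis).mean()
        assert abs(peak - 8.0) <= step + 0.5

    def test_harmonic_tone_spectral_modulation(self):
        f0 = 100.0
        t = np.arange(11025) / SR
        x = sum(np.sin(2 * np.pi * k * f0 * t) for k in range(1, 40))
        clip = _clip(0.1 * x / np.max(np.abs(x)))
        mps = ft.modulation_power_spectrum(clip)
        marg = mps.power.sum(axis=1)
        sel = mps.spectral_axis > 5.0
        peak = mps.spectral_axis[sel][np.argmax(marg[sel])]
        assert abs(peak - 10.0) < 1.0  # 100 Hz spacing = 10 cyc/kHz

    def test_stationary_noise_concentrates_at_zero_temporal_modulation(self):
        mps = ft.modulation_power_spectrum(_noise())
        marg = mps.power.sum(axis=0)
        zero_bin = np.argmin(np.abs(mps.temporal_axis))
        assert np.argmax(marg) == zero_bin

    def test_axis_limits_match_convention(self):
        mps = ft.modulation_power_spectrum(_noise())
        assert mps.temporal_axis.max() <= ft.MPS_TEMPORAL_MAX_HZ * 1.01
        assert mps.spectral_axis.max() <= ft.MPS_SPECTRAL_MAX_CYC_PER_KHZ * 1.01
        assert mps.spectral_axis.min() >= 0
        assert mps.temporal_axis.min() < 0


class TestSummaries:
    def test_silence_rejected(self):
        with pytest.raises(ft.FeatureError):
            ft.summarize(_clip(np.zeros(11025)))

    def test_level_invariance(self):
        clip = synth_vowel(164.81, "a", seed=0)
        half = AudioClip(clip.samples * 0.5, SR, "half", "vocal", "a",
                         nominal_f0=164.81)
        r1 = ft.summarize(clip)
        r2 = ft.summarize(half)
        for key in ("spectral_centroid_median", "spectral_flatness_median",
                    "spectral_variability_median", "aperiodicity_median",
                    "f0_median"):
            assert r1.scalars[key] == pytest.approx(r2.scalars[key], rel=1e-6)

    def test_feature_row_invariants(self, feature_table):
        df = feature_table.scalars
        assert ((df.spectral_flatness_median >= 0)
                & (df.spectral_flatness_median <= 1)).all()
        assert ((df.spectral_variability_median >= 0)
                & (df.spectral_variability_median <= 2)).all()
        assert ((df.aperiodicity_median >= 0)
                & (df.aperiodicity_median <= 1)).all()
        assert (df.spectral_centroid_iqr >= 0).all()
        assert (df.f0_iqr >= 0).all()

    def test_vocal_pitch_stable_environmental_not(self, feature_table):
        df = feature_table.scalars
        cats = feature_table.categories
        voc = df.loc[[i for i in df.index if cats[i] == "vocal"]]
        env = df.loc[[i for i in df.index if cats[i] == "environmental"]]
        assert (voc.f0_iqr < 5).all()
        assert env.aperiodicity_median.min() > voc.aperiodicity_median.max()
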