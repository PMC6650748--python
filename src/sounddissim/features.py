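"""Acoustic descriptor suite for standardized clips.

Scalar descriptors (summarized by median, and IQR where meaningful):

* log-attack-time, temporal centroid (energy-envelope shape)
* spectral centroid and flatness of the ERB-spaced cochleagram envelope
* spectral variability (1 - correlation of successive channel spectra)
* YIN fundamental frequency and aperiodicity (depth of the chosen dip in
  the cumulative-mean-normalized difference function)

Vector descriptors:

* per-channel cochleagram energy (median and IQR over frames, 77 channels
  spanning 30 Hz - 16 kHz on the ERB-rate scale)
* modulation power spectrum (2-D FFT of a Gaussian-window log-magnitude
  spectrogram clipped to a 50 dB dynamic range), with axis limits of
  47.92 Hz temporal and 31.24 cyc/kHz spectral modulation
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .stimuli import AudioClip


class FeatureError(ValueError):
    pass


#: scalar feature columns of a FeatureRow, in canonical order
SCALAR_FEATURES = [
    "log_attack_time",
    "temporal_centroid",
    "spectral_centroid_median",
    "spectral_centroid_iqr",
    "spectral_flatness_median",
    "spectral_flatness_iqr",
    "spectral_variability_median",
    "aperiodicity_median",
    "f0_median",
    "f0_iqr",
]

#: vector-valued features (Euclidean distances in downstream analyses)
VECTOR_FEATURES = ["cochleagram_median", "cochleagram_iqr", "mps"]

ALL_FEATURES = SCALAR_FEATURES + VECTOR_FEATURES

_EPS = 1e-12


# ---------------------------------------------------------------------------
# ERB cochleagram
# ---------------------------------------------------------------------------

def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-rate (Glasberg-Moore): 21.4*log10(4.37*f/1000 + 1)."""
    return 21.4 * np.log10(4.37 * np.asarray(f, dtype=float) / 1000.0 + 1.0)


def erb_rate_inverse(e: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) * 1000.0 / 4.37


def erb_center_frequencies(n_channels: int = 77, fmin: float = 30.0,
                           fmax: float = 16000.0) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale."""
    return np.asarray(
        erb_rate_inverse(np.linspace(erb_rate(fmin), erb_rate(fmax), n_channels))
    )


@dataclass
class Cochleagram:
    energy: np.ndarray            # channels x frames, linear envelope energy
    center_frequencies: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.energy < 0):
            raise FeatureError("cochleagram energy must be non-negative")
        if np.any(np.diff(self.center_frequencies) <= 0):
            raise FeatureError("center frequencies must be strictly increasing")


def _gammatone_envelope(x: np.ndarray, cf: float, sr: int, order: int = 4) -> np.ndarray:
    """Envelope of one gammatone channel via a cascade of complex one-poles.

    A 4th-order gammatone is realized as four identical complex
    first-order filters with pole exp((-2*pi*b + 2j*pi*cf)/sr), where
    b = 1.019 * ERB(cf); this form is numerically stable at every center
    frequency and the complex output magnitude is the channel envelope.
    """
    bw = 1.019 * 24.7 * (4.37 * cf / 1000.0 + 1.0)
    pole = np.exp((-2 * np.pi * bw + 2j * np.pi * cf) / sr)
    gain = 1.0 - np.abs(pole)  # unity gain at cf per stage
    y = x.astype(complex)
    for _ in range(order):
        y = signal.lfilter([gain], [1.0, -pole], y)
    return np.abs(y)


def erb_cochleagram(clip: AudioClip, n_channels: int = 77, fmin: float = 30.0,
                    fmax: float = 16000.0, frame_rate: float = 200.0) -> Cochleagram:
    """Gammatone filterbank envelopes framed at ``frame_rate``.

    Each of the ERB-spaced channels is a 4th-order gammatone filter; the
    channel envelope (magnitude of the complex filter output) is averaged
    within non-overlapping frames.  Channel gains are scaled by the
    inverse square root of channel bandwidth (referenced to the 1 kHz
    channel) so that white noise produces a flat channel-energy profile;
    without this the wider high-frequency channels collect more noise
    energy and bias the flatness descriptor.
    """
    sr = clip.sample_rate
    if fmax >= sr / 2:
        raise FeatureError("fmax must be below the Nyquist frequency")
    x = np.asarray(clip.samples, dtype=float)
    cfs = erb_center_frequencies(n_channels, fmin, fmax)
    bws = 1.019 * 24.7 * (4.37 * cfs / 1000.0 + 1.0)
    bw_ref = 1.019 * 24.7 * (4.37 * 1000.0 / 1000.0 + 1.0)
    gains = np.sqrt(bw_ref / bws)
    hop = max(1, round(sr / frame_rate))
    n_frames = x.size // hop
    energy = np.empty((n_channels, n_frames))
    for c, cf in enumerate(cfs):
        env = gains[c] * _gammatone_envelope(x, cf, sr)
        energy[c] = env[: n_frames * hop].reshape(n_frames, hop).mean(axis=1)
    times = (np.arange(n_frames) + 0.5) * hop / sr
    return Cochleagram(energy, cfs, times)


def spectral_frame_stats(coch: Cochleagram) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame spectral centroid (Hz) and flatness (0-1).

    Centroid is the energy-weighted mean of channel center frequencies;
    flatness is the geometric-to-arithmetic mean ratio of channel energies
    (with a small floor to avoid log(0)).  All-zero frames yield NaN and
    are excluded from downstream summaries.
    """
    E = coch.energy
    if E.size == 0:
        raise FeatureError("empty cochleagram")
    total = E.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = (coch.center_frequencies[:, None] * E).sum(axis=0) / total
        flatness = np.exp(np.mean(np.log(E + _EPS), axis=0)) / np.mean(E + _EPS, axis=0)
    centroid[total == 0] = np.nan
    flatness = np.clip(flatness, 0.0, 1.0)
    flatness[total == 0] = np.nan
    return centroid, flatness


def spectral_variability(coch: Cochleagram) -> np.ndarray:
    """Per-step 1 - Pearson correlation of successive channel spectra.

    Steps where either frame has zero variance across channels are
    skipped (returned as NaN).
    """
    E = coch.energy
    if E.shape[1] < 2:
        raise FeatureError("need at least 2 frames")
    A, B = E[:, :-1], E[:, 1:]
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    denom = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac * Bc).sum(axis=0) / denom
    v = 1.0 - r
    v[denom == 0] = np.nan
    return v


# ---------------------------------------------------------------------------
# YIN fundamental frequency and aperiodicity
# ---------------------------------------------------------------------------

def yin_track(
    clip: AudioClip,
    fmin_search: float = 80.0,
    fmax_search: float = 800.0,
    window: float = 0.025,
    hop: float = 0.005,
    threshold: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame F0 (Hz) and aperiodicity (0-1) via the YIN algorithm.

    Each frame computes the difference function d(tau), its
    cumulative-mean-normalized form d'(tau), picks the first dip below
    ``threshold`` (descending to its local minimum; global minimum if no
    dip qualifies), refines tau by parabolic interpolation, and reports
    the dip depth d'(tau*) as the frame's aperiodicity.
    """
    sr = clip.sample_rate
    W = math.ceil(window * sr)
    if W < 2 * sr / fmin_search:
        raise FeatureError("window must span at least 2 periods of fmin_search")
    tau_min = max(2, int(sr / fmax_search))
    tau_max = int(math.ceil(sr / fmin_search))
    frame_len = W + tau_max
    x = np.asarray(clip.samples, dtype=float)
    if x.size < frame_len:
        raise FeatureError("clip shorter than one analysis frame")
    hop_n = max(1, round(hop * sr))
    starts = np.arange(0, x.size - frame_len + 1, hop_n)

    f0s = np.empty(starts.size)
    aps = np.empty(starts.size)
    taus = np.arange(tau_max + 1)
    for i, s in enumerate(starts):
        frame = x[s : s + frame_len]
        # d(tau) = sum_j (x[j] - x[j+tau])^2 over the W-sample window
        csum2 = np.concatenate([[0.0], np.cumsum(frame**2)])
        e0 = csum2[W]                                  # sum x[j]^2
        e_tau = csum2[taus + W] - csum2[taus]          # sum x[j+tau]^2
        # cross terms via FFT correlation
        nfft = 1 << int(frame_len * 2 - 1).bit_length()
        fx = np.fft.rfft(frame, nfft)
        fw = np.fft.rfft(frame[:W][::-1], nfft)
        corr = np.fft.irfft(fx * fw, nfft)[W - 1 : W + tau_max]
        d = e0 + e_tau - 2.0 * corr
        d = np.maximum(d, 0.0)
        # cumulative-mean normalization
        dprime = np.ones_like(d)
        running = np.cumsum(d[1:])
        dprime[1:] = d[1:] * np.arange(1, d.size) / np.maximum(running, _EPS)

        tau = _pick_dip(dprime, tau_min, tau_max, threshold)
        tau_refined = _parabolic(dprime, tau)
        f0s[i] = sr / tau_refined
        aps[i] = float(np.clip(dprime[tau], 0.0, 1.0))
    return f0s, aps


def _pick_dip(dprime: np.ndarray, tau_min: int, tau_max: int, threshold: float) -> int:
    tau = tau_min
    while tau <= tau_max:
        if dprime[tau] < threshold:
            while tau + 1 <= tau_max and dprime[tau + 1] < dprime[tau]:
                tau += 1
            return tau
        tau += 1
    return int(tau_min + np.argmin(dprime[tau_min : tau_max + 1]))


def _parabolic(d: np.ndarray, tau: int) -> float:
    if 0 < tau < d.size - 1:
        a, b, c = d[tau - 1], d[tau], d[tau + 1]
        denom = a - 2 * b + c
        if abs(denom) > _EPS:
            shift = 0.5 * (a - c) / denom
            if abs(shift) < 1:
                return tau + shift
    return float(tau)


# ---------------------------------------------------------------------------
# Temporal envelope features
# ---------------------------------------------------------------------------

def energy_envelope(clip: AudioClip, frame: float = 0.010,
                    hop: float = 0.0025) -> tuple[np.ndarray, np.ndarray]:
    """Short-frame RMS envelope and frame-center times."""
    x = np.asarray(clip.samples, dtype=float)
    n, h = round(frame * clip.sample_rate), round(hop * clip.sample_rate)
    if x.size < n:
        raise FeatureError("clip shorter than one envelope frame")
    starts = np.arange(0, x.size - n + 1, h)
    env = np.sqrt(np.array([np.mean(x[s : s + n] ** 2) for s in starts]))
    times = (starts + n / 2) / clip.sample_rate
    return env, times


def temporal_features(clip: AudioClip) -> tuple[float, float]:
    """(log-attack-time, temporal centroid).

    Attack onset/end are the first crossings of 10% and 90% of the
    envelope maximum; log-attack-time is log10 of their time difference
    (floored at one envelope hop).  Temporal centroid is the center of
    gravity of the RMS envelope.
    """
    env, times = energy_envelope(clip)
    peak = env.max()
    if peak == 0:
        raise FeatureError("silent clip")
    t10 = times[np.flatnonzero(env >= 0.1 * peak)[0]]
    t90 = times[np.flatnonzero(env >= 0.9 * peak)[0]]
    hop = times[1] - times[0] if times.size > 1 else 0.0025
    lat = math.log10(max(t90 - t10, hop))
    centroid = float((times * env).sum() / env.sum())
    return lat, centroid


# ---------------------------------------------------------------------------
# Modulation power spectrum
# ---------------------------------------------------------------------------

@dataclass
class ModulationPowerSpectrum:
    power: np.ndarray           # spectral-modulation x temporal-modulation
    spectral_axis: np.ndarray   # cyc/kHz, >= 0 after folding
    temporal_axis: np.ndarray   # Hz, symmetric about 0

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise FeatureError("MPS power must be non-negative")


#: printed modulation-axis limits that fix the spectrogram sampling
MPS_TEMPORAL_MAX_HZ = 47.92
MPS_SPECTRAL_MAX_CYC_PER_KHZ = 31.24


def modulation_power_spectrum(
    clip: AudioClip,
    dynamic_range_db: float = 50.0,
    temporal_max_hz: float = MPS_TEMPORAL_MAX_HZ,
    spectral_max_cyc_per_khz: float = MPS_SPECTRAL_MAX_CYC_PER_KHZ,
) -> ModulationPowerSpectrum:
    """2-D FFT of a Gaussian-window log-magnitude spectrogram.

    Spectrogram hop and frequency-bin spacing are chosen so the
    modulation-domain Nyquist limits equal the requested axis maxima
    (hop = 1/(2*temporal_max); bin spacing = 1/(2*spectral_max)); the
    Gaussian window sigma equals the hop.  The log spectrogram is clipped
    to ``dynamic_range_db`` below its maximum before transforming; the
    spectral-modulation axis is folded to >= 0 (Hermitian symmetry of the
    real spectrogram's 2-D transform).
    """
    sr = clip.sample_rate
    hop_s = 1.0 / (2.0 * temporal_max_hz)
    df = 1.0 / (2.0 * spectral_max_cyc_per_khz / 1000.0)  # Hz between bins
    hop = max(1, round(hop_s * sr))
    nfft = int(round(sr / df))
    sigma = float(hop)
    win_len = min(nfft, int(6 * sigma) | 1)
    win = signal.windows.gaussian(win_len, sigma)
    _, _, S = signal.stft(
        np.asarray(clip.samples, dtype=float), fs=sr, window=win,
        nperseg=win_len, noverlap=win_len - hop, nfft=nfft, boundary="zeros",
    )
    logS = 20.0 * np.log10(np.abs(S) + _EPS)
    logS = np.maximum(logS, logS.max() - dynamic_range_db)
    F = np.fft.fft2(logS)
    power = np.abs(F) ** 2
    n_freq, n_time = logS.shape
    spec_axis = np.fft.fftfreq(n_freq, d=sr / nfft) * 1000.0   # cyc/kHz
    temp_axis = np.fft.fftfreq(n_time, d=hop / sr)             # Hz
    # fold: keep non-negative spectral modulations, full temporal axis
    keep = spec_axis >= 0
    order = np.argsort(temp_axis)
    return ModulationPowerSpectrum(
        power[keep][:, order], spec_axis[keep], temp_axis[order]
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class FeatureRow:
    """All descriptors of one standardized clip."""

    label: str
    scalars: dict = field(default_factory=dict)
    cochleagram_median: np.ndarray | None = None
    cochleagram_iqr: np.ndarray | None = None
    mps: ModulationPowerSpectrum | None = None


def _iqr(v: np.ndarray) -> float:
    v = v[~np.isnan(v)]
    return float(np.percentile(v, 75) - np.percentile(v, 25))


def _median(v: np.ndarray) -> float:
    return float(np.nanmedian(v))


def summarize(clip: AudioClip, frame_rate: float = 200.0) -> FeatureRow:
    """Assemble the full FeatureRow for one standardized clip.

    Frame-wise features are summarized by median (and IQR where retained);
    degenerate (silent or zero-variance) frames are excluded.
    """
    if np.max(np.abs(clip.samples), initial=0.0) == 0:
        raise FeatureError(f"silent clip {clip.label!r}")
    coch = erb_cochleagram(clip, frame_rate=frame_rate)
    centroid, flatness = spectral_frame_stats(coch)
    variability = spectral_variability(coch)
    f0, aperiodicity = yin_track(clip)
    lat, tc = temporal_features(clip)
    scalars = {
        "log_attack_time": lat,
        "temporal_centroid": tc,
        "spectral_centroid_median": _median(centroid),
        "spectral_centroid_iqr": _iqr(centroid),
        "spectral_flatness_median": _median(flatness),
        "spectral_flatness_iqr": _iqr(flatness),
        "spectral_variability_median": _median(variability),
        "aperiodicity_median": _median(aperiodicity),
        "f0_median": _median(f0),
        "f0_iqr": _iqr(f0),
    }
    return FeatureRow(
        label=clip.label,
        scalars=scalars,
        cochleagram_median=np.median(coch.energy, axis=1),
        cochleagram_iqr=np.percentile(coch.energy, 75, axis=1)
        - np.percentile(coch.energy, 25, axis=1),
        mps=modulation_power_spectrum(clip),
    )


@dataclass
class FeatureTable:
    """Per-item feature summaries: scalar DataFrame + aligned vector arrays.

    ``vectors['mps']`` stores the flattened dB-scale modulation power per
    item (the representation used for Euclidean distances).
    """

    scalars: pd.DataFrame                 # index = item labels
    vectors: dict[str, np.ndarray]        # name -> (n_items, dim)
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def items(self) -> list[str]:
        return list(self.scalars.index)

    def feature_values(self, name: str) -> np.ndarray:
        """Values of one feature, (n_items,) scalar or (n_items, dim) vector."""
        if name in self.scalars.columns:
            return self.scalars[name].to_numpy()
        if name in self.vectors:
            return self.vectors[name]
        raise FeatureError(f"unknown feature {name!r}")


def extract_features(clips, categories: dict[str, str] | None = None,
                     frame_rate: float = 200.0) -> FeatureTable:
    """Feature table for a list of standardized clips."""
    rows = [summarize(c, frame_rate=frame_rate) for c in clips]
    scalars = pd.DataFrame([r.scalars for r in rows], index=[r.label for r in rows])
    scalars = scalars[SCALAR_FEATURES]
    vectors = {
        "cochleagram_median": np.vstack([r.cochleagram_median for r in rows]),
        "cochleagram_iqr": np.vstack([r.cochleagram_iqr for r in rows]),
        "mps": np.vstack([
            10.0 * np.log10(r.mps.power.ravel() + _EPS) for r in rows
        ]),
    }
    cats = categories or {c.label: c.category for c in clips}
    return FeatureTable(scalars, vectors, cats)
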