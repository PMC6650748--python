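"""Stimulus standardization: onset detection, trimming, ramps, RMS leveling.

Every clip is trimmed to a fixed duration starting at its detected onset
(the first sample whose high-pass-filtered absolute amplitude strictly
exceeds 10% of the filtered maximum), given raised-cosine onset/offset
ramps, and normalized to a common RMS level.  The high-pass filter (zero
phase, 4th-order magnitude response) is used for onset detection only;
output samples always come from the unfiltered waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .stimuli import AudioClip


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    onset_fraction: float = 0.10
    highpass_cutoff: float = 20.0
    target_duration: float = 0.250
    ramp_duration: float = 0.005
    target_rms: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.onset_fraction < 1:
            raise PreprocessError("onset_fraction must lie in (0, 1)")
        if 2 * self.ramp_duration >= self.target_duration:
            raise PreprocessError("ramps must fit inside the target duration")


def to_mono(samples: np.ndarray) -> np.ndarray:
    """Stereo to mono by retaining channel 0 (the left channel)."""
    samples = np.asarray(samples, dtype=float)
    return samples[:, 0] if samples.ndim == 2 else samples


def _highpass(samples: np.ndarray, cutoff: float, sample_rate: int) -> np.ndarray:
    # 2nd-order design run forward-backward: zero phase, 4th-order magnitude
    sos = signal.butter(2, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, samples)


def detect_onset(clip: AudioClip, config: PreprocessConfig | None = None) -> int:
    """Index of the first sample whose filtered |amplitude| strictly exceeds
    ``onset_fraction`` of the filtered maximum."""
    config = config or PreprocessConfig()
    x = to_mono(clip.samples)
    if x.size == 0 or np.max(np.abs(x)) == 0:
        raise PreprocessError(f"silent clip {clip.label!r}")
    filtered = np.abs(_highpass(x, config.highpass_cutoff, clip.sample_rate))
    threshold = config.onset_fraction * filtered.max()
    idx = np.flatnonzero(filtered > threshold)
    if idx.size == 0:  # cannot happen: the maximum itself exceeds the fraction
        raise PreprocessError(f"no onset found in {clip.label!r}")
    return int(idx[0])


def cosine_ramps(n_samples: int, ramp_samples: int) -> np.ndarray:
    """Unit envelope with raised-cosine on/off ramps of ``ramp_samples``."""
    env = np.ones(n_samples)
    if ramp_samples > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_samples) / ramp_samples))
        env[:ramp_samples] = ramp
        env[-ramp_samples:] = ramp[::-1]
    return env


def standardize_clip(clip: AudioClip, config: PreprocessConfig | None = None) -> AudioClip:
    """Trim to ``target_duration`` from onset, ramp, and RMS-normalize."""
    config = config or PreprocessConfig()
    onset = detect_onset(clip, config)
    x = to_mono(clip.samples)
    n_out = round(config.target_duration * clip.sample_rate)
    if onset + n_out > x.size:
        raise PreprocessError(
            f"clip {clip.label!r}: only {x.size - onset} samples after onset, "
            f"need {n_out}"
        )
    out = x[onset : onset + n_out].copy()
    out *= cosine_ramps(n_out, round(config.ramp_duration * clip.sample_rate))
    rms = np.sqrt(np.mean(out**2))
    if rms == 0:
        raise PreprocessError(f"clip {clip.label!r} is silent after trimming")
    out *= config.target_rms / rms
    if np.max(np.abs(out)) > 1.0:  # guard the full-scale invariant
        out /= np.max(np.abs(out))
    return replace(clip, samples=out)


def standardize_set(clips, config: PreprocessConfig | None = None):
    """Standardize a collection of clips, preserving order."""
    config = config or PreprocessConfig()
    return [standardize_clip(c, config) for c in clips]
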