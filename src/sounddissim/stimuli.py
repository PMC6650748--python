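"""Synthetic 36-item natural-sound stimulus set.

The set mirrors the structure of a three-category natural-sound study:
12 vowel-like vocal sounds (6 simulated speakers x 2 vowels), 12 harmonic
instrument-like sounds (each renderable at 10 equal-tempered notes), and
12 noise-dominated environmental sounds spanning 6 excitation media
(air, liquid, deformation, impact, mechanical, movement).

Vocal fundamental frequencies are matched to the nearest note of the
12-tone equal-tempered scale (A4 = 440 Hz); instruments are rendered at
every matched vocal note plus the default note E3 used for
instrument-instrument and instrument-environmental pairings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

CATEGORIES = ("vocal", "instrument", "environmental")

# Pitch classes with flat spelling (matching the conventional note list
# for this stimulus design: Ab2, Bb2, ... rather than G#2, A#2).
_PITCH_CLASSES = ["C", "Db", "D", "Eb", "E", "F", "Gb", "G", "Ab", "A", "Bb", "B"]
_SHARP_ALIASES = {"C#": "Db", "D#": "Eb", "F#": "Gb", "G#": "Ab", "A#": "Bb"}

#: default note for instrument-instrument and instrument-environmental pairings
DEFAULT_NOTE = "E3"

ENVIRONMENTAL_MEDIA = ("air", "liquid", "deformation", "impact", "mechanical", "movement")


class StimulusError(ValueError):
    """Invalid stimulus specification or configuration."""


@dataclass
class AudioClip:
    """A labeled, categorized waveform.

    samples are full-scale amplitudes in [-1, 1]; ``nominal_f0`` may be
    absent only for environmental (noise-dominated) clips.
    """

    samples: np.ndarray
    sample_rate: int
    label: str
    category: str
    subcategory: str
    nominal_f0: float | None = None
    note_name: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise StimulusError("sample_rate must be positive")
        if self.category not in CATEGORIES:
            raise StimulusError(f"unknown category {self.category!r}")
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-9:
            raise StimulusError(f"clip {self.label!r} exceeds full scale")
        if self.nominal_f0 is None and self.category != "environmental":
            raise StimulusError(f"{self.category} clip {self.label!r} requires nominal_f0")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class StimulusSet:
    """36 base clips plus note-matched instrument renderings.

    ``note_table`` maps each vocal label to its matched equal-tempered
    note; ``renderings`` maps (instrument label, note) to the clip played
    at that note.  Base instrument clips are the ``default_note``
    renderings.
    """

    clips: list[AudioClip]
    note_table: dict[str, str]
    renderings: dict[tuple[str, str], AudioClip]
    default_note: str = DEFAULT_NOTE

    def by_category(self, category: str) -> list[AudioClip]:
        return [c for c in self.clips if c.category == category]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.clips]

    @property
    def categories(self) -> dict[str, str]:
        return {c.label: c.category for c in self.clips}

    @property
    def subcategories(self) -> dict[str, str]:
        return {c.label: c.subcategory for c in self.clips}


# ---------------------------------------------------------------------------
# Equal temperament
# ---------------------------------------------------------------------------

def note_to_frequency(note_name: str) -> float:
    """Frequency in Hz of an equal-tempered note (A4 = 440 Hz), A0–C8."""
    name = note_name.strip()
    if len(name) < 2:
        raise StimulusError(f"unknown note name {note_name!r}")
    pc, octave_str = name[:-1], name[-1]
    pc = pc[0].upper() + pc[1:].lower()
    pc = pc.replace("♭", "b").replace("♯", "#")
    pc = _SHARP_ALIASES.get(pc, pc)
    if pc not in _PITCH_CLASSES or not octave_str.isdigit():
        raise StimulusError(f"unknown note name {note_name!r}")
    octave = int(octave_str)
    midi = 12 * (octave + 1) + _PITCH_CLASSES.index(pc)
    if not 21 <= midi <= 108:  # A0 .. C8
        raise StimulusError(f"note {note_name!r} outside A0–C8")
    return 440.0 * 2.0 ** ((midi - 69) / 12.0)


def _midi_to_name(midi: int) -> str:
    return f"{_PITCH_CLASSES[midi % 12]}{midi // 12 - 1}"


def nearest_equal_tempered_note(f0: float) -> str:
    """Nearest equal-tempered note to ``f0`` by absolute Hz difference.

    Ties are broken toward the lower note.
    """
    if not f0 > 0:
        raise StimulusError("f0 must be positive")
    best_midi, best_err = None, math.inf
    for midi in range(21, 109):
        err = abs(440.0 * 2.0 ** ((midi - 69) / 12.0) - f0)
        if err < best_err - 1e-12:  # strict improvement; tie keeps lower note
            best_midi, best_err = midi, err
    return _midi_to_name(best_midi)


# ---------------------------------------------------------------------------
# Synthesis primitives
# ---------------------------------------------------------------------------

def _normalize_peak(x: np.ndarray, peak: float = 0.9) -> np.ndarray:
    m = np.max(np.abs(x))
    return x * (peak / m) if m > 0 else x


def _resonator_sos(freq: float, bw: float, sample_rate: int) -> np.ndarray:
    """Two-pole resonator (Klatt-style formant filter), unity peak gain."""
    r = math.exp(-math.pi * bw / sample_rate)
    theta = 2 * math.pi * freq / sample_rate
    a = [1.0, -2 * r * math.cos(theta), r * r]
    b = [1.0 - r]  # approximate unity gain at resonance
    return signal.tf2sos(b, a)


def _harmonic_phase(f0: float, n: int, sample_rate: int, jitter_sd: float, rng) -> np.ndarray:
    """Instantaneous phase of a harmonic source with slow F0 jitter."""
    if jitter_sd > 0:
        dev = rng.standard_normal(n)
        # low-pass the deviation so jitter varies over ~10 ms, not per sample
        sos = signal.butter(2, 100.0, fs=sample_rate, output="sos")
        dev = signal.sosfiltfilt(sos, dev)
        dev = dev / (np.std(dev) + 1e-12) * jitter_sd
    else:
        dev = np.zeros(n)
    inst_f = f0 * (1.0 + dev)
    return 2 * math.pi * np.cumsum(inst_f) / sample_rate


#: canonical two-formant presets (F1, F2) in Hz
VOWEL_FORMANTS = {"a": (710.0, 1100.0), "i": (280.0, 2250.0)}


def synth_vowel(
    f0: float,
    vowel: str,
    duration: float = 0.3,
    sample_rate: int = 44100,
    seed: int | np.random.Generator = 0,
    formant_scale: float = 1.0,
    spectral_tilt: float = 2.0,
    label: str | None = None,
) -> AudioClip:
    """Vowel-like clip: jittered harmonic source through a two-resonator cascade.

    ``spectral_tilt`` is the per-harmonic power-law rolloff exponent of the
    glottal source (amplitude of harmonic k proportional to k**-tilt);
    ``formant_scale`` scales both formants, individuating speakers by
    vocal-tract length.
    """
    if not 60.0 <= f0 <= 400.0:
        raise StimulusError("vowel f0 must lie in 60–400 Hz")
    if vowel not in VOWEL_FORMANTS:
        raise StimulusError(f"unknown vowel {vowel!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = round(duration * sample_rate)
    phase = _harmonic_phase(f0, n, sample_rate, jitter_sd=0.002, rng=rng)
    n_harm = max(1, int(5000.0 / f0))
    src = np.zeros(n)
    for k in range(1, n_harm + 1):
        src += k ** (-spectral_tilt) * np.sin(k * phase)
    f1, f2 = (f * formant_scale for f in VOWEL_FORMANTS[vowel])
    out = signal.sosfilt(_resonator_sos(f1, 90.0, sample_rate), src)
    out = signal.sosfilt(_resonator_sos(f2, 120.0, sample_rate), out)
    # gentle rise so onset detection has material to cut
    t = np.arange(n) / sample_rate
    out *= np.minimum(1.0, t / 0.02)
    return AudioClip(
        _normalize_peak(out), sample_rate, label or f"vowel_{vowel}_{f0:.0f}",
        "vocal", vowel, nominal_f0=f0, note_name=nearest_equal_tempered_note(f0),
    )


def synth_instrument(
    f0: float,
    attack: float = 20.0,
    brightness: float = 4.0,
    duration: float = 0.3,
    sample_rate: int = 44100,
    decay: float | None = None,
    label: str | None = None,
    subcategory: str = "instrument",
    note_name: str | None = None,
) -> AudioClip:
    """Harmonic instrument-like tone, deterministic given its arguments.

    Additive harmonics with exponential spectral rolloff (harmonic k has
    amplitude exp(-(k-1)/brightness)); the amplitude envelope rises
    linearly over ``attack`` milliseconds, then sustains, or decays
    exponentially with time constant ``decay`` seconds (plucked or struck
    excitation) when given.
    """
    if attack / 1000.0 >= duration:
        raise StimulusError("attack must be shorter than duration")
    n = round(duration * sample_rate)
    t = np.arange(n) / sample_rate
    n_harm = max(1, int(min(16000.0, sample_rate / 2 * 0.9) / f0))
    out = np.zeros(n)
    for k in range(1, n_harm + 1):
        out += math.exp(-(k - 1) / brightness) * np.sin(2 * math.pi * k * f0 * t)
    env = np.minimum(1.0, t / (attack / 1000.0))
    if decay is not None:
        env = env * np.exp(-np.maximum(0.0, t - attack / 1000.0) / decay)
    out *= env
    return AudioClip(
        _normalize_peak(out), sample_rate, label or f"instrument_{f0:.0f}",
        "instrument", subcategory, nominal_f0=f0,
        note_name=note_name or nearest_equal_tempered_note(f0),
    )


def synth_environmental(
    medium: str,
    duration: float = 0.3,
    sample_rate: int = 44100,
    seed: int | np.random.Generator = 0,
    variant: int = 0,
    label: str | None = None,
) -> AudioClip:
    """Noise-dominated clip following a per-medium excitation recipe.

    Recipes follow the everyday-sound media taxonomy: impact = decaying
    broadband burst; air = low-passed sustained noise; liquid = sparse
    decaying chirps over a noise bed; deformation = gated noise crackle;
    mechanical = amplitude-modulated noise; movement = band-passed noise
    under a slow random amplitude walk.  ``variant`` selects between the
    two tokens per medium (different filter/rate parameters).
    """
    if medium not in ENVIRONMENTAL_MEDIA:
        raise StimulusError(f"unknown medium {medium!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = round(duration * sample_rate)
    t = np.arange(n) / sample_rate
    noise = rng.standard_normal(n)

    if medium == "impact":
        tau = (0.03, 0.06)[variant % 2]
        out = noise * np.exp(-t / tau)
    elif medium == "air":
        cutoff = (900.0, 1800.0)[variant % 2]
        sos = signal.butter(4, cutoff, fs=sample_rate, output="sos")
        out = signal.sosfilt(sos, noise)
    elif medium == "liquid":
        bed = 0.08 * signal.sosfilt(
            signal.butter(2, [300, 3000], "bandpass", fs=sample_rate, output="sos"), noise
        )
        out = bed.copy()
        n_drops = (6, 10)[variant % 2]
        for d in range(n_drops):
            # first droplet lands early so the onset leaves a full
            # target-duration of material for trimming
            start = (rng.integers(0, int(0.02 * sample_rate)) if d == 0
                     else rng.integers(0, max(1, n - 800)))
            length = int(rng.integers(300, 800))
            tt = np.arange(length) / sample_rate
            fstart = rng.uniform(1500, 3500)
            # downward chirp from fstart to fstart/2 over the droplet
            sweep = np.sin(2 * math.pi * (fstart * tt - 0.25 * fstart * tt**2 / tt[-1]))
            out[start : start + length] += sweep * np.exp(-tt / 0.004)
    elif medium == "deformation":
        rate = (60.0, 120.0)[variant % 2]
        gate = (rng.random(n) < rate / sample_rate).astype(float)
        gate[rng.integers(0, int(0.01 * sample_rate))] = 1.0  # early crackle
        gate = np.convolve(gate, np.hanning(int(0.004 * sample_rate)), mode="same")
        out = noise * (0.15 + gate)
    elif medium == "mechanical":
        am_rate = (25.0, 50.0)[variant % 2]
        out = noise * (0.5 + 0.5 * np.sin(2 * math.pi * am_rate * t + rng.uniform(0, 2 * math.pi)))
    else:  # movement
        band = ((200.0, 1200.0), (500.0, 2500.0))[variant % 2]
        sos = signal.butter(2, band, "bandpass", fs=sample_rate, output="sos")
        walk = np.cumsum(rng.standard_normal(n))
        walk_sos = signal.butter(2, 8.0, fs=sample_rate, output="sos")
        walk = signal.sosfiltfilt(walk_sos, walk)
        walk = (walk - walk.min()) / (np.ptp(walk) + 1e-12)
        out = signal.sosfilt(sos, noise) * (0.3 + 0.7 * walk)

    return AudioClip(
        _normalize_peak(out), sample_rate, label or f"{medium}_{variant + 1}",
        "environmental", medium,
    )


# ---------------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------------

#: per speaker: (F0 of /a/, F0 of /i/, formant scale, glottal tilt).  F0s
#: span the 99.16–251.38 Hz vocal range and snap to the 9 matched notes
#: {G2, Ab2, A2, Bb2, B2, C3, Ab3, Bb3, B3} under nearest_equal_tempered_note.
DEFAULT_SPEAKERS = {
    "m1": (99.16, 104.9, 1.00, 2.2),
    "m2": (108.5, 110.9, 0.96, 2.0),
    "m3": (118.2, 121.8, 1.04, 2.4),
    "f1": (132.5, 124.5, 1.12, 1.8),
    "f2": (205.2, 208.9, 1.16, 1.9),
    "f3": (236.1, 251.38, 1.20, 2.1),
}

#: instrument name -> (attack ms, brightness, decay s or None, family)
DEFAULT_INSTRUMENTS = {
    "guitar": (3.0, 4.0, 0.30, "plucked_strings"),
    "piano": (4.0, 5.0, 0.40, "plucked_strings"),
    "harp": (3.0, 3.0, 0.35, "plucked_strings"),
    "cello_pizz": (4.0, 3.5, 0.30, "plucked_strings"),
    "contrabass_pizz": (5.0, 3.0, 0.25, "plucked_strings"),
    "cello_arco": (70.0, 7.0, None, "bowed_strings"),
    "contrabass_arco": (80.0, 6.0, None, "bowed_strings"),
    "bass_clarinet": (60.0, 2.5, None, "woodwinds"),
    "bassoon": (50.0, 5.0, None, "woodwinds"),
    "french_horn": (40.0, 4.5, None, "brass"),
    "trombone": (45.0, 6.0, None, "brass"),
    "marimba": (2.0, 1.5, 0.15, "percussion"),
}

#: 12 environmental tokens: 2 per excitation medium
DEFAULT_ENVIRONMENTAL = [(m, v) for m in ENVIRONMENTAL_MEDIA for v in (0, 1)]


@dataclass
class SynthConfig:
    """Configuration of the default synthetic study stimulus set."""

    speakers: dict = field(default_factory=lambda: dict(DEFAULT_SPEAKERS))
    vowels: tuple = ("a", "i")
    instruments: dict = field(default_factory=lambda: dict(DEFAULT_INSTRUMENTS))
    environmental: list = field(default_factory=lambda: list(DEFAULT_ENVIRONMENTAL))
    sample_rate: int = 44100
    duration: float = 0.3
    default_note: str = DEFAULT_NOTE


def build_stimulus_set(config: SynthConfig | None = None, seed: int = 0) -> StimulusSet:
    """Build the 36-item set plus all note-matched instrument renderings.

    Base instrument clips are rendered at the default note (E3); each
    instrument is additionally rendered at every matched vocal note, so
    each instrument exists at 10 unique notes under the default config.
    """
    config = config or SynthConfig()
    if len(config.speakers) != 6 or len(config.vowels) != 2:
        raise StimulusError("config must list 6 speakers x 2 vowels")
    if len(config.instruments) != 12:
        raise StimulusError("config must list 12 instruments")
    if len(config.environmental) != 12:
        raise StimulusError("config must list 12 environmental tokens")

    ss = np.random.SeedSequence([seed, 0x5D15])
    streams = iter(ss.spawn(64))

    clips: list[AudioClip] = []
    note_table: dict[str, str] = {}

    for name, (f0_a, f0_i, fscale, tilt) in config.speakers.items():
        for vowel, f0 in zip(config.vowels, (f0_a, f0_i)):
            label = f"{name}_{vowel}"
            clip = synth_vowel(
                f0, vowel, config.duration, config.sample_rate,
                seed=np.random.default_rng(next(streams)),
                formant_scale=fscale, spectral_tilt=tilt, label=label,
            )
            clips.append(clip)
            note_table[label] = clip.note_name

    notes = sorted(set(note_table.values()) | {config.default_note},
                   key=note_to_frequency)
    renderings: dict[tuple[str, str], AudioClip] = {}
    for name, (attack, brightness, decay, family) in config.instruments.items():
        for note in notes:
            renderings[(name, note)] = synth_instrument(
                note_to_frequency(note), attack, brightness,
                config.duration, config.sample_rate, decay=decay,
                label=name, subcategory=family, note_name=note,
            )
        clips.append(renderings[(name, config.default_note)])

    for medium, variant in config.environmental:
        clips.append(
            synth_environmental(
                medium, config.duration, config.sample_rate,
                seed=np.random.default_rng(next(streams)), variant=variant,
            )
        )

    return StimulusSet(clips, note_table, renderings, config.default_note)
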