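"""WAV, manifest and table serialization."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .dissimilarity import DissimMatrix, RatingTable
from .stimuli import AudioClip, StimulusSet


def save_wav(clip: AudioClip, path, dtype: str = "float32") -> None:
    """Write a clip as PCM-16 or float-32 WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "float32":
        wavfile.write(path, clip.sample_rate, clip.samples.astype(np.float32))
    elif dtype == "pcm16":
        wavfile.write(path, clip.sample_rate,
                      np.round(clip.samples * 32767).astype(np.int16))
    else:
        raise ValueError(f"unknown dtype {dtype!r}")


def load_wav(path, label: str | None = None, category: str = "environmental",
             subcategory: str = "unknown", **kwargs) -> AudioClip:
    """Read a WAV file as an AudioClip (stereo kept as 2-D; amplitudes
    scaled to full scale -1..1 for integer formats)."""
    path = Path(path)
    sr, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return AudioClip(data, sr, label or path.stem, category, subcategory, **kwargs)


def write_stimulus_set(stimulus_set: StimulusSet, outdir,
                       include_renderings: bool = False) -> pd.DataFrame:
    """Write per-clip WAVs plus a manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    rows = []
    for clip in stimulus_set.clips:
        fname = f"{clip.label}.wav"
        save_wav(clip, outdir / fname)
        rows.append((clip.label, clip.category, clip.subcategory,
                     clip.note_name or "", clip.nominal_f0 or "", fname))
    if include_renderings:
        for (name, note), clip in stimulus_set.renderings.items():
            fname = f"renderings/{name}_{note}.wav"
            save_wav(clip, outdir / fname)
            rows.append((clip.label, clip.category, clip.subcategory,
                         note, clip.nominal_f0 or "", fname))
    manifest = pd.DataFrame(rows, columns=["label", "category", "subcategory",
                                           "note", "f0", "filename"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def write_dissim_matrix(matrix: DissimMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index_label="item")


def read_dissim_matrix(path, kind: str = "behavioral_rating",
                       categories: dict | None = None) -> DissimMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimMatrix(list(df.index), df.to_numpy(), kind, categories or {})


def write_rating_table(table: RatingTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_rating_table(path) -> RatingTable:
    return RatingTable(pd.read_csv(path))
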