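"""Reading and writing the pipeline's on-disk formats.

WAV files go through :mod:`scipy.io.wavfile` (PCM16 or float32).
Syllable segmentations use a tab-separated sidecar with one row per
syllable: ``syllable_index<TAB>start_sample<TAB>end_sample`` (0-based,
half-open).  Score tables are plain CSV handled by pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .audio import AudioSignal, SyllableSegmentation

__all__ = [
    "read_wav",
    "write_wav",
    "read_segmentation",
    "write_segmentation",
    "read_scores",
    "write_scores",
]

SCORE_COLUMNS = [
    "subject",
    "compression_ratio",
    "spectral_content",
    "silence_added",
    "measurement",
    "n_keywords",
    "n_correct",
]


def write_wav(path: str | Path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write a mono WAV file.

    ``subtype`` is ``"float32"`` (default, lossless for our amplitudes)
    or ``"pcm16"``.
    """
    if subtype == "float32":
        wavfile.write(path, signal.sample_rate, signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        scaled = np.clip(np.round(signal.samples * 32767.0), -32768, 32767)
        wavfile.write(path, signal.sample_rate, scaled.astype(np.int16))
    else:
        raise ValueError(f"unknown subtype {subtype!r}; use 'float32' or 'pcm16'")


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono WAV file into an :class:`AudioSignal`.

    Integer PCM is rescaled to [-1, 1]; multichannel input is rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data / 32767.0
    elif data.dtype == np.int32:
        samples = data / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        samples = data.astype(np.float64)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioSignal(samples, int(rate))


def write_segmentation(path: str | Path, seg: SyllableSegmentation) -> None:
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(seg):
            fh.write(f"{i}\t{a}\t{b}\n")


def read_segmentation(path: str | Path) -> SyllableSegmentation:
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            _, a, b = line.split("\t")
            intervals.append((int(a), int(b)))
    return SyllableSegmentation(intervals)


def write_scores(path: str | Path, table: pd.DataFrame) -> None:
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    table.to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: score table missing columns: {missing}")
    # Recompute derived columns so a hand-edited CSV stays internally consistent.
    from .stats import rau

    table["percent"] = 100.0 * table["n_correct"] / table["n_keywords"]
    table["rau"] = [rau(c, n) for c, n in zip(table["n_correct"], table["n_keywords"])]
    return table
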