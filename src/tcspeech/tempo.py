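"""Uniform time-scale compression and syllabic-rate bookkeeping.

Compression shortens a waveform by a ratio CR = output/input duration
while leaving pitch and formants in place, so the long-term magnitude
spectrum is preserved and the modulation spectrum shifts up by 1/CR.
The study settings are CR = 0.4 (control) and CR = 0.166 (fast).

The time-scale modifier is a waveform-similarity overlap-add (WSOLA)
scheme: fixed synthesis hop, Hann windows, and a bounded search for the
analysis frame that best continues the previously written one.  It is a
documented equivalent of pitch-synchronous overlap-add for this
purpose — all contracts here are on duration, spectrum and envelope,
not on the sample-exact output of any particular implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .audio import AudioSignal, SyllableSegmentation

__all__ = [
    "CompressionRatio",
    "CR_CONTROL",
    "CR_FAST",
    "time_compress",
    "scale_segmentation",
    "syllabic_rate",
]


@dataclass(frozen=True)
class CompressionRatio:
    """Output duration divided by input duration, in (0, 1]."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.value <= 1.0:
            raise ValueError(
                f"compression ratio must lie in (0, 1] (compression only), got {self.value}"
            )

    def __float__(self) -> float:
        return float(self.value)


CR_CONTROL = CompressionRatio(0.4)
CR_FAST = CompressionRatio(0.166)


def _as_ratio(cr) -> float:
    if isinstance(cr, CompressionRatio):
        return cr.value
    cr = float(cr)
    CompressionRatio(cr)  # validates
    return cr


def time_compress(
    signal: AudioSignal,
    cr,
    frame_ms: float = 25.0,
    search_ms: float = 10.0,
) -> AudioSignal:
    """Uniformly time-compress ``signal`` by ratio ``cr`` (WSOLA).

    The output length is exactly ``round(len(signal) * cr)`` samples.
    ``frame_ms`` sets the analysis/synthesis frame (hop = frame/2) and
    ``search_ms`` the alignment search radius around the nominal
    analysis position.

    Raises
    ------
    ValueError
        For a ratio outside (0, 1] or an input shorter than two frames.
    """
    ratio = _as_ratio(cr)
    fs = signal.sample_rate
    x = signal.samples
    frame = int(round(frame_ms * 1e-3 * fs))
    frame += frame % 2  # even, so hop = frame/2 is exact
    if frame < 4:
        raise ValueError("frame length too short at this sample rate")
    if x.size < 2 * frame:
        raise ValueError(
            f"input of {x.size} samples is shorter than two frames ({2 * frame}); "
            "nothing to time-compress"
        )
    if ratio == 1.0:
        return signal.copy()

    hop = frame // 2
    radius = int(round(search_ms * 1e-3 * fs))
    n_in = x.size
    n_out = int(round(n_in * ratio))
    window = hann(frame, sym=False)

    out = np.zeros(n_out + frame, dtype=np.float64)
    wsum = np.zeros_like(out)
    # Cumulative energy for O(1) candidate-norm lookups.
    csum = np.concatenate(([0.0], np.cumsum(x * x)))

    prev_start = 0
    k = 0
    while k * hop < n_out:
        pos = k * hop
        nominal = int(round(pos / ratio))
        nominal = min(max(nominal, 0), n_in - frame)
        if k == 0:
            start = 0
        else:
            nat = min(prev_start + hop, n_in - frame)
            template = x[nat : nat + frame]
            lo = max(0, nominal - radius)
            hi = min(n_in - frame, nominal + radius)
            if hi <= lo:
                start = nominal
            else:
                segment = x[lo : hi + frame]
                corr = np.correlate(segment, template, mode="valid")
                norms = np.sqrt(csum[lo + frame : hi + frame + 1] - csum[lo : hi + 1])
                score = corr / (norms + 1e-12)
                # Prefer the nominal position among near-ties.
                offsets = np.abs(np.arange(lo, hi + 1) - nominal)
                score -= 1e-6 * offsets / max(radius, 1)
                start = lo + int(np.argmax(score))
        out[pos : pos + frame] += x[start : start + frame] * window
        wsum[pos : pos + frame] += window
        prev_start = start
        k += 1

    good = wsum > 1e-3
    out[good] /= wsum[good]
    out = out[:n_out]
    peak = np.max(np.abs(out)) if out.size else 0.0
    if peak > 1.0:  # rare constructive overlap at splices
        out *= 0.999 / peak
    return AudioSignal(out, fs)


def scale_segmentation(seg: SyllableSegmentation, cr) -> SyllableSegmentation:
    """Map syllable boundaries through uniform compression.

    Each index is multiplied by the ratio and rounded; ordering,
    disjointness and non-emptiness are preserved by construction.
    """
    ratio = _as_ratio(cr)
    intervals: list[tuple[int, int]] = []
    prev_end = 0
    for a, b in seg:
        na = max(int(round(a * ratio)), prev_end)
        nb = max(int(round(b * ratio)), na + 1)
        intervals.append((na, nb))
        prev_end = nb
    return SyllableSegmentation(intervals)


def syllabic_rate(seg: SyllableSegmentation, duration: float) -> float:
    """Syllable count divided by duration, in syllables per second."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if seg.n_syllables == 0:
        warnings.warn("empty segmentation: syllabic rate is 0", stacklevel=2)
        return 0.0
    return seg.n_syllables / duration
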