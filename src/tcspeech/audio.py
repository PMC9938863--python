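"""Core containers for the stimulus pipeline.

Every DSP stage consumes and produces :class:`AudioSignal` objects, and
syllable bookkeeping travels alongside as :class:`SyllableSegmentation`
(ordered, non-overlapping half-open sample-index intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AudioSignal", "SyllableSegmentation"]

# Peak tolerance: float round-off from filtering/overlap-add, not clipping.
_PEAK_TOL = 1e-9


@dataclass
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples
        Amplitude values in ``[-1, 1]``, stored as float64.
    sample_rate
        Sampling frequency in Hz. Downstream filter banks extend to
        7937.5 Hz, so rates of at least 16 kHz are expected in practice.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D (mono) sample array")
        if not isinstance(self.sample_rate, (int, np.integer)) or self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate!r}")
        self.sample_rate = int(self.sample_rate)
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + _PEAK_TOL:
            raise ValueError(
                f"peak amplitude {np.max(np.abs(self.samples)):.6f} exceeds full scale"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        """Root-mean-square amplitude (linear, full scale = 1)."""
        if not self.samples.size:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    def rms_db(self) -> float:
        """RMS level in dB re full scale."""
        r = self.rms()
        if r <= 0.0:
            return -np.inf
        return float(20.0 * np.log10(r))

    def copy(self) -> "AudioSignal":
        return AudioSignal(self.samples.copy(), self.sample_rate)


@dataclass
class SyllableSegmentation:
    """Ordered syllable intervals for one sentence.

    Intervals are 0-based half-open ``(start, end)`` sample indices,
    sorted, pairwise disjoint and each non-empty.
    """

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = [(int(a), int(b)) for a, b in self.intervals]
        prev_end = None
        for i, (a, b) in enumerate(self.intervals):
            if a < 0 or b <= a:
                raise ValueError(f"interval {i} = ({a}, {b}) is empty or negative")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"interval {i} overlaps or precedes its predecessor")
            prev_end = b

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def n_syllables(self) -> int:
        return len(self.intervals)

    @property
    def starts(self) -> np.ndarray:
        return np.array([a for a, _ in self.intervals], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([b for _, b in self.intervals], dtype=np.int64)

    def tiled(self, total_samples: int) -> "SyllableSegmentation":
        """Extend each interval to the start of the next, tiling the signal.

        Useful when each syllable should own its trailing gap (as manual
        segmentation of connected speech does), so that silence
        insertion preserves the full syllabic period.
        """
        if not self.intervals:
            return SyllableSegmentation([])
        starts = [a for a, _ in self.intervals]
        ends = starts[1:] + [max(int(total_samples), self.intervals[-1][1])]
        return SyllableSegmentation(list(zip(starts, ends)))

    def validate_for(self, signal: AudioSignal) -> None:
        """Raise if any interval extends beyond ``signal``."""
        if self.intervals and self.intervals[-1][1] > len(signal):
            raise ValueError(
                f"segmentation end {self.intervals[-1][1]} beyond signal length {len(signal)}"
            )
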