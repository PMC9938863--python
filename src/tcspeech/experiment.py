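"""Experimental design and batch stimulus rendering.

The design crosses speech rate (original, CR 0.4, CR 0.166), spectral
content (original, 16-channel, 8-channel noise vocoded) and syllabic
repackaging (100 ms silences), with vocoding and repackaging applied
only to the fastest rate.  Every time-compressed condition is assessed
twice (test and retest blocks); the untouched original sentence is
assessed once, giving 8 unique conditions and 15 assessments per
participant, each with a unique sentence list.

Free-field presentation level (65 dB SPL, A-weighted) has no meaning
inside a file, so levels are set to a configurable A-weighted digital
reference (default -25 dB FS); relative levels across conditions are
preserved, which is all the downstream computation needs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio import AudioSignal
from .repackage import insert_silences
from .synth import SyntheticSentence
from .tempo import scale_segmentation, syllabic_rate, time_compress
from .vocoder import VocoderSpec, vocode

__all__ = [
    "Condition",
    "Assignment",
    "DEFAULT_LIST_POOL",
    "DEFAULT_TARGET_DBFS",
    "SILENCE_S",
    "build_condition_matrix",
    "assign_lists",
    "a_weighted_rms_db",
    "set_level",
    "render_all",
]

SPEECH_RATES = (1.0, 0.4, 0.166)
SPECTRAL_CONTENTS = ("original", "8ch", "16ch")
MEASUREMENTS = ("test", "retest")

#: Duration of the silence inserted after each syllable (seconds).
SILENCE_S = 0.1

#: Digital proxy for the 65 dB SPL presentation level.
DEFAULT_TARGET_DBFS = -25.0

#: The 15 corpus list ids preselected for the experiment (6 repackaged
#: lists + 9 non-repackaged lists; a 16th list serves as spare).
DEFAULT_LIST_POOL = (6, 8, 9, 10, 13, 16, 18, 21, 22, 23, 25, 28, 30, 33, 35)


@dataclass(frozen=True)
class Condition:
    """One cell of the design matrix."""

    compression_ratio: float
    spectral_content: str
    silence_added: bool
    measurement: str = "test"

    def __post_init__(self) -> None:
        if float(self.compression_ratio) not in SPEECH_RATES:
            raise ValueError(f"compression_ratio must be one of {SPEECH_RATES}")
        if self.spectral_content not in SPECTRAL_CONTENTS:
            raise ValueError(f"spectral_content must be one of {SPECTRAL_CONTENTS}")
        if self.measurement not in MEASUREMENTS:
            raise ValueError(f"measurement must be one of {MEASUREMENTS}")
        if self.compression_ratio != 0.166 and (
            self.spectral_content != "original" or self.silence_added
        ):
            raise ValueError("vocoding and silence insertion apply only to CR 0.166")
        if self.compression_ratio == 1.0 and self.measurement == "retest":
            raise ValueError("the original-rate condition is assessed once (test only)")

    @property
    def is_time_compressed(self) -> bool:
        return self.compression_ratio < 1.0

    def slug(self) -> str:
        cr = {1.0: "orig", 0.4: "cr040", 0.166: "cr0166"}[float(self.compression_ratio)]
        sil = "sil" if self.silence_added else "nosil"
        return f"{cr}_{self.spectral_content}_{sil}_{self.measurement}"


def build_condition_matrix() -> list[Condition]:
    """The full assessment schedule: 8 unique conditions, 15 assessments.

    Unique rows: original speech; CR 0.4; and CR 0.166 crossed with
    three spectral contents and silence on/off.  Every time-compressed
    row is repeated as a retest; the original-rate row is not.
    """
    unique = [
        Condition(1.0, "original", False),
        Condition(0.4, "original", False),
    ]
    for silence in (False, True):
        for spectral in ("8ch", "16ch", "original"):
            unique.append(Condition(0.166, spectral, silence))
    retests = [
        Condition(c.compression_ratio, c.spectral_content, c.silence_added, "retest")
        for c in unique
        if c.is_time_compressed
    ]
    return unique + retests


@dataclass
class Assignment:
    """One participant's lists, block orders and test ear."""

    participant: int
    condition_lists: dict[Condition, int]
    test_order: list[Condition]
    retest_order: list[Condition]
    ear: str

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValueError("ear must be 'left' or 'right'")
        ids = list(self.condition_lists.values())
        if len(set(ids)) != len(ids):
            raise ValueError("each condition must map to a unique list")

    @property
    def conditions(self) -> list[Condition]:
        return self.test_order + self.retest_order


def assign_lists(
    n_participants: int,
    list_pool=DEFAULT_LIST_POOL,
    seed: int = 0,
) -> list[Assignment]:
    """Randomize lists, block orders and ears for a cohort.

    Every participant receives a unique list per assessed condition and
    independent pseudo-random presentation orders for the test and
    retest blocks; ears are balanced across the cohort (the odd
    participant, if any, is assigned at random).  Deterministic for a
    fixed seed.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    matrix = build_condition_matrix()
    pool = list(list_pool)
    if len(set(pool)) != len(pool):
        raise ValueError("list_pool must not contain duplicates")
    if len(pool) < len(matrix):
        raise ValueError(
            f"list pool of {len(pool)} cannot cover {len(matrix)} assessed conditions"
        )
    test_block = [c for c in matrix if c.measurement == "test"]
    retest_block = [c for c in matrix if c.measurement == "retest"]

    ss = np.random.SeedSequence(seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    ears = ["left", "right"] * (n_participants // 2)
    if n_participants % 2:
        ears.append(cohort_rng.choice(["left", "right"]))
    cohort_rng.shuffle(ears)

    assignments = []
    for pid, child in enumerate(ss.spawn(n_participants + 1)[1:]):
        rng = np.random.default_rng(child)
        lists = rng.choice(pool, size=len(matrix), replace=False)
        assignments.append(
            Assignment(
                participant=pid,
                condition_lists={c: int(l) for c, l in zip(matrix, lists)},
                test_order=[test_block[i] for i in rng.permutation(len(test_block))],
                retest_order=[retest_block[i] for i in rng.permutation(len(retest_block))],
                ear=ears[pid],
            )
        )
    return assignments


# ---------------------------------------------------------------------------
# A-weighted level scaling
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _a_weighting_sos(fs: int) -> np.ndarray:
    """Digital A-weighting filter (bilinear transform of the analog curve)."""
    two_pi = 2.0 * np.pi
    zeros = np.zeros(4)
    poles = -two_pi * np.array(
        [20.598997057568145, 20.598997057568145, 107.65264864304628,
         737.8622307362899, 12194.21714799801, 12194.21714799801]
    )
    zd, pdig, kd = sps.bilinear_zpk(zeros, poles, 1.0, fs)
    sos = sps.zpk2sos(zd, pdig, kd)
    # Normalize to unit gain at 1 kHz.
    _, h = sps.sosfreqz(sos, worN=[1000.0], fs=fs)
    sos[0, :3] /= np.abs(h[0])
    return sos


def a_weighted_rms_db(signal: AudioSignal) -> float:
    """A-weighted RMS level in dB re full scale."""
    y = sps.sosfilt(_a_weighting_sos(signal.sample_rate), signal.samples)
    r = float(np.sqrt(np.mean(y * y))) if y.size else 0.0
    if r <= 0.0:
        return -np.inf
    return 20.0 * float(np.log10(r))


def set_level(
    signal: AudioSignal,
    target_dbfs: float = DEFAULT_TARGET_DBFS,
) -> tuple[AudioSignal, float]:
    """Scale ``signal`` so its A-weighted RMS equals ``target_dbfs``.

    Returns the scaled signal and the applied linear gain.  Raises for
    silent input (undefined gain) or when the target would clip.
    """
    current = a_weighted_rms_db(signal)
    if not np.isfinite(current):
        raise ValueError("cannot set the level of a silent signal")
    gain = 10.0 ** ((target_dbfs - current) / 20.0)
    scaled = signal.samples * gain
    peak = float(np.max(np.abs(scaled)))
    if peak > 1.0:
        raise ValueError(
            f"target level {target_dbfs} dBFS would clip (peak {20 * np.log10(peak):.1f} dBFS); "
            "choose a lower target"
        )
    return AudioSignal(scaled, signal.sample_rate), float(gain)


# ---------------------------------------------------------------------------
# Batch rendering
# ---------------------------------------------------------------------------


def process_sentence(
    sentence: SyntheticSentence,
    condition: Condition,
    carrier_seed: int = 0,
    target_dbfs: float = DEFAULT_TARGET_DBFS,
    silence: float = SILENCE_S,
) -> tuple[AudioSignal, float, float]:
    """Run one sentence through compress -> repackage -> vocode -> level.

    Vocoding follows silence insertion (the inserted zeros stay silent
    under a level-matched vocoder either way).  Returns the processed
    signal, the realized syllabic rate from the ground-truth
    segmentation, and the level gain.
    """
    audio = sentence.audio
    seg = sentence.syllables
    if condition.is_time_compressed:
        audio = time_compress(audio, condition.compression_ratio)
        seg = scale_segmentation(seg, condition.compression_ratio)
    if condition.silence_added:
        # Segmentation partitions the whole sentence (each syllable owns
        # its trailing gap), as manual syllable segmentation does.
        audio, seg = insert_silences(audio, seg.tiled(len(audio)), silence)
    if condition.spectral_content != "original":
        n_ch = 8 if condition.spectral_content == "8ch" else 16
        audio = vocode(audio, VocoderSpec.preset(n_ch, carrier_seed=carrier_seed))
    rate = syllabic_rate(seg, audio.duration)
    audio, gain = set_level(audio, target_dbfs)
    return audio, rate, gain


def render_all(
    corpus: dict[int, list[SyntheticSentence]],
    assignments: list[Assignment],
    out_dir: str | Path,
    seed: int = 0,
    target_dbfs: float = DEFAULT_TARGET_DBFS,
    silence: float = SILENCE_S,
    write_audio: bool = True,
) -> pd.DataFrame:
    """Render every assigned condition to WAV files plus a manifest.

    ``corpus`` maps list ids to sentence lists (as from
    :func:`tcspeech.synth.generate_list`).  The manifest CSV records
    participant, condition, list, file, realized syllabic rate and the
    applied level gain; the run is idempotent for a fixed seed.
    """
    from . import io as tio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for asg in assignments:
        for cond in asg.conditions:
            list_id = asg.condition_lists[cond]
            if list_id not in corpus:
                raise KeyError(f"corpus is missing list {list_id}")
            for s_idx, sentence in enumerate(corpus[list_id]):
                # Stable per-stimulus carrier seed below 2**31 (crc32 is
                # process-independent, unlike hash()).
                cond_key = zlib.crc32(cond.slug().encode())
                carrier_seed = int(
                    np.random.SeedSequence(
                        [seed, asg.participant, cond_key, s_idx]
                    ).generate_state(1)[0]
                    % 2**31
                )
                audio, rate, gain = process_sentence(
                    sentence, cond, carrier_seed=carrier_seed,
                    target_dbfs=target_dbfs, silence=silence,
                )
                fname = f"p{asg.participant:02d}_{cond.slug()}_l{list_id:02d}_s{s_idx:02d}.wav"
                if write_audio:
                    tio.write_wav(out_dir / fname, audio)
                rows.append(
                    {
                        "participant": asg.participant,
                        "ear": asg.ear,
                        "compression_ratio": cond.compression_ratio,
                        "spectral_content": cond.spectral_content,
                        "silence_added": cond.silence_added,
                        "measurement": cond.measurement,
                        "list_id": list_id,
                        "sentence": s_idx,
                        "file": fname,
                        "realized_rate_sps": rate,
                        "level_gain": gain,
                        "target_dbfs": target_dbfs,
                        "seed": seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
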