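"""Shared fixtures: all audio material is generated at test time."""

from __future__ import annotations

import pytest

from tcspeech import generate_modulated_noise, generate_sentence

FS = 16000  # test-time sample rate: fastest rate that clears the 7937.5 Hz band edge


@pytest.fixture(scope="session")
def sentence():
    """A 9-syllable sentence at 2.5 sps with ground-truth boundaries."""
    return generate_sentence(9, nominal_rate=2.5, seed=2, sample_rate=FS)


@pytest.fixture(scope="session")
def fast_sentence(sentence):
    """The same sentence uniformly compressed to CR 0.166."""
    from tcspeech import scale_segmentation, time_compress

    return (
        time_compress(sentence.audio, 0.166),
        scale_segmentation(sentence.syllables, 0.166),
    )


@pytest.fixture(scope="session")
def modulated_noise():
    """Speech-shaped fixture for vocoder level/envelope measurements."""
    return generate_modulated_noise(seed=7, sample_rate=FS)
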