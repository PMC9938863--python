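# Methods

This note documents the models implemented in `tcspeech`, the defaults
and why they were chosen, the numerical decisions that were genuinely
open, and what the synthetic test bed can and cannot show.

## Signals and units

All audio is mono float64 in [−1, 1] (`AudioSignal`), default 44.1 kHz
(configurable; everything ≥ 16 kHz works, since the highest filter edge
is 7937.5 Hz).  Syllable bookkeeping uses half-open 0-based sample
intervals (`SyllableSegmentation`).  Rates are syllables per second
(sps = syllable count / duration); compression ratios are CR =
output/input duration, restricted to (0, 1].

## Synthetic corpus

`generate_sentence` builds a sentence as *n* syllable units at a nominal
rate *r*: each unit occupies a `duty` fraction (default 0.7) of the
syllabic period 1/*r* and consists of a harmonic source (f0 drawn
uniformly in 100–140 Hz per syllable, 1/k spectral tilt up to 5 kHz)
passed through two randomly drawn resonances (F1 ∈ 350–850 Hz,
F2 ∈ 1–2.4 kHz) and gated by a raised-cosine (Tukey, α = 0.5) amplitude
envelope.  Inter-syllable gaps carry noise at −60 dB relative to the
syllable peak, so automatic segmentation is non-trivial while ground
truth stays exact.  Synthesis fails deliberately when a syllable would
be shorter than four pitch periods.  The corpus statistics mirror the
emulated sentence-test material: ~9 syllables per sentence (SD 2.2,
clipped to 4–15), ~2.5 sps, lists of 10 sentences carrying 32–33
keywords (abstract tokens, partitioned at least one per sentence).

These signals are *not* speech: no phonology, no coarticulation, no
lexical content.  They are broadband, envelope-structured and
zero-crossing-rich, which is exactly what the compression, repackaging
and vocoding stages operate on — passing tests demonstrates correctness
of the signal processing and statistics, not intelligibility of any
real corpus.

`generate_modulated_noise` provides a second fixture — syllabically
gated noise band-limited to the analysis range (187.5–7937.5 Hz) — whose
long-term spectrum is flat across the vocoder bands.  Per-band level
and envelope measurements use it, because the sentence generator's
line spectrum leaves the top bands nearly empty.  Its default peak of
0.5 leaves headroom for the raised crest factor of vocoded output.

## Simulated listeners

`PsychometricModel` is a logistic model of per-keyword recall:

    logit p = intercept + rate_slope · rate_TC + channel_effect[spectral]
              + repackaging_gain[spectral] · silence + b_subject,
    b_subject ~ N(0, subject_sd²)

with keyword outcomes conditionally independent Bernoulli draws
(binomial counts per condition).  `rate_TC` is the post-compression
syllabic rate of the condition (2.5 / 6.6 / 15.6 sps for CR 1 / 0.4 /
0.166 — corpus-empirical values, not arithmetic identities).
Repackaging enters as an additive gain rather than a rate restoration:
empirically, repackaged 15.6 sps speech is far less intelligible than
genuine 6 sps speech, so modelling it as a return to the slow rate
would be wrong.

The `published_pattern` defaults (intercept 10.99, rate_slope −0.725
per sps, channel effects 0 / −1.41 / −2.62 logits for original / 16ch /
8ch, repackaging gains 0.95 / 0.93 / 0.74, subject_sd 0.75) are
calibrated so the *expected group means* reproduce the reported
pattern: ~100% at 6.6 sps, ~42% at 15.6 sps with the original spectrum,
~15% / ~5% for 16- and 8-channel vocoded fast speech, and repackaging
benefits of roughly 23 / 16 / 5 percentage points.  subject_sd = 0.75
gives a between-listener SD near 18–20 points at mid-scale.  Only group
means are calibrated; no claim is made about matching individual-level
variability or ranges.  The `null` model (all effects zero, p = 0.5)
drives the type-I-error check.

## Time compression

The time-scale modifier is WSOLA: 25 ms Hann frames, 50% synthesis
overlap, and a ±10 ms search that aligns each analysis frame with the
natural continuation of the previous one by normalized cross-
correlation (ties broken toward the nominal position).  The output
length is exactly `round(n · CR)`.  The published experiments used
pitch-synchronous overlap-add; WSOLA is a documented equivalent for
this purpose — both leave pitch and formants in place and shift the
modulation spectrum up by 1/CR — and every contract here (duration,
spectral centroid within ±5%, RMS within ±3 dB, ground-truth rate
bookkeeping) is algorithm-agnostic.  Pitch-marking parameters of the
original tool chain are not recoverable, so no sample-level equivalence
is claimed.

## Repackaging

Automatic segmentation computes a 10 ms RMS envelope, smooths it over
25 ms to suppress pitch-rate ripple, picks syllabic peaks (≥ 20% of the
global peak, prominence ≥ 10%, ≥ 30 ms apart), places boundaries at the
envelope minima between peaks and the −35 dB (re local peak) onset/offset
crossings, and snaps every edge to a zero-endpoint: the nearest sample
with |x| < 10⁻⁴ within ±5 ms, else the nearest sign change.  On the
synthetic corpus the boundaries land within ~10 ms of ground truth; the
ground-truth override means no repackaging result ever depends on the
detector.  If an expected syllable count is given, surplus valleys are
merged shallowest-first.

`insert_silences` extracts the intervals, appends `round(silence · fs)`
zero samples after each (exact length bookkeeping, zero-valued silence)
and concatenates in order; material outside the intervals is dropped.
Pipelines that should preserve the full syllabic period first call
`SyllableSegmentation.tiled`, which extends each syllable to the start
of the next — the analogue of manually partitioning a whole sentence
into syllables.  With tiling, the measured output rate matches the
bookkeeping formula 1/(1/rate + silence) to within rounding, e.g.
15.6 sps + 100 ms → 6.09… ≈ 6.1 sps.

## Noise vocoder

Analysis bands are contiguous between the printed edges (9 edges for 8
channels, 17 for 16), realized as cascaded fourth-order Butterworth
high-pass + low-pass at the band edges (stable for the narrow
low-frequency bands).  Envelopes are half-wave rectification followed
by a fourth-order 200 Hz low-pass, applied uniformly to all bands as
specified even where the band itself is narrower than 200 Hz.  Carriers
are independent per-channel white Gaussian noise streams spawned from
one seed, filtered through the identical band filters, modulated by the
envelope and rescaled so each channel's RMS equals its source band's
RMS.  Channels are summed; there is no global renormalization (the
per-channel match already ties output level to the input's in-band
level), only a recorded peak-protection scale if the sum would clip.
All filtering is causal single-pass, mirroring real-time practice.

Two measurement facts, verified against the analytic filter responses,
matter for interpretation:

* Re-analyzing the (exactly level-matched) output through the same
  causal 4th-order bank biases per-band RMS by up to ~1–2 dB — own-band
  energy is attenuated twice at the edges while neighbours leak in
  through the shallow skirts.  The 0.5 dB level contract therefore
  holds, and is tested, at the synthesis definition (channel RMS vs
  band RMS); re-analysis consistency is a separate, looser (≤ 2.5 dB)
  property.
* Raw 200 Hz envelopes of noise carriers contain intrinsic Rayleigh
  fluctuations that cap input/output envelope correlation near 0.5–0.8
  in narrow bands regardless of implementation.  Envelope fidelity
  (r ≥ 0.9 per channel) is therefore evaluated on syllabic-band
  envelopes: both envelopes smoothed by a 50 ms moving average, the
  modulation range that carries the rhythm information at issue.

Fine-structure destruction is checked directly: envelope-gated carriers
(band/envelope) of input and output correlate at |r| < 0.1.

## Experiment orchestration

The condition matrix crosses rate (original, CR 0.4, CR 0.166),
spectral content (original, 16ch, 8ch) and repackaging, with vocoding
and silences only at CR 0.166: 8 unique conditions, and every
time-compressed condition assessed twice (test and retest blocks) for
15 assessments per participant.  List assignment draws one unique list
per assessment from a 15-list pool per participant, with independent
seeded block orders and ears balanced across the cohort.

Free-field level (65 dB SPL, A-weighted) has no digital meaning, so
`set_level` scales to an A-weighted RMS of −25 dB FS by default — the
mapping preserves relative levels across conditions, which is all the
downstream computation uses.  The A-weighting filter is the bilinear
transform of the standard analog curve, normalized at 1 kHz; it tracks
the analog magnitude closely through the stimulus band (< 8 kHz) and
deviates only toward Nyquist.  Rendering order is compress → repackage
(on the tiled segmentation) → vocode → level; vocoding a signal with
zero-valued gaps leaves the gaps silent, so the order relative to
silence insertion is immaterial under a level-matched vocoder, and the
inserted gaps survive ≥ 40 dB below syllable level in the output.

## Statistics

Scores are analyzed as percent correct in the ANOVA and transformed to
RAU for normality checking and post-hocs, matching the study
convention.  The RAU transform uses the published N+1 closed form,
defined at both endpoints (0/33 → −15.0, 33/33 → 115.0, asymptotic
range ≈ [−23, 123]).

The repeated-measures ANOVA is computed from first principles for
balanced fully-within designs: inclusion–exclusion marginal-mean
projections give every effect's SS with the effect × subject
interaction as its error term; Greenhouse–Geisser ε and Mauchly's W
come from the covariance of orthonormal contrast scores; generalized
eta-squared follows the within-design partitioning (effect SS over
effect SS + subject SS + all error SS).  The GG-corrected p is reported
whenever an effect has more than one numerator df and Mauchly's test
rejects at 0.05 (or cannot be computed for rank reasons).  The
implementation agrees with pingouin (F, ε, η²G, corrected p) and
statsmodels AnovaRM (F, dfs) to ~10⁻⁹ in the test suite; a fully
independent implementation is kept as the oracle precisely because this
module is hand-built.  One analytic caveat: "corrected p ≥ uncorrected
p" is a theorem only for clearly super-unit F; near or below F = 1 the
df shrinkage can nudge p either way (both values being far from
significance), and the property tests restrict to F ≥ 2 accordingly.

The unpaired rate contrast uses Welch's t with Satterthwaite df (the
fractional-df convention of the reported analysis); a paired variant is
provided for within-subject contrasts and reports t = 0, p = 1 for
exactly identical samples.  Post-hocs are paired t-tests on per-subject
RAU means with Bonferroni multiplication capped at 1.  The repackaging
benefit is score(silence) − score(no silence) per subject and spectral
condition, averaged over test/retest, in both percent and RAU.

## Problem sizes and verification

The test suite and the acceptance script run at desk scale by choice:
16 kHz audio, 4–9-syllable sentences, 500 null cohorts and 200
patterned cohorts of 14 simulated listeners (the ANOVA is pure numpy,
~1 ms per cohort).  The acceptance script reports (t1) the repackaged
rate, from the bookkeeping formula with a full-pipeline cross-check
required to agree within 5%, and (t2) the mean empirical type-I error
(%) of the two main effects under the null simulator.

## Known limitations

* The corpus is a physical stand-in, not language; keyword scoring of
  synthetic sentences is bookkeeping over abstract tokens.
* The listener model has no within-sentence keyword correlation, no
  learning across blocks, and no lapse/guessing floor; its magnitudes
  are calibrated to group means only.
* WSOLA is contract-equivalent, not sample-equivalent, to
  pitch-synchronous methods; transient doubling/skipping can occur
  within a search radius at extreme compression.
* The vocoder's per-band level match is exact at synthesis; any
  re-analysis through the shallow 4th-order bank (including by this
  package's own `bandsplit`) carries the documented ~1–2 dB bias.
* Mauchly's test is undefined when subjects − 1 < contrast dimension;
  the GG correction is then applied unconditionally.
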