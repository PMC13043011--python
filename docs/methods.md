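# Methods

## Session model and temporal normalization

A session couples four streams: a facial-landmark stream (478 3-D points in
normalized image coordinates plus 52 ARKit-style blendshape activations per
frame), one mono audio track per participant response, a timed
agent/participant transcript (5 agent messages, 4 participant responses by
default), and clinical scores. Webcam capture rates are uncontrolled, so
raw landmark frames arrive at irregular 30–60 fps; analysis runs on a
uniform 30 fps grid obtained by linear interpolation between the two raw
frames bracketing each grid point. No extrapolation is performed: the grid
starts at the first raw timestamp and never extends past the last, because
interpolation between neighbors is undefined outside the observed range.
Audio is resampled to 22,050 Hz with a polyphase filter before any acoustic
analysis.

Clinical instruments: PHQ-9 total (0–27); Cancer Fatigue Scale as 15 items
split into physical (0–28), affective (0–16) and cognitive (0–16) subscales
whose sum is the total; Trail Making Test parts A and B as completion times
in seconds (longer = worse). The bundle format (JSON-lines landmarks, WAV
audio, JSON transcript/clinical/meta) is this package's own dialect; the
production serialization of such platforms is not public.

## Visual features (13)

Blink and yawn events are detected on blendshape activations with
hysteresis: a blink opens when mean(eyeBlinkLeft, eyeBlinkRight) crosses
θ_on = 0.5 and closes below θ_off = 0.3, with durations restricted to
66–500 ms (standard blink physiology; hysteresis prevents chatter at the
threshold). Yawns use jawOpen ≥ 0.6 sustained ≥ 1.5 s. Eyelid droop is the
mean eye-closure level over all frames *outside* blink events, so slow
baseline sag is separated from phasic blinks. Gaze components come from the
eye-look blendshape quadruples (rightward − leftward; upward − downward);
`gaze_x_dist`/`gaze_y_dist` are mean absolute deviations from center and
`gaze_down_dist` averages only the downward-positive component.
`affect_measure` is the mean temporal SD over the expression blendshapes
(all except the eye-look and eye-blink groups, which would inflate
"expressivity" with gaze and blink dynamics). `movement_speech_measure` is
the mean x–y landmark displacement per second restricted to
participant-speech segments; it is depth-independent by construction.
`eye_movements_per_s` counts gaze-velocity peaks above 3× the median
absolute velocity with ≥ 100 ms separation — a scale-free threshold robust
to per-user gaze range. All per-second rates use the interpolated stream
duration as denominator.

The production definitions of the expressivity and movement measures on the
platform that motivated this pipeline are proprietary; the definitions here
are declared substitutes with the same intent, not reconstructions.

## Acoustic features (28)

Frame analysis uses 2,048-sample windows with a 512-sample hop at 22,050 Hz.
Speech frames are those with RMS above −40 dB relative to the track's peak
frame RMS. Volume statistics (mean, SD, range, least-squares slope vs time)
are computed over speech frames; `ealvi` is defined here as the fraction of
speech frames whose RMS falls below 0.5× the median speech-frame RMS — a
low-volume-excursion index. This definition is a declared placeholder: the
name appears in the feature lists this pipeline mirrors without a published
definition.

Pitch is tracked per frame by normalized autocorrelation in a 75–500 Hz
search range with parabolic lag interpolation; a frame is voiced when its
periodicity strength exceeds 0.45. Two robustness devices are standard
practice and matter in testing: the signal is low-passed at 1.2 kHz before
autocorrelation (suppressing upper-formant ringing), and frames whose
estimate strays more than ~half an octave from the track median are
re-searched near the median (a minimal continuity constraint against octave
and formant-period errors). Pure tones are recovered within 0.2 Hz;
programmed linear glides within 5 % of the true slope.

Jitter and shimmer are computed from glottal-cycle peaks: waveform maxima
spaced by roughly one median-f0 period, refined to sub-sample position and
amplitude by parabolic interpolation. `jitter_local` is the mean absolute
consecutive-period difference over the mean period; `jitter_rap` uses the
deviation from the local 3-period average; `shimmer_local` and `shimmer_db`
are the analogous amplitude statistics. Inter-peak intervals outside
0.5–1.5× the nominal period (pauses, octave slips) are discarded, and
fewer than three valid periods yields a missing value. On strictly periodic
synthesis the measured jitter and shimmer are below 10⁻³; on the full
synthesizer with zero programmed perturbation the floor is ≈ 0.7 % jitter
and ≈ 1.6 % shimmer (placement quantization plus resonator ringing), well
below the programmed perturbations of interest. HNR is
10·log10(r/(1−r)) of the per-frame periodicity strength averaged over
voiced frames — a bounded periodicity index rather than a calibrated
harmonics-to-noise measurement.

Spectral centroid, bandwidth and rolloff (85 %) are per-frame statistics
averaged over speech frames. Spectral flatness is computed on the
across-frame *mean* power spectrum: the per-frame estimator is biased low
even for white noise (the geometric mean of exponential bins converges to
e^{−γ} ≈ 0.56 of the arithmetic mean), whereas the averaged-spectrum
definition approaches 1 for noise and 0 for tones, which is the behavior a
flatness feature should have. The epsilon guard is applied after
normalizing by the mean power so the statistic is amplitude-scale
invariant.

Formants are found per 25 ms frame by linear-prediction root-finding: audio
is decimated to 11,025 Hz and pre-emphasized (0.97), LPC coefficients of
order 12 are obtained by the autocorrelation method (Levinson recursion via
a Toeplitz solve), and roots with bandwidth < 400 Hz in 90 Hz–Nyquist are
kept. Order 12 matches the ~11 kHz analysis rate (≈ fs/1000 + 2); at
22,050 Hz it would undermodel the spectrum. Programmed resonances at
500/1,500/2,500 Hz are recovered within 5 %.

Pauses are maximal sub-threshold frame runs lasting ≥ 300 ms, excluding
leading and trailing silence. Zero pauses is a valid observation (rate 0);
the mean pause length is then undefined and reported as missing rather than
0, which would bias session means downward.

Session values are unweighted means over the (default 4) responses, with
missing response values excluded per feature. Undefined features are always
explicit missing markers (`nan`), never silent zeros, and are handled
pairwise downstream.

## Linguistic features (25)

Readability uses the published formulas: ARI = 4.71·(chars/words) +
0.5·(words/sentences) − 21.43; Flesch-Kincaid grade = 0.39·(words/sentences)
+ 11.8·(syllables/words) − 15.59; Gunning Fog = 0.4·[(words/sentences) +
100·(complex/words)] with "complex" = ≥ 3 syllables and no proper-noun
exclusion (transcribed speech lacks reliable casing). Syllables are counted
by vowel groups with a silent-final-e rule, so readability values are
bit-reproducible on fixture texts. Sentence segmentation is
punctuation-based; a response without terminal punctuation counts as one
sentence.

Fluency: word rate over summed participant speaking time; hesitations from
a filler lexicon {um, uh, er, ah, hmm, mhm, uhm}; transcript pauses as
inter-word gaps ≥ 0.5 s within a turn (missing when word timings are
absent); response latency as participant turn start minus preceding agent
turn end. Affect uses small shipped valence lexicons: per-response valence
is (positive − negative)/(positive + negative) keyword counts in [−1, 1],
and keyword proportions are counts over all participant tokens. Lexical
structure covers length, diversity, pronoun/negation/content-word usage and
syllable statistics. Ratio- and proportion-type features are computed over
the concatenated responses — except the type–token ratio, which is averaged
per response so that duplicating a response leaves it unchanged (the
concatenated TTR would halve under duplication, violating the intended
invariance). Genuinely per-response quantities (lengths, latencies,
sentiment, readability) are averaged across responses.

The registry realizes the named feature stems of the source feature library
at the printed 13/28/25 partition; where a stem maps to several standard
statistics (complexity → three indices; sentiment → mean and SD; latency →
mean and SD) the expansion is frozen so the counts stay meaningful.

## Synthetic cohort

Each participant draws three latent severities (depression, fatigue,
cognition) from a standard normal with correlations 0.5
(depression–fatigue) and 0.2 (each with cognition) — the symptom domains
overlap, as their behavioral signatures do. Across a participant's sessions
the latents wander as an AR(1) process (ρ = 0.7, innovation SD 0.3), which
is what makes the within-person risk score exercisable. A standardized
effect matrix maps latents into generator parameters:
`param = baseline + scale·(Σ β·latent + residual)`, residual SD chosen so
the parameter's variance stays near one scale unit; values are clipped into
physical ranges (f0 ∈ [75, 400] Hz, rates ≥ 0, proportions in [0, 1]) with
clips counted through the module logger. Default effect signs: depression
raises pitch and volume slope and lowers volume variability, sentence
length, long-word proportion and valence; fatigue does the same to the
voice, and additionally raises F2, eyelid droop and yawn rate and lowers
blink rate; cognition (longer TMT times) raises shimmer and response
latency. Effect magnitudes are calibration choices (default |β| = 0.3–0.5),
not estimates — no public effect sizes exist at this granularity.

Clinical scores are noisy monotone maps of the latents, rounded and clipped
to instrument ranges. Audio is synthesized source-filter style: a glottal
impulse train with per-cycle period (jitter) and amplitude (shimmer)
perturbations, smoothed by two leaky integrators to the ~−12 dB/oct tilt of
natural voicing, filtered through resonators at the formant targets, gated
by pause-parameter silences, and amplitude-shaped to the programmed RMS
level, slope and wander. Landmark streams advance with instantaneous frame
rate uniform in [30, 60] fps; blinks and yawns are Poisson processes
driving the corresponding blendshapes over the droop baseline; generated
values are quantized to 10⁻⁴ (far below tracker noise) to keep bundles
compact. Transcripts are assembled from word banks to hit the programmed
filler rate, sentence length, long-word proportion and valence, with word
timings consistent with the programmed speech rate, latency and pause
parameters.

The generator is deliberately *not* photorealistic: faces are a fixed
ring layout with rigid wander, language is bag-of-words, audio is a single
sustained vowel quality. Passing round-trip tests therefore shows that the
extractors recover the programmed physical parameters through the full
render-and-analyze path — not that they are validated on real faces or
speech.

Two observation levels: full bundle rendering (used for extraction
round-trip tests at small n) and a parameter-level feature table in which
each registry feature equals its generator-parameter counterpart plus
Gaussian measurement noise (0.3 parameter-SDs by default), with readability
indices derived from the sentence-length and long-word parameters through
the published formulas and unrelated features as pure baseline-plus-noise.
Statistical calibration experiments (type-I error, sign recovery) run on
this level: they test the inference stage, and waveform rendering at
thousands of sessions would add only runtime, not evidence.

## Correlation stage

Only the earliest session per participant enters (ties break to the lowest
session id). The outlier rule removes values more than 2 *sample* SDs from
the mean, in a single pass with mean and SD from the full sample — the rule
is not iterated, a choice documented because the source procedure is silent
on both points. Pearson r with the two-sided p from the t transform on
n−2 degrees of freedom; pairs are pairwise-complete and `n_used` is
reported per result. No multiple-testing correction is applied by default,
matching the uncorrected screening design; a Benjamini–Hochberg option
(within measure) exists but is off. TMT is correlated as part A, part B and
summed total. Under the zero-effect cohort (n = 40, 100 replicates,
52,800 tests) the significant fraction is 0.048 at α = 0.05.

## Risk score

Features significant for a measure's *total* score (not subscales) enter
the composite; correlation signs are frozen into the series metadata so
reported trajectories remain reproducible as correlations are re-estimated.
The sum is unweighted, following the plain description of the procedure
(|r|-weighting is a possible variant but was not chosen). A participant
needs ≥ 2 sessions; a zero-SD feature contributes zeros; a missing value
contributes 0 with a warning rather than invalidating the session, keeping
longitudinal series contiguous. A single-feature composite is emitted with
a warning — it is a z-scored feature, not a genuine composite.

## Problem sizes and determinism

Tests and the acceptance script use 2–4 s synthetic responses, 5–120 s
landmark streams, cohorts of 40 participants and 100 Monte-Carlo
replicates; these sizes give stable statistics (binomial SE ≈ 3 % on the
recovery rates) at interactive runtimes. Every random draw flows from an
explicit seed through `numpy.random.default_rng`; identical configs produce
byte-identical session bundles.

## Known limitations

- The `ealvi`, expressivity and movement definitions are declared
  substitutes for proprietary production features.
- The acoustic 28 and linguistic 25 registries realize named stems at the
  printed counts; the exact production decomposition is not public.
- HNR is a periodicity index, not a calibrated dB measurement; jitter and
  shimmer have a sub-percent measurement floor on rendered audio.
- Whether gaze should derive from iris landmarks rather than eye-look
  blendshapes is untested here.
- The synthetic cohort plants linear Gaussian couplings; real
  feature–symptom relations are unlikely to be linear or stationary, and
  calibration results do not certify performance on real data.
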