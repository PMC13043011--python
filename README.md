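# convodx

Multimodal digital biomarkers from conversational check-in sessions.

Remote mental-health and fatigue monitoring platforms can capture three
behavioral data streams during a short voice conversation with an agent:
facial landmarks from the webcam (478 3-D points plus 52 named blendshape
activations per frame, at an uncontrolled 30–60 fps), the audio of each
participant response, and the timed transcript. `convodx` turns one such
session into a library of **66 session-level features** — 13 visual, 28
acoustic and 25 linguistic — and implements the two analyses built on top of
them:

1. **Baseline correlation screen.** Using each participant's earliest
   session, every feature is Pearson-correlated against depression (PHQ-9
   total), fatigue (Cancer Fatigue Scale total and physical / affective /
   cognitive subscales) and cognition (Trail Making Test parts A, B and
   total time). Per feature, values more than 2 sample SDs from the mean are
   removed first (single pass). Results are summarized as counts of
   significant features per measure × modality over the 13/28/25
   denominators.
2. **Within-person composite risk score.** For a participant with repeated
   sessions, each feature significant for a measure is z-scored against that
   participant's own across-session mean and SD,

   `risk(s) = Σ_f sign(r_f) · z_f(s)`,

   so positive scores mean the session deviated from the personal baseline
   in the direction associated with higher symptom severity.

Because operational cohort data cannot be shared, the package includes a
first-class **synthetic cohort generator**: correlated latent severities per
participant, an effect matrix mapping latents into physical generator
parameters (pitch level and slope, volume trajectory, jitter/shimmer,
formant targets, blink/yawn rates, eyelid droop, speech rate, lexical
make-up, …), source-filter audio synthesis, irregularly sampled landmark
streams and word-bank transcripts — all a pure function of one seed. Every
stage of the pipeline is tested against this generator's planted ground
truth.

## Worked example

`examples/01_extract_session_features.py` renders one synthetic session and
extracts all 66 features:

```
session P001-s01: 66 features extracted

feature              extracted     planted
pitch_mean            117.2987    117.1317
vol_mean                0.1220      0.1212
vol_std                 0.0244      0.0212
jitter_local            0.0147      0.0095
f2_mean              1484.0200   1526.5151
eyelid_droop            0.0752      0.0742
blinks_per_s            0.1000      0.1412
words_per_s             2.5307      2.5814
```

Each extracted value estimates the planted generator parameter on the left
of it: `pitch_mean` recovers the programmed 117 Hz fundamental,
`eyelid_droop` the programmed baseline eyelid closure, and so on — the
end-to-end extraction round trip. The other examples run the baseline
correlation screen on an 8-participant cohort
(`02_baseline_correlations.py`), build a rising fatigue-risk trajectory
(`03_risk_trajectory.py`), and show the on-disk session bundle format
(`04_session_bundles.py`).

A thin CLI wraps the same stages:

```bash
convodx simulate --n 8 --seed 0 --out cohort/
convodx extract --bundles cohort/ --out features.csv
convodx correlate --features features_wide.csv --scores scores.csv \
    --out correlations.csv
convodx riskscore --features features_wide.csv \
    --correlations correlations.csv --measure fatigue --out risk.csv
convodx run --seed 0 --out run/        # all of the above, with a manifest
```

## Layout

```
src/convodx/
  session.py     data model, bundle I/O, 30 fps interpolation, resampling
  registry.py    the frozen 66-feature registry (13 visual / 28 audio / 25 text)
  visual.py      blink/yawn detection, gaze, droop, expressivity
  acoustic.py    volume, pitch, jitter/shimmer/HNR, spectra, formants, pauses
  text.py        readability, fluency, lexicon affect, lexical structure
  synth.py       synthetic cohort generator with planted couplings
  correlate.py   baseline selection, outlier rule, Pearson screen
  risk.py        within-person composite risk trajectories
  pipeline.py    simulate → extract → correlate → riskscore, with manifest
  cli.py         `convodx` command group
docs/methods.md  model, parameters, numerical choices, limitations
```
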