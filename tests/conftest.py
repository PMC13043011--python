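"""Shared fixtures: small hand-built streams, tracks and sessions."""

from __future__ import annotations

import numpy as np
import pytest

from convodx.session import (AudioTrack, ClinicalScores, LandmarkStream,
                             Session, Transcript, TranscriptTurn,
                             BLENDSHAPE_INDEX, N_BLENDSHAPES, N_LANDMARKS)


def make_stream(times, blend: dict[str, np.ndarray] | None = None,
                landmarks: np.ndarray | None = None) -> LandmarkStream:
    """LandmarkStream with a static face and selected blendshape series."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    if landmarks is None:
        landmarks = np.full((n, N_LANDMARKS, 3), 0.5)
        landmarks[..., 2] = 0.0
    bs = np.zeros((n, N_BLENDSHAPES))
    for name, series in (blend or {}).items():
        bs[:, BLENDSHAPE_INDEX[name]] = series
    return LandmarkStream(timestamps=times, landmarks=landmarks,
                          blendshapes=bs)


def make_transcript(n_responses: int = 1, response_dur: float = 4.0,
                    text: str = "i felt fine today.") -> Transcript:
    turns = []
    t = 0.0
    for k in range(n_responses):
        turns.append(TranscriptTurn("agent", "how are you?", t, t + 2.0))
        t += 2.0
        start = t + 1.0
        toks = text.replace(".", "").split()
        slot = response_dur / len(toks)
        words = [(w, start + i * slot, start + (i + 0.8) * slot)
                 for i, w in enumerate(toks)]
        turns.append(TranscriptTurn("participant", text, start,
                                    start + response_dur, words))
        t = start + response_dur
    turns.append(TranscriptTurn("agent", "thanks, take care.", t, t + 2.0))
    return Transcript(turns)


def make_clinical() -> ClinicalScores:
    return ClinicalScores(phq9_total=6, cfs_total=24, cfs_physical=12,
                          cfs_affective=7, cfs_cognitive=5,
                          tmt_a_seconds=25.0, tmt_b_seconds=58.0)


def make_session(n_responses: int = 2, sr: int = 22050) -> Session:
    rng = np.random.default_rng(42)
    transcript = make_transcript(n_responses=n_responses)
    dur = transcript.turns[-1].end
    times = np.cumsum(rng.uniform(1 / 60, 1 / 30, size=int(dur * 45)))
    times = times[times < dur]
    stream = make_stream(
        times, blend={"eyeBlinkLeft": np.full(len(times), 0.1),
                      "eyeBlinkRight": np.full(len(times), 0.1)})
    t = np.arange(int(1.5 * sr)) / sr
    tracks = [AudioTrack(0.25 * np.sin(2 * np.pi * 180 * t)
                         .astype(np.float32), sr, response_index=k + 1)
              for k in range(n_responses)]
    return Session(participant_id="P001",
                   session_timestamp="2025-03-06T10:00:00",
                   landmark_stream=stream, audio_tracks=tracks,
                   transcript=transcript, clinical_scores=make_clinical())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_session() -> Session:
    return make_session()
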