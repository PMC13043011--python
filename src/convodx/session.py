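"""Session data model, bundle I/O and temporal normalization.

A check-in session couples four streams: a facial-landmark stream (478
3-D points plus 52 named blendshape activations per frame, captured at an
irregular 30-60 fps), one mono audio track per participant response, a timed
agent/participant transcript, and the session's clinical scores (PHQ-9, CFS
with subscales, TMT parts A and B).

Because capture rates vary by device, analysis runs on temporally
normalized streams: landmark streams linearly interpolated onto a uniform
30 fps grid and audio resampled to 22,050 Hz.

Bundle layout on disk (one directory per session)::

    landmarks.jsonl   one frame per line: {"t": s, "lm": [478*3 floats],
                      "bs": {blendshape name: score}}
    response_<k>.wav  mono float32 RIFF WAV, k = 1..n_responses
    transcript.json   {"turns": [{"speaker", "text", "start", "end", "words"}]}
    clinical.json     ClinicalScores fields
    meta.json         {"participant_id", "session_timestamp"}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import interp1d
from scipy.io import wavfile
from scipy.signal import resample_poly

N_LANDMARKS = 478
N_BLENDSHAPES = 52

# The 52 canonical ARKit-style face blendshapes emitted by mesh landmarkers.
BLENDSHAPE_NAMES: tuple[str, ...] = (
    "browDownLeft", "browDownRight", "browInnerUp",
    "browOuterUpLeft", "browOuterUpRight",
    "cheekPuff", "cheekSquintLeft", "cheekSquintRight",
    "eyeBlinkLeft", "eyeBlinkRight",
    "eyeLookDownLeft", "eyeLookDownRight",
    "eyeLookInLeft", "eyeLookInRight",
    "eyeLookOutLeft", "eyeLookOutRight",
    "eyeLookUpLeft", "eyeLookUpRight",
    "eyeSquintLeft", "eyeSquintRight",
    "eyeWideLeft", "eyeWideRight",
    "jawForward", "jawLeft", "jawOpen", "jawRight",
    "mouthClose", "mouthDimpleLeft", "mouthDimpleRight",
    "mouthFrownLeft", "mouthFrownRight", "mouthFunnel",
    "mouthLeft", "mouthLowerDownLeft", "mouthLowerDownRight",
    "mouthPressLeft", "mouthPressRight", "mouthPucker", "mouthRight",
    "mouthRollLower", "mouthRollUpper", "mouthShrugLower", "mouthShrugUpper",
    "mouthSmileLeft", "mouthSmileRight",
    "mouthStretchLeft", "mouthStretchRight",
    "mouthUpperUpLeft", "mouthUpperUpRight",
    "noseSneerLeft", "noseSneerRight",
    "tongueOut",
)
assert len(BLENDSHAPE_NAMES) == N_BLENDSHAPES

BLENDSHAPE_INDEX: dict[str, int] = {n: i for i, n in enumerate(BLENDSHAPE_NAMES)}


class SessionError(Exception):
    """Base error for session loading/validation."""


class SessionLoadError(SessionError):
    """A bundle file is missing or unreadable."""


class SessionValidationError(SessionError):
    """A type invariant is violated; the message names field and index."""


@dataclass
class LandmarkStream:
    """Time-ordered facial-landmark frames.

    timestamps : (n,) seconds from session start, strictly increasing
    landmarks  : (n, 478, 3) normalized image coordinates; x, y in [0, 1],
                 z is relative depth (unconstrained)
    blendshapes: (n, 52) activations in [0, 1], columns ordered as
                 :data:`BLENDSHAPE_NAMES`
    """

    timestamps: np.ndarray
    landmarks: np.ndarray
    blendshapes: np.ndarray
    nominal_fps_range: tuple[float, float] = (30.0, 60.0)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        self.blendshapes = np.asarray(self.blendshapes, dtype=float)

    def validate(self) -> None:
        n = len(self.timestamps)
        if self.landmarks.shape != (n, N_LANDMARKS, 3):
            raise SessionValidationError(
                f"landmarks shape {self.landmarks.shape}, "
                f"expected ({n}, {N_LANDMARKS}, 3)")
        if self.blendshapes.shape != (n, N_BLENDSHAPES):
            raise SessionValidationError(
                f"blendshapes shape {self.blendshapes.shape}, "
                f"expected ({n}, {N_BLENDSHAPES})")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            i = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0])
            raise SessionValidationError(
                f"timestamps not strictly increasing at frame {i + 1}")
        bad = (self.blendshapes < 0) | (self.blendshapes > 1)
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise SessionValidationError(
                f"blendshape score outside [0, 1] at frame {i}")
        xy = self.landmarks[..., :2]
        bad = (xy < 0) | (xy > 1)
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise SessionValidationError(
                f"landmark x/y outside [0, 1] at frame {i}")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def blendshape(self, name: str) -> np.ndarray:
        """Per-frame activation series for one named blendshape."""
        return self.blendshapes[:, BLENDSHAPE_INDEX[name]]


@dataclass
class AudioTrack:
    """Mono waveform for one participant response (float32 in [-1, 1])."""

    samples: np.ndarray
    sample_rate: int
    response_index: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.sample_rate <= 0:
            raise SessionValidationError(
                f"sample_rate must be > 0, got {self.sample_rate}")
        if self.samples.size == 0:
            raise SessionValidationError(
                f"response {self.response_index}: empty samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class TranscriptTurn:
    speaker: str            # "agent" | "participant"
    text: str
    start: float
    end: float
    words: list[tuple[str, float, float]] | None = None

    def validate(self, index: int) -> None:
        if self.speaker not in ("agent", "participant"):
            raise SessionValidationError(
                f"turn {index}: unknown speaker {self.speaker!r}")
        if self.start > self.end:
            raise SessionValidationError(
                f"turn {index}: start {self.start} > end {self.end}")
        if self.words:
            prev_end = None
            for j, (_, ws, we) in enumerate(self.words):
                if ws < self.start - 1e-9 or we > self.end + 1e-9 or ws > we:
                    raise SessionValidationError(
                        f"turn {index}: word {j} timing outside turn span")
                if prev_end is not None and ws < prev_end - 1e-9:
                    raise SessionValidationError(
                        f"turn {index}: word {j} overlaps previous word")
                prev_end = we


@dataclass
class Transcript:
    turns: list[TranscriptTurn]

    def validate(self) -> None:
        for i, t in enumerate(self.turns):
            t.validate(i)

    @property
    def participant_turns(self) -> list[TranscriptTurn]:
        return [t for t in self.turns if t.speaker == "participant"]

    @property
    def agent_turns(self) -> list[TranscriptTurn]:
        return [t for t in self.turns if t.speaker == "agent"]


@dataclass
class ClinicalScores:
    """Clinical instrument scores collected alongside a check-in.

    PHQ-9 total 0-27; CFS total with physical (0-28), affective (0-16) and
    cognitive (0-16) subscales; TMT part A and B completion times in seconds.
    """

    phq9_total: int
    cfs_total: int
    cfs_physical: int
    cfs_affective: int
    cfs_cognitive: int
    tmt_a_seconds: float
    tmt_b_seconds: float

    def validate(self) -> None:
        if not 0 <= self.phq9_total <= 27:
            raise SessionValidationError(
                f"phq9_total {self.phq9_total} outside [0, 27]")
        for name in ("cfs_physical", "cfs_affective", "cfs_cognitive"):
            if getattr(self, name) < 0:
                raise SessionValidationError(f"{name} is negative")
        subs = self.cfs_physical + self.cfs_affective + self.cfs_cognitive
        if self.cfs_total != subs:
            raise SessionValidationError(
                f"cfs_total {self.cfs_total} != subscale sum {subs}")
        if self.tmt_a_seconds <= 0 or self.tmt_b_seconds <= 0:
            raise SessionValidationError("TMT times must be > 0")

    def as_dict(self) -> dict:
        return {
            "phq9_total": self.phq9_total,
            "cfs_total": self.cfs_total,
            "cfs_physical": self.cfs_physical,
            "cfs_affective": self.cfs_affective,
            "cfs_cognitive": self.cfs_cognitive,
            "tmt_a_seconds": self.tmt_a_seconds,
            "tmt_b_seconds": self.tmt_b_seconds,
        }


@dataclass
class Session:
    participant_id: str
    session_timestamp: str          # ISO-8601
    landmark_stream: LandmarkStream
    audio_tracks: list[AudioTrack]
    transcript: Transcript
    clinical_scores: ClinicalScores

    def validate(self) -> None:
        self.landmark_stream.validate()
        self.transcript.validate()
        self.clinical_scores.validate()
        n_turns = len(self.transcript.participant_turns)
        if n_turns != len(self.audio_tracks):
            raise SessionValidationError(
                f"{n_turns} participant turns but "
                f"{len(self.audio_tracks)} audio tracks")


# ---------------------------------------------------------------------------
# bundle I/O

def write_session(session: Session, bundle_path: str | Path) -> Path:
    """Write a session to a bundle directory; returns the directory path."""
    session.validate()
    path = Path(bundle_path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "landmarks.jsonl", "w") as fh:
        stream = session.landmark_stream
        for i in range(stream.n_frames):
            rec = {
                "t": float(stream.timestamps[i]),
                "lm": [float(v) for v in stream.landmarks[i].ravel()],
                "bs": {n: float(stream.blendshapes[i, j])
                       for j, n in enumerate(BLENDSHAPE_NAMES)},
            }
            fh.write(json.dumps(rec) + "\n")

    for track in session.audio_tracks:
        wavfile.write(path / f"response_{track.response_index}.wav",
                      track.sample_rate, track.samples.astype(np.float32))

    turns = [
        {"speaker": t.speaker, "text": t.text, "start": t.start, "end": t.end,
         "words": ([[w, ws, we] for w, ws, we in t.words]
                   if t.words is not None else None)}
        for t in session.transcript.turns
    ]
    (path / "transcript.json").write_text(json.dumps({"turns": turns}))
    (path / "clinical.json").write_text(
        json.dumps(session.clinical_scores.as_dict()))
    (path / "meta.json").write_text(json.dumps({
        "participant_id": session.participant_id,
        "session_timestamp": session.session_timestamp,
    }))
    return path


def _require(path: Path) -> Path:
    if not path.exists():
        raise SessionLoadError(f"missing bundle file: {path.name}")
    return path


def read_session(bundle_path: str | Path) -> Session:
    """Read and fully validate a session bundle directory."""
    path = Path(bundle_path)
    if not path.is_dir():
        raise SessionLoadError(f"bundle directory not found: {path}")

    ts, lms, bss = [], [], []
    with open(_require(path / "landmarks.jsonl")) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            rec = json.loads(line)
            lm = np.asarray(rec["lm"], dtype=float)
            if lm.size != N_LANDMARKS * 3:
                raise SessionValidationError(
                    f"frame {i}: {lm.size // 3} landmark points, "
                    f"expected {N_LANDMARKS}")
            bs = rec["bs"]
            if len(bs) != N_BLENDSHAPES:
                raise SessionValidationError(
                    f"frame {i}: {len(bs)} blendshapes, "
                    f"expected {N_BLENDSHAPES}")
            try:
                bss.append([bs[n] for n in BLENDSHAPE_NAMES])
            except KeyError as e:
                raise SessionValidationError(
                    f"frame {i}: missing blendshape {e.args[0]!r}") from e
            ts.append(rec["t"])
            lms.append(lm.reshape(N_LANDMARKS, 3))
    stream = LandmarkStream(np.array(ts), np.array(lms), np.array(bss))

    meta = json.loads(_require(path / "meta.json").read_text())
    clin = json.loads(_require(path / "clinical.json").read_text())
    traw = json.loads(_require(path / "transcript.json").read_text())
    turns = [
        TranscriptTurn(
            speaker=t["speaker"], text=t["text"],
            start=float(t["start"]), end=float(t["end"]),
            words=([(w, float(s), float(e)) for w, s, e in t["words"]]
                   if t.get("words") is not None else None))
        for t in traw["turns"]
    ]
    transcript = Transcript(turns)

    tracks = []
    n_resp = len(transcript.participant_turns)
    for k in range(1, n_resp + 1):
        wav = _require(path / f"response_{k}.wav")
        rate, data = wavfile.read(wav)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if data.dtype == np.int16:
            data = data.astype(np.float32) / 32768.0
        tracks.append(AudioTrack(samples=data, sample_rate=int(rate),
                                 response_index=k))

    session = Session(
        participant_id=meta["participant_id"],
        session_timestamp=meta["session_timestamp"],
        landmark_stream=stream,
        audio_tracks=tracks,
        transcript=transcript,
        clinical_scores=ClinicalScores(**clin),
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# temporal normalization

def interpolate_stream(stream: LandmarkStream,
                       target_fps: float = 30.0) -> LandmarkStream:
    """Resample an irregular landmark stream onto a uniform frame grid.

    Output timestamps are ``t0 + k / target_fps`` for
    ``k = 0 .. floor((t_last - t0) * target_fps)``; every coordinate and
    blendshape is the linear interpolation between the two raw frames
    bracketing each grid point.  No extrapolation: the grid never extends
    past the last raw frame.
    """
    if target_fps <= 0:
        raise ValueError(f"target_fps must be > 0, got {target_fps}")
    if stream.n_frames < 2:
        raise ValueError("interpolation requires at least 2 frames")

    t = stream.timestamps
    n_out = int(np.floor((t[-1] - t[0]) * target_fps + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / target_fps
    grid = np.minimum(grid, t[-1])   # guard float overshoot at the edge

    flat = np.concatenate(
        [stream.landmarks.reshape(stream.n_frames, -1), stream.blendshapes],
        axis=1)
    interp = interp1d(t, flat, axis=0, assume_sorted=True)(grid)

    nlm = N_LANDMARKS * 3
    return LandmarkStream(
        timestamps=grid,
        landmarks=interp[:, :nlm].reshape(n_out, N_LANDMARKS, 3),
        blendshapes=np.clip(interp[:, nlm:], 0.0, 1.0),
        nominal_fps_range=(target_fps, target_fps),
    )


def resample_audio(track: AudioTrack, target_rate: int = 22050) -> AudioTrack:
    """Resample a track to ``target_rate`` Hz (polyphase, duration-preserving)."""
    if track.samples.size == 0:
        raise ValueError("cannot resample empty audio")
    if track.sample_rate == target_rate:
        return AudioTrack(track.samples.copy(), target_rate,
                          track.response_index)
    g = np.gcd(int(track.sample_rate), int(target_rate))
    out = resample_poly(track.samples.astype(np.float64),
                        target_rate // g, track.sample_rate // g)
    return AudioTrack(out.astype(np.float32), target_rate,
                      track.response_index)
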