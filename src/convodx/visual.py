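"""Visual features from an interpolated landmark stream.

The 13 session-level visual features cover ocular events (blinks, yawns,
saccade-like gaze shifts), gaze distribution, eyelid droop, facial
expressivity and speech-locked facial movement.  Event detection runs on
blendshape activations with hysteresis thresholds; all per-second rates use
the interpolated stream duration as denominator.

Undefined features (e.g. movement during speech when there are no speech
segments) are reported as ``nan``, never as a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig, VisualConfig
from .registry import VISUAL_FEATURES
from .session import LandmarkStream, Transcript

# blendshape groups
_BLINK_PAIR = ("eyeBlinkLeft", "eyeBlinkRight")
_LOOK_UP = ("eyeLookUpLeft", "eyeLookUpRight")
_LOOK_DOWN = ("eyeLookDownLeft", "eyeLookDownRight")
_LOOK_RIGHT = ("eyeLookOutRight", "eyeLookInLeft")
_LOOK_LEFT = ("eyeLookOutLeft", "eyeLookInRight")
_SMILE_PAIR = ("mouthSmileLeft", "mouthSmileRight")
_FROWN_PAIR = ("mouthFrownLeft", "mouthFrownRight")
_BROW_DOWN = ("browDownLeft", "browDownRight")
# excluded from the expressivity subset: gaze and blink dynamics would
# inflate "expressiveness"
_GAZE_BLINK_PREFIXES = ("eyeLook", "eyeBlink")


@dataclass(frozen=True)
class OcularEvent:
    kind: str        # "blink" | "yawn"
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def _pair_mean(stream: LandmarkStream, names: tuple[str, str]) -> np.ndarray:
    return (stream.blendshape(names[0]) + stream.blendshape(names[1])) / 2.0


def _hysteresis_events(signal: np.ndarray, times: np.ndarray, kind: str,
                       on: float, off: float,
                       min_dur: float, max_dur: float) -> list[OcularEvent]:
    """Threshold-crossing events with hysteresis.

    An event opens at the first sample with ``signal >= on`` and closes at
    the first subsequent sample with ``signal < off`` (half-open in time, so
    a k-frame excursion at frame period dt has duration k*dt).  Events still
    open at the end of the stream close at the last timestamp.
    """
    events: list[OcularEvent] = []
    start = None
    for i in range(len(signal)):
        if start is None:
            if signal[i] >= on:
                start = times[i]
        elif signal[i] < off:
            events.append(OcularEvent(kind, start, times[i]))
            start = None
    if start is not None and times[-1] > start:
        events.append(OcularEvent(kind, start, times[-1]))
    return [e for e in events if min_dur <= e.duration <= max_dur]


def detect_blinks(stream: LandmarkStream,
                  config: VisualConfig | None = None) -> list[OcularEvent]:
    """Blink events from the mean of the eyeBlinkLeft/Right blendshapes."""
    if stream.n_frames == 0:
        raise ValueError("empty stream")
    cfg = config or VisualConfig()
    sig = _pair_mean(stream, _BLINK_PAIR)
    return _hysteresis_events(sig, stream.timestamps, "blink",
                              cfg.blink_on, cfg.blink_off,
                              cfg.blink_min_dur, cfg.blink_max_dur)


def detect_yawns(stream: LandmarkStream,
                 config: VisualConfig | None = None) -> list[OcularEvent]:
    """Yawn events: sustained jawOpen activation."""
    if stream.n_frames == 0:
        raise ValueError("empty stream")
    cfg = config or VisualConfig()
    sig = stream.blendshape("jawOpen")
    return _hysteresis_events(sig, stream.timestamps, "yawn",
                              cfg.yawn_on, cfg.yawn_off,
                              cfg.yawn_min_dur, np.inf)


def _event_mask(times: np.ndarray, events: list[OcularEvent]) -> np.ndarray:
    """Boolean mask of frames that fall inside any event."""
    mask = np.zeros(len(times), dtype=bool)
    for e in events:
        mask |= (times >= e.start) & (times < e.end)
    return mask


def eyelid_droop(stream: LandmarkStream,
                 blink_events: list[OcularEvent]) -> float:
    """Baseline eyelid closure: mean blink-blendshape level outside blinks."""
    sig = _pair_mean(stream, _BLINK_PAIR)
    outside = ~_event_mask(stream.timestamps, blink_events)
    if not outside.any():
        raise ValueError("stream is entirely within blink events")
    return float(sig[outside].mean())


def _gaze_components(stream: LandmarkStream) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (horizontal, vertical) gaze components.

    Horizontal is rightward minus leftward activation, vertical is upward
    minus downward; both are 0 for a centered gaze.
    """
    horiz = _pair_mean(stream, _LOOK_RIGHT) - _pair_mean(stream, _LOOK_LEFT)
    vert = _pair_mean(stream, _LOOK_UP) - _pair_mean(stream, _LOOK_DOWN)
    return horiz, vert


def gaze_features(stream: LandmarkStream) -> tuple[float, float, float]:
    """(gaze_down_dist, gaze_x_dist, gaze_y_dist).

    ``gaze_x_dist`` / ``gaze_y_dist`` are mean absolute deviations from
    center per axis; ``gaze_down_dist`` averages only the downward-positive
    component, so an upward gaze contributes 0.
    """
    if stream.n_frames == 0:
        raise ValueError("empty stream")
    horiz, vert = _gaze_components(stream)
    gaze_x_dist = float(np.abs(horiz).mean())
    gaze_y_dist = float(np.abs(vert).mean())
    gaze_down_dist = float(np.maximum(-vert, 0.0).mean())
    return gaze_down_dist, gaze_x_dist, gaze_y_dist


def _speech_segments(transcript: Transcript) -> list[tuple[float, float]]:
    return [(t.start, t.end) for t in transcript.participant_turns
            if t.end > t.start]


def _in_segments(times: np.ndarray,
                 segments: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for s, e in segments:
        mask |= (times >= s) & (times <= e)
    return mask


def expressivity_features(
    stream: LandmarkStream,
    speech_segments: list[tuple[float, float]],
    config: VisualConfig | None = None,
) -> tuple[float, float, float, float, float]:
    """(affect_measure, mouth_curvature, eyebrow_droop,
    movement_speech_measure, eye_movements_per_s).

    affect_measure: mean temporal SD over the expression blendshapes
    (everything except the eye-look/eye-blink groups); lower = flatter
    affect.  movement_speech_measure: mean x-y landmark displacement per
    second restricted to participant-speech segments (``nan`` when there are
    no speech segments).  eye_movements_per_s: rate of gaze-velocity peaks
    above ``saccade_mad_factor`` times the median absolute velocity.
    """
    if stream.n_frames == 0:
        raise ValueError("empty stream")
    cfg = config or VisualConfig()
    from .session import BLENDSHAPE_NAMES

    expr_cols = [i for i, n in enumerate(BLENDSHAPE_NAMES)
                 if not n.startswith(_GAZE_BLINK_PREFIXES)]
    affect = float(stream.blendshapes[:, expr_cols].std(axis=0).mean())

    mouth_curv = float((_pair_mean(stream, _SMILE_PAIR)
                        - _pair_mean(stream, _FROWN_PAIR)).mean())
    brow = float(_pair_mean(stream, _BROW_DOWN).mean())

    # speech-locked movement, x-y plane only
    movement = np.nan
    if speech_segments and stream.n_frames >= 2:
        times = stream.timestamps
        inside = _in_segments(times, speech_segments)
        pair = inside[:-1] & inside[1:]
        if pair.any():
            dxy = np.diff(stream.landmarks[..., :2], axis=0)
            disp = np.linalg.norm(dxy, axis=2).mean(axis=1)   # per frame pair
            dt = np.diff(times)
            movement = float(disp[pair].sum() / dt[pair].sum())

    # saccade-like events from gaze velocity peaks
    eye_mov_rate = 0.0
    if stream.n_frames >= 3 and stream.duration > 0:
        horiz, vert = _gaze_components(stream)
        dt = np.diff(stream.timestamps)
        vel = np.hypot(np.diff(horiz), np.diff(vert)) / dt
        med = float(np.median(np.abs(vel)))
        thresh = max(cfg.saccade_mad_factor * med, 1e-6)
        fps = 1.0 / float(np.median(dt))
        min_sep = max(int(round(cfg.saccade_min_sep * fps)), 1)
        peaks, _ = find_peaks(vel, height=thresh, distance=min_sep)
        eye_mov_rate = len(peaks) / stream.duration

    return affect, mouth_curv, brow, movement, eye_mov_rate


def extract_visual(stream: LandmarkStream, transcript: Transcript,
                   config: AnalysisConfig | None = None) -> dict[str, float]:
    """All 13 visual features for one interpolated session stream."""
    cfg = (config or AnalysisConfig()).visual
    duration = stream.duration
    if duration <= 0:
        raise ValueError("stream too short to extract visual features")

    blinks = detect_blinks(stream, cfg)
    yawns = detect_yawns(stream, cfg)
    droop = eyelid_droop(stream, blinks)
    gaze_down, gaze_x, gaze_y = gaze_features(stream)
    affect, mouth_curv, brow, movement, eye_mov = expressivity_features(
        stream, _speech_segments(transcript), cfg)

    out = {
        "affect_measure": affect,
        "mouth_curvature": mouth_curv,
        "eyebrow_droop": brow,
        "gaze_down_dist": gaze_down,
        "gaze_x_dist": gaze_x,
        "gaze_y_dist": gaze_y,
        "movement_speech_measure": movement,
        "eyelid_droop": droop,
        "blinks_per_s": len(blinks) / duration,
        "blink_len": (float(np.mean([e.duration for e in blinks]))
                      if blinks else np.nan),
        "yawns_per_s": len(yawns) / duration,
        "yawn_len": (float(np.mean([e.duration for e in yawns]))
                     if yawns else np.nan),
        "eye_movements_per_s": eye_mov,
    }
    assert set(out) == set(VISUAL_FEATURES)
    return out
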