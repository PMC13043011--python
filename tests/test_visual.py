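"""Visual feature extraction: event detection, gaze, expressivity."""

import numpy as np
import pytest

from convodx.registry import VISUAL_FEATURES
from convodx.synth import PARAM_SPECS, synth_landmarks
from convodx.visual import (detect_blinks, detect_yawns, expressivity_features,
                            extract_visual, eyelid_droop, gaze_features)

from conftest import make_stream, make_transcript


def _pulse(times, t0, t1, level):
    sig = np.zeros(len(times))
    sig[(times >= t0) & (times < t1)] = level
    return sig


def blink_stream(times, pulses, baseline=0.0):
    sig = np.full(len(np.asarray(times)), baseline)
    for t0, t1 in pulses:
        sig += _pulse(times, t0, t1, 0.9 - baseline)
    return make_stream(times, blend={"eyeBlinkLeft": sig,
                                     "eyeBlinkRight": sig})


class TestBlinks:
    def test_flat_signal_no_events(self):
        times = np.arange(0, 10, 1 / 30)
        assert detect_blinks(blink_stream(times, [])) == []

    def test_single_pulse_duration(self):
        times = np.arange(0, 2, 1 / 30)
        events = detect_blinks(blink_stream(times, [(1.0, 1.1)]))
        assert len(events) == 1
        assert events[0].duration == pytest.approx(0.1, abs=1 / 30)

    def test_three_pulses_in_ten_seconds_rate(self):
        times = np.arange(0, 10 + 1e-9, 1 / 30)
        pulses = [(1, 1.15), (4, 4.15), (8, 8.15)]
        stream = blink_stream(times, pulses)
        events = detect_blinks(stream)
        assert len(events) == 3
        feats = extract_visual(stream, make_transcript())
        assert feats["blinks_per_s"] == pytest.approx(0.3, rel=1e-6)

    def test_too_short_and_too_long_excursions_discarded(self):
        times = np.arange(0, 10, 1 / 30)
        # one frame (~33 ms) and a 1 s closure are both outside blink bounds
        stream = blink_stream(times, [(2.0, 2.02), (5.0, 6.0)])
        assert detect_blinks(stream) == []

    def test_blink_len_is_mean_event_duration(self):
        times = np.arange(0, 10, 1 / 30)
        stream = blink_stream(times, [(1, 1.1), (4, 4.3)])
        events = detect_blinks(stream)
        feats = extract_visual(stream, make_transcript())
        assert feats["blink_len"] == pytest.approx(
            np.mean([e.duration for e in events]))

    def test_time_shift_invariance(self):
        times = np.arange(0, 10, 1 / 30)
        stream = blink_stream(times, [(1, 1.15), (4, 4.15)])
        shifted = blink_stream(times + 100.0,
                               [(101, 101.15), (104, 104.15)])
        e0 = detect_blinks(stream)
        e1 = detect_blinks(shifted)
        assert [e.duration for e in e0] == pytest.approx(
            [e.duration for e in e1])
        assert [e.start + 100 for e in e0] == pytest.approx(
            [e.start for e in e1])


class TestYawns:
    def test_no_jaw_activity(self):
        times = np.arange(0, 10, 1 / 30)
        assert detect_yawns(make_stream(times)) == []

    def test_sustained_opening_detected(self):
        times = np.arange(0, 5, 1 / 30)
        jaw = _pulse(times, 1.0, 3.0, 0.8)
        events = detect_yawns(make_stream(times, blend={"jawOpen": jaw}))
        assert len(events) == 1
        assert events[0].duration == pytest.approx(2.0, abs=0.05)

    def test_short_opening_rejected(self):
        times = np.arange(0, 5, 1 / 30)
        jaw = _pulse(times, 1.0, 1.5, 0.8)
        assert detect_yawns(make_stream(times, blend={"jawOpen": jaw})) == []


class TestEyelidDroop:
    def test_constant_baseline(self):
        times = np.arange(0, 5, 1 / 30)
        stream = blink_stream(times, [], baseline=0.2)
        assert eyelid_droop(stream, []) == pytest.approx(0.2)

    def test_blink_frames_masked_out(self):
        times = np.arange(0, 5, 1 / 30)
        stream = blink_stream(times, [(2.0, 2.15)], baseline=0.2)
        events = detect_blinks(stream)
        assert len(events) == 1
        assert eyelid_droop(stream, events) == pytest.approx(0.2)

    def test_zero_signal(self):
        times = np.arange(0, 5, 1 / 30)
        assert eyelid_droop(make_stream(times), []) == 0.0


class TestGaze:
    times = np.arange(0, 3, 1 / 30)

    def test_centered_gaze_all_zero(self):
        assert gaze_features(make_stream(self.times)) == (0.0, 0.0, 0.0)

    def test_downward_gaze(self):
        n = len(self.times)
        stream = make_stream(self.times, blend={
            "eyeLookDownLeft": np.full(n, 0.4),
            "eyeLookDownRight": np.full(n, 0.4)})
        down, x, y = gaze_features(stream)
        assert down == pytest.approx(0.4)
        assert y == pytest.approx(0.4)
        assert x == pytest.approx(0.0)

    def test_upward_gaze_does_not_count_as_down(self):
        n = len(self.times)
        stream = make_stream(self.times, blend={
            "eyeLookUpLeft": np.full(n, 0.4),
            "eyeLookUpRight": np.full(n, 0.4)})
        down, x, y = gaze_features(stream)
        assert down == 0.0
        assert y == pytest.approx(0.4)


class TestExpressivity:
    def test_frozen_face_is_flat(self):
        times = np.arange(0, 5, 1 / 30)
        stream = make_stream(times)
        affect, _, _, movement, saccades = expressivity_features(
            stream, [(0.0, 5.0)])
        assert affect == 0.0
        assert movement == 0.0
        assert saccades == 0.0

    def test_mouth_curvature_arithmetic(self):
        times = np.arange(0, 2, 1 / 30)
        n = len(times)
        stream = make_stream(times, blend={
            "mouthSmileLeft": np.full(n, 0.6),
            "mouthSmileRight": np.full(n, 0.6),
            "mouthFrownLeft": np.full(n, 0.1),
            "mouthFrownRight": np.full(n, 0.1)})
        _, curvature, _, _, _ = expressivity_features(stream, [])
        assert curvature == pytest.approx(0.5)

    def test_uniform_translation_speed(self):
        # 0.01 units/frame at 30 fps during speech -> 0.3 units/s
        times = np.arange(0, 2, 1 / 30)
        stream = make_stream(times)
        stream.landmarks = stream.landmarks.copy()
        stream.landmarks[..., 0] = 0.2 + 0.01 * np.arange(len(times))[:, None]
        _, _, _, movement, _ = expressivity_features(stream, [(0.0, 2.0)])
        assert movement == pytest.approx(0.3, rel=1e-6)

    def test_no_speech_segments_flags_movement_missing(self):
        times = np.arange(0, 2, 1 / 30)
        _, _, _, movement, _ = expressivity_features(make_stream(times), [])
        assert np.isnan(movement)

    def test_depth_scaling_leaves_movement_unchanged(self, rng):
        times = np.arange(0, 2, 1 / 30)
        stream = make_stream(times)
        stream.landmarks = stream.landmarks.copy()
        stream.landmarks[..., 0] += rng.normal(0, 0.002,
                                               (len(times), 1))
        base = expressivity_features(stream, [(0, 2)])[3]
        stream.landmarks[..., 2] *= 10.0
        scaled = expressivity_features(stream, [(0, 2)])[3]
        assert scaled == pytest.approx(base)


class TestExtractVisual:
    def test_exactly_13_named_features(self):
        times = np.arange(0, 5, 1 / 30)
        feats = extract_visual(make_stream(times), make_transcript())
        assert set(feats) == set(VISUAL_FEATURES)

    def test_static_face_rates_are_zero(self):
        times = np.arange(0, 5, 1 / 30)
        feats = extract_visual(make_stream(times), make_transcript())
        for name in ("blinks_per_s", "yawns_per_s", "eye_movements_per_s",
                     "affect_measure"):
            assert feats[name] == 0.0

    def test_generated_blink_rate_recovered(self):
        # planted 0.4 blinks/s over 60 s: detected count within the central
        # 95% Poisson interval of mean 24
        params = {k: v[0] for k, v in PARAM_SPECS.items()}
        params.update(blink_rate=0.4, yawn_rate=0.0)
        stream = synth_landmarks(params, 60.0, np.random.default_rng(7))
        from convodx.session import interpolate_stream
        events = detect_blinks(interpolate_stream(stream))
        assert 15 <= len(events) <= 34
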