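"""Acoustic features against constructed signals with known ground truth."""

import numpy as np
import pytest
from scipy.signal import lfilter

from convodx.acoustic import (ealvi, extract_acoustic, formant_features,
                              frame_rms, pause_features,
                              perturbation_features, pitch_features,
                              speech_mask, spectral_features,
                              volume_features)
from convodx.config import AcousticConfig
from convodx.registry import ACOUSTIC_FEATURES
from convodx.session import AudioTrack

SR = 22050
CFG = AcousticConfig()


def tone(freq=220.0, dur=2.0, amp=0.3, sr=SR):
    t = np.arange(int(dur * sr)) / sr
    return AudioTrack(amp * np.sin(2 * np.pi * freq * t), sr)


def pulse_train(period_samples, dur=2.0, amps=None, sr=SR,
                formants=((500, 80), (1500, 110), (2500, 150))):
    """Resonator-filtered impulse train; strictly periodic by construction."""
    n = int(dur * sr)
    x = np.zeros(n)
    idx = np.arange(0, n, period_samples)
    if amps is None:
        x[idx] = 1.0
    else:
        x[idx] = np.resize(amps, len(idx))
    for f, bw in formants:
        r = np.exp(-np.pi * bw / sr)
        th = 2 * np.pi * f / sr
        x = lfilter([1 - r], [1, -2 * r * np.cos(th), r ** 2], x)
    return AudioTrack(x, sr)


class TestVolume:
    def test_constant_tone_has_flat_envelope(self):
        v = volume_features(tone())
        assert v["vol_std"] == pytest.approx(0.0, abs=1e-3)
        assert v["vol_slope"] == pytest.approx(0.0, abs=1e-3)
        assert v["vol_range"] == pytest.approx(0.0, abs=5e-3)

    def test_ramp_slope_matches_ols_oracle(self):
        # RMS envelope ramps 0.1 -> 0.3 over 2 s; extracted slope must match
        # a closed-form OLS fit on independently computed frame RMS values
        t = np.arange(2 * SR) / SR
        x = np.sqrt(2) * (0.1 + 0.1 * t) * np.sin(2 * np.pi * 200 * t)
        track = AudioTrack(x, SR)
        v = volume_features(track)
        times, rms = frame_rms(track)
        mask = speech_mask(rms)
        tt, rr = times[mask], rms[mask]
        oracle = (np.sum((tt - tt.mean()) * (rr - rr.mean()))
                  / np.sum((tt - tt.mean()) ** 2))
        assert v["vol_slope"] == pytest.approx(oracle, rel=1e-9)
        assert v["vol_slope"] == pytest.approx(0.1, rel=0.1)

    def test_silent_track_flagged_missing(self):
        v = volume_features(AudioTrack(np.zeros(SR) + 1e-12, SR))
        assert all(np.isnan(x) for x in v.values())


class TestEalvi:
    def test_constant_amplitude_is_zero(self):
        assert ealvi(np.full(100, 0.2)) == 0.0

    def test_half_frames_soft_is_half(self):
        rms = np.concatenate([np.full(50, 1.0), np.full(50, 0.2)])
        assert ealvi(rms) == 0.5

    def test_ramp_matches_enumeration(self):
        rms = np.linspace(0.1, 1.0, 200)
        expected = np.mean(rms < 0.5 * np.median(rms))
        assert ealvi(rms) == pytest.approx(expected)


class TestPitch:
    def test_pure_tone_within_1hz(self):
        p = pitch_features(tone(220.0))
        assert p["pitch_mean"] == pytest.approx(220.0, abs=1.0)
        assert p["pitch_std"] < 1.0
        assert p["voiced_fraction"] > 0.9

    def test_white_noise_is_unvoiced(self, rng):
        p = pitch_features(AudioTrack(0.3 * rng.standard_normal(2 * SR), SR))
        assert p["voiced_fraction"] < 0.05
        assert np.isnan(p["pitch_mean"])

    def test_linear_glide_slope(self):
        t = np.arange(2 * SR) / SR
        phase = 2 * np.pi * np.cumsum(180 + 40 * t) / SR
        p = pitch_features(AudioTrack(0.3 * np.sin(phase), SR))
        assert p["pitch_slope"] == pytest.approx(40.0, rel=0.05)


class TestPerturbation:
    def test_strictly_periodic_is_zero(self):
        pert = perturbation_features(pulse_train(150))
        assert pert["jitter_local"] == pytest.approx(0.0, abs=1e-3)
        assert pert["shimmer_local"] == pytest.approx(0.0, abs=1e-3)

    def test_planted_jitter_matches_period_sequence_oracle(self, rng):
        # pulses with programmed period perturbation; jitter_local must match
        # the brute-force statistic on the generated period sequence
        eps = 0.02
        base = 150.0
        n = int(2.0 * SR)
        periods = base * (1 + eps * rng.standard_normal(200))
        positions = np.round(np.cumsum(periods)).astype(int)
        positions = positions[positions < n - 200]
        x = np.zeros(n)
        x[positions] = 1.0
        for f, bw in ((500, 80), (1500, 110)):
            r = np.exp(-np.pi * bw / SR)
            th = 2 * np.pi * f / SR
            x = lfilter([1 - r], [1, -2 * r * np.cos(th), r ** 2], x)
        placed = np.diff(positions).astype(float)
        oracle = np.abs(np.diff(placed)).mean() / placed.mean()
        pert = perturbation_features(AudioTrack(x, SR))
        assert pert["jitter_local"] == pytest.approx(oracle, rel=0.10)

    def test_alternating_amplitude_shimmer(self):
        # amplitudes A, 1.1A alternating: mean |dA| / mean A = 0.1/1.05;
        # unfiltered pulses so cycle peak amplitudes are exactly as planted
        pert = perturbation_features(
            pulse_train(150, amps=[1.0, 1.1], formants=()))
        assert pert["shimmer_local"] == pytest.approx(0.1 / 1.05, rel=0.10)

    def test_too_few_periods_flagged_missing(self):
        pert = perturbation_features(pulse_train(150, dur=0.015))
        assert np.isnan(pert["jitter_local"])


class TestSpectral:
    def test_pure_tone_centroid(self):
        s = spectral_features(tone(1000.0))
        bin_hz = SR / CFG.frame_length
        assert s["spectral_centroid_mean"] == pytest.approx(1000.0,
                                                            abs=3 * bin_hz)

    def test_white_noise_flatness_near_one(self, rng):
        s = spectral_features(AudioTrack(0.3 * rng.standard_normal(2 * SR),
                                         SR))
        assert s["spectral_flatness_mean"] > 0.9

    def test_two_equal_tones_centroid_is_mean(self):
        t = np.arange(2 * SR) / SR
        x = 0.3 * (np.sin(2 * np.pi * 500 * t) + np.sin(2 * np.pi * 1500 * t))
        s = spectral_features(AudioTrack(x, SR))
        bin_hz = SR / CFG.frame_length
        assert s["spectral_centroid_mean"] == pytest.approx(1000.0,
                                                            abs=3 * bin_hz)


class TestFormants:
    def test_programmed_resonances_recovered(self):
        f = formant_features(pulse_train(160))
        assert f["f1_mean"] == pytest.approx(500, rel=0.10)
        assert f["f2_mean"] == pytest.approx(1500, rel=0.10)
        assert f["f3_mean"] == pytest.approx(2500, rel=0.10)

    def test_stationary_filter_has_tiny_std(self):
        f = formant_features(pulse_train(160))
        assert f["f1_std"] < 30
        assert f["f2_std"] < 30

    def test_f2_f1_ratio(self):
        f = formant_features(pulse_train(160))
        assert f["f2_f1_ratio"] == pytest.approx(3.0, rel=0.15)

    def test_unvoiced_audio_flagged_missing(self, rng):
        f = formant_features(AudioTrack(0.1 * rng.standard_normal(SR), SR))
        assert np.isnan(f["f1_mean"])


class TestPauses:
    def _gapped(self, gap):
        t = np.arange(int(1.0 * SR)) / SR
        seg = 0.3 * np.sin(2 * np.pi * 200 * t)
        return AudioTrack(np.concatenate(
            [seg, np.zeros(int(gap * SR)), seg]), SR)

    def test_continuous_tone_no_pauses(self):
        p = pause_features(tone())
        assert p["pause_rate"] == 0.0
        assert np.isnan(p["pause_mean_len"])

    def test_400ms_gap_detected(self):
        p = pause_features(self._gapped(0.4))
        assert p["pause_rate"] == pytest.approx(1 / 2.4, rel=0.05)
        assert p["pause_mean_len"] == pytest.approx(0.4, abs=0.11)

    def test_gap_below_min_pause_ignored(self):
        cfg = AcousticConfig(min_pause=0.5)
        p = pause_features(self._gapped(0.4), cfg)
        assert p["pause_rate"] == 0.0


class TestExtractAcoustic:
    def test_exactly_28_named_features(self):
        out = extract_acoustic([tone()])
        assert set(out) == set(ACOUSTIC_FEATURES)

    def test_identical_responses_average_to_single(self):
        tracks = [tone(200.0, amp=0.2) for _ in range(4)]
        single = extract_acoustic(tracks[:1])
        four = extract_acoustic(tracks)
        for k in ACOUSTIC_FEATURES:
            if np.isnan(single[k]):
                assert np.isnan(four[k])
            else:
                assert four[k] == pytest.approx(single[k], rel=1e-9)

    def test_amplitude_scaling_invariance(self, rng):
        track = pulse_train(150, amps=1 + 0.05 * rng.standard_normal(300))
        a = extract_acoustic([track])
        scaled = AudioTrack(track.samples * 0.25, SR)
        b = extract_acoustic([scaled])
        for k in ("pitch_mean", "jitter_local", "shimmer_local",
                  "spectral_flatness_mean", "voiced_fraction", "ealvi",
                  "pause_rate", "f1_mean", "f2_mean"):
            if not np.isnan(a[k]):
                assert b[k] == pytest.approx(a[k], rel=0.02), k
        assert b["vol_mean"] == pytest.approx(0.25 * a["vol_mean"], rel=0.01)

    def test_time_reversal_flips_slopes(self):
        t = np.arange(2 * SR) / SR
        x = np.sqrt(2) * (0.1 + 0.08 * t) * np.sin(2 * np.pi * 200 * t)
        fwd = volume_features(AudioTrack(x, SR))
        rev = volume_features(AudioTrack(x[::-1].copy(), SR))
        assert rev["vol_slope"] == pytest.approx(-fwd["vol_slope"], rel=0.05)
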