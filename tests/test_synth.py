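"""Synthetic cohort generator: determinism, structure, round-trip recovery."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from convodx.acoustic import pitch_features, perturbation_features, \
    volume_features
from convodx.session import (interpolate_stream, N_BLENDSHAPES, N_LANDMARKS,
                             read_session)
from convodx.synth import (CohortConfig, PARAM_SPECS, feature_table_from_params,
                           render_session, simulate_cohort, simulate_truth,
                           synth_audio, synth_landmarks, synth_transcript)
from convodx.text import extract_text
from convodx.visual import detect_blinks

BASE_PARAMS = {k: v[0] for k, v in PARAM_SPECS.items()}

FAST_RENDER = {"response_dur": 3.0, "yawn_rate": 0.0}


def small_config(**kw):
    defaults = dict(n_participants=2, mean_sessions=1.0, seed=11,
                    param_overrides=dict(FAST_RENDER))
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestDeterminism:
    def test_same_seed_same_truth(self):
        a = simulate_truth(small_config())
        b = simulate_truth(small_config())
        assert a.equals(b)

    def test_same_seed_byte_identical_bundles(self, tmp_path):
        _, paths_a = simulate_cohort(small_config(), tmp_path / "a")
        _, paths_b = simulate_cohort(small_config(), tmp_path / "b")
        assert [p.name for p in paths_a] == [p.name for p in paths_b]
        for pa, pb in zip(paths_a, paths_b):
            for f in sorted(x.name for x in pa.iterdir()):
                assert filecmp.cmp(pa / f, pb / f, shallow=False), f

    def test_different_seed_changes_realization(self):
        a = simulate_truth(small_config(seed=1))
        b = simulate_truth(small_config(seed=2))
        assert not np.allclose(a["f0_mean"], b["f0_mean"])


class TestStructure:
    def test_landmark_frames_carry_478_points_52_blendshapes(self, rng):
        stream = synth_landmarks(BASE_PARAMS, 5.0, rng)
        stream.validate()
        assert stream.landmarks.shape[1:] == (N_LANDMARKS, 3)
        assert stream.blendshapes.shape[1] == N_BLENDSHAPES

    def test_frame_rate_is_irregular_within_30_60(self, rng):
        stream = synth_landmarks(BASE_PARAMS, 10.0, rng)
        dt = np.diff(stream.timestamps)
        assert (dt > 1 / 61).all() and (dt < 1 / 29).all()
        assert dt.std() > 0

    def test_transcript_has_4_participant_5_agent_turns(self, rng):
        t = synth_transcript(BASE_PARAMS, rng)
        assert len(t.participant_turns) == 4
        assert len(t.agent_turns) == 5
        speakers = [turn.speaker for turn in t.turns]
        assert speakers == ["agent", "participant"] * 4 + ["agent"]

    def test_rendered_bundle_round_trips(self, tmp_path):
        truth, paths = simulate_cohort(small_config(), tmp_path / "c")
        session = read_session(paths[0])
        assert len(session.audio_tracks) == 4
        assert (tmp_path / "c" / "cohort_truth.json").exists()

    def test_clinical_scores_respect_instrument_ranges(self):
        cfg = CohortConfig(n_participants=25, mean_sessions=2.0, seed=5)
        truth = simulate_truth(cfg)
        assert truth["phq9_total"].between(0, 27).all()
        assert truth["cfs_physical"].between(0, 28).all()
        assert truth["cfs_affective"].between(0, 16).all()
        assert truth["cfs_cognitive"].between(0, 16).all()
        assert (truth["cfs_total"] == truth["cfs_physical"]
                + truth["cfs_affective"] + truth["cfs_cognitive"]).all()
        assert (truth[["tmt_a_seconds", "tmt_b_seconds"]] > 0).all().all()


class TestAudioRoundTrip:
    def test_zero_perturbation_yields_near_zero_jitter_shimmer(self, rng):
        p = dict(BASE_PARAMS, jitter_eps=0.0, shimmer_eps=0.0, pause_rate=0.0,
                 rms_wander=0.003, rms_slope=0.0, f0_slope=0.0)
        track = synth_audio(p, 3.0, rng)
        pert = perturbation_features(track)
        assert pert["jitter_local"] < 0.012
        assert pert["shimmer_local"] < 0.03

    def test_programmed_pitch_recovered(self, rng):
        p = dict(BASE_PARAMS, f0_mean=200.0, f0_slope=0.0, pause_rate=0.0)
        track = synth_audio(p, 3.0, rng)
        assert pitch_features(track)["pitch_mean"] == pytest.approx(200.0,
                                                                    abs=2.0)

    def test_programmed_volume_slope_recovered(self, rng):
        p = dict(BASE_PARAMS, rms_slope=0.02, rms_wander=0.003,
                 pause_rate=0.0)
        track = synth_audio(p, 4.0, rng)
        assert volume_features(track)["vol_slope"] == pytest.approx(0.02,
                                                                    rel=0.10)


class TestLandmarkRoundTrip:
    def test_zero_blink_rate_no_events(self, rng):
        p = dict(BASE_PARAMS, blink_rate=0.0)
        stream = interpolate_stream(synth_landmarks(p, 20.0, rng))
        assert detect_blinks(stream) == []

    def test_planted_blink_rate_within_poisson_interval(self, rng):
        # 0.4 blinks/s over 120 s: central 95% interval of Poisson(48)
        p = dict(BASE_PARAMS, blink_rate=0.4)
        stream = interpolate_stream(synth_landmarks(p, 120.0, rng))
        assert 35 <= len(detect_blinks(stream)) <= 62


class TestTranscriptRoundTrip:
    def test_zero_filler_rate(self, rng):
        t = synth_transcript(dict(BASE_PARAMS, filler_rate=0.0), rng)
        assert extract_text(t)["hesitations_per_s"] == 0.0

    def test_gunning_fog_matches_formula_on_realized_text(self, rng):
        from convodx.text import count_syllables, sentences, tokenize
        t = synth_transcript(dict(BASE_PARAMS, long_word_prop=0.1,
                                  speech_rate=3.0, response_dur=33.0), rng)
        fogs = []
        for turn in t.participant_turns:
            toks = tokenize(turn.text)
            n_sent = len(sentences(turn.text))
            n_cplx = sum(count_syllables(w) >= 3 for w in toks)
            fogs.append(0.4 * (len(toks) / n_sent + 100 * n_cplx / len(toks)))
        assert extract_text(t)["gunning_fog_complexity"] == pytest.approx(
            np.mean(fogs))

    def test_planted_filler_rate_recovered(self, rng):
        t = synth_transcript(dict(BASE_PARAMS, filler_rate=0.3,
                                  response_dur=30.0), rng)
        assert extract_text(t)["hesitations_per_s"] == pytest.approx(
            0.3, abs=0.1)


class TestFastFeatureTable:
    def test_table_has_all_features_per_session(self):
        cfg = CohortConfig(n_participants=10, mean_sessions=2.0, seed=3)
        truth = simulate_truth(cfg)
        table = feature_table_from_params(truth, cfg)
        assert len(table) == len(truth)
        from convodx.registry import ALL_FEATURES
        assert all(f in table.columns for f in ALL_FEATURES)

    def test_mapped_features_track_parameters(self):
        cfg = CohortConfig(n_participants=60, mean_sessions=1.0, seed=9)
        truth = simulate_truth(cfg)
        table = feature_table_from_params(truth, cfg)
        for feat, param in (("pitch_mean", "f0_mean"),
                            ("vol_std", "rms_wander"),
                            ("eyelid_droop", "droop_baseline")):
            r = np.corrcoef(table[feat], truth[param])[0, 1]
            assert r > 0.9, (feat, r)
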