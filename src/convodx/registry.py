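"""Canonical registry of the 66 session-level features.

The feature library is partitioned into 13 visual, 28 acoustic and 25
linguistic features.  The registry is frozen: extractors must return exactly
these names, and the correlation stage uses the modality partition for its
significance-count table denominators.

Each entry also records the temporal aggregation unit used to produce the
session-level value (``per_second``, ``per_frame``, ``per_response`` or
``per_event``).
"""

from __future__ import annotations

import pandas as pd

VISUAL_FEATURES: dict[str, str] = {
    "affect_measure": "per_frame",
    "mouth_curvature": "per_frame",
    "eyebrow_droop": "per_frame",
    "gaze_down_dist": "per_frame",
    "gaze_x_dist": "per_frame",
    "gaze_y_dist": "per_frame",
    "movement_speech_measure": "per_second",
    "eyelid_droop": "per_frame",
    "blinks_per_s": "per_second",
    "blink_len": "per_event",
    "yawns_per_s": "per_second",
    "yawn_len": "per_event",
    "eye_movements_per_s": "per_second",
}

ACOUSTIC_FEATURES: dict[str, str] = {
    "pitch_mean": "per_response",
    "pitch_std": "per_response",
    "pitch_range": "per_response",
    "pitch_slope": "per_response",
    "vol_mean": "per_response",
    "vol_std": "per_response",
    "vol_range": "per_response",
    "vol_slope": "per_response",
    "ealvi": "per_response",
    "jitter_local": "per_response",
    "jitter_rap": "per_response",
    "shimmer_local": "per_response",
    "shimmer_db": "per_response",
    "hnr_mean": "per_response",
    "spectral_centroid_mean": "per_response",
    "spectral_centroid_std": "per_response",
    "spectral_bandwidth_mean": "per_response",
    "spectral_flatness_mean": "per_response",
    "spectral_rolloff_mean": "per_response",
    "f1_mean": "per_response",
    "f2_mean": "per_response",
    "f3_mean": "per_response",
    "f1_std": "per_response",
    "f2_std": "per_response",
    "f2_f1_ratio": "per_response",
    "pause_rate": "per_second",
    "pause_mean_len": "per_event",
    "voiced_fraction": "per_response",
}

TEXT_FEATURES: dict[str, str] = {
    "words_per_s": "per_second",
    "response_latency_mean": "per_response",
    "response_latency_std": "per_response",
    "transcript_len_words": "per_response",
    "mean_response_len_words": "per_response",
    "ari_complexity": "per_response",
    "fk_complexity": "per_response",
    "gunning_fog_complexity": "per_response",
    "sentiment_mean": "per_response",
    "sentiment_std": "per_response",
    "emotion_keyword_prop": "per_response",
    "positive_emotion_prop": "per_response",
    "negative_emotion_prop": "per_response",
    "hesitations_per_s": "per_second",
    "hesitation_prop": "per_response",
    "transcript_pause_rate": "per_second",
    "transcript_pause_mean_len": "per_event",
    "type_token_ratio": "per_response",
    "mean_word_len": "per_response",
    "mean_sentence_len": "per_response",
    "first_person_singular_prop": "per_response",
    "negation_prop": "per_response",
    "content_word_prop": "per_response",
    "syllables_per_word": "per_response",
    "long_word_prop": "per_response",
}

#: feature name -> modality tag used in the shared output CSV
FEATURE_MODALITY: dict[str, str] = {
    **{name: "visual" for name in VISUAL_FEATURES},
    **{name: "audio" for name in ACOUSTIC_FEATURES},
    **{name: "text" for name in TEXT_FEATURES},
}

#: modality -> denominator for the significance-count table
MODALITY_COUNTS: dict[str, int] = {
    "visual": len(VISUAL_FEATURES),
    "audio": len(ACOUSTIC_FEATURES),
    "text": len(TEXT_FEATURES),
}

ALL_FEATURES: tuple[str, ...] = tuple(FEATURE_MODALITY)


def feature_registry() -> pd.DataFrame:
    """Return the registry as a DataFrame (feature, modality, aggregation)."""
    agg = {**VISUAL_FEATURES, **ACOUSTIC_FEATURES, **TEXT_FEATURES}
    return pd.DataFrame(
        {
            "feature": list(ALL_FEATURES),
            "modality": [FEATURE_MODALITY[f] for f in ALL_FEATURES],
            "aggregation": [agg[f] for f in ALL_FEATURES],
        }
    )
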