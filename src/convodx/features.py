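"""Session-level feature extraction: one 66-feature vector per session.

Normalizes the session temporally (30 fps landmark interpolation, 22,050 Hz
audio resampling) and runs the three modality extractors.  Output is
available both as a wide dict and as long-form CSV rows
(participant_id, session_id, feature, modality, value).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .acoustic import extract_acoustic
from .config import AnalysisConfig
from .registry import ALL_FEATURES, FEATURE_MODALITY
from .session import Session, interpolate_stream, read_session, resample_audio
from .text import extract_text
from .visual import extract_visual


def extract_features(session: Session,
                     config: AnalysisConfig | None = None) -> dict[str, float]:
    """All 66 features for one session (``nan`` marks undefined values)."""
    cfg = config or AnalysisConfig()
    stream = interpolate_stream(session.landmark_stream, cfg.target_fps)
    tracks = [resample_audio(t, cfg.target_sample_rate)
              for t in session.audio_tracks]

    out: dict[str, float] = {}
    out.update(extract_visual(stream, session.transcript, cfg))
    out.update(extract_acoustic(tracks, cfg))
    out.update(extract_text(session.transcript, cfg))
    assert set(out) == set(ALL_FEATURES)
    return out


def features_long(session: Session, values: dict[str, float]) -> pd.DataFrame:
    """Long-form rows for the shared feature CSV."""
    sid = f"{session.participant_id}@{session.session_timestamp}"
    return pd.DataFrame([{
        "participant_id": session.participant_id,
        "session_id": sid,
        "feature": f,
        "modality": FEATURE_MODALITY[f],
        "value": values[f],
    } for f in ALL_FEATURES])


def extract_bundles(bundle_dirs: list[Path],
                    config: AnalysisConfig | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Extract features for a list of session bundles.

    Corrupt or invalid bundles are skipped and reported in the returned
    list of error strings; valid sessions are unaffected.  Returns
    (wide feature table, clinical score table, errors).
    """
    wide_rows, score_rows, errors = [], [], []
    for path in bundle_dirs:
        try:
            session = read_session(path)
            values = extract_features(session, config)
        except Exception as exc:   # fault isolation per bundle
            errors.append(f"{Path(path).name}: {exc}")
            continue
        wide_rows.append({
            "participant_id": session.participant_id,
            "session_id": Path(path).name,
            "session_timestamp": session.session_timestamp,
            **values,
        })
        score_rows.append({
            "participant_id": session.participant_id,
            "session_id": Path(path).name,
            "session_timestamp": session.session_timestamp,
            **session.clinical_scores.as_dict(),
        })
    wide = pd.DataFrame(wide_rows)
    scores = pd.DataFrame(score_rows)
    return wide, scores, errors


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    long = wide.melt(
        id_vars=[c for c in ("participant_id", "session_id",
                             "session_timestamp") if c in wide.columns],
        value_vars=[f for f in ALL_FEATURES if f in wide.columns],
        var_name="feature", value_name="value")
    long["modality"] = long["feature"].map(FEATURE_MODALITY)
    return long


def missing_count(wide: pd.DataFrame) -> int:
    cols = [f for f in ALL_FEATURES if f in wide.columns]
    return int(np.isnan(wide[cols].to_numpy(dtype=float)).sum())
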