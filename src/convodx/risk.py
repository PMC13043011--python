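"""Within-person composite risk score.

For a participant with repeated sessions, each feature found significant
for a clinical measure at baseline is z-scored against that participant's
own across-session mean and SD, the z-scores are sign-aligned with the
direction of the feature's baseline correlation, and the aligned deviations
are summed per session.  The resulting trajectory is an interpretable index
of deviation from the participant's personal baseline: positive values mean
the session moved in the direction associated with higher symptom severity.

The feature set for a measure is drawn from the measure's *total* score
(not subscales); correlation signs are frozen into the series metadata so a
reported trajectory stays reproducible as correlations are re-estimated.
A composite over a single feature is still emitted, with a warning, since a
one-feature "composite" is of limited meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlate import CorrelationResult

#: friendly measure names accepted by the risk stage
MEASURE_ALIASES = {"depression": "phq9", "fatigue": "cfs_total",
                   "cognition": "tmt_total"}


@dataclass
class RiskSeries:
    participant_id: str
    measure: str
    timestamps: list[str]
    scores: np.ndarray                       # (n_sessions,)
    contributions: pd.DataFrame              # sessions x features
    feature_signs: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "measure": self.measure,
            "session_timestamp": self.timestamps,
            "risk_score": self.scores,
        })


def zscore_within(values: np.ndarray) -> np.ndarray:
    """Within-participant z-scores (sample SD); an all-constant series maps
    to all zeros.  Requires at least 2 sessions."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("within-person z-scores need >= 2 sessions")
    sd = np.nanstd(v, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return np.zeros(len(v))
    return (v - np.nanmean(v)) / sd


def significant_features(correlation_results: list[CorrelationResult],
                         measure: str) -> dict[str, int]:
    """feature -> correlation sign for features significant on ``measure``."""
    measure = MEASURE_ALIASES.get(measure, measure)
    return {r.feature: (1 if r.r >= 0 else -1)
            for r in correlation_results
            if r.measure == measure and r.significant and np.isfinite(r.r)}


def composite_risk(feature_series: pd.DataFrame,
                   correlation_results: list[CorrelationResult],
                   measure: str) -> RiskSeries:
    """Composite risk trajectory for one participant's session series.

    ``feature_series``: one row per session (time-ordered), feature columns.
    Missing feature values contribute 0 to that session's score and are
    flagged via a warning.
    """
    signs = significant_features(correlation_results, measure)
    if not signs:
        raise ValueError(
            f"no significant features for measure {measure!r}; "
            "composite risk score is undefined")
    if len(signs) == 1:
        warnings.warn(
            f"only one significant feature for {measure!r}; the composite "
            "reduces to a single z-scored feature", stacklevel=2)
    if len(feature_series) < 2:
        raise ValueError("risk series needs >= 2 sessions")
    pids = feature_series["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("feature_series must contain a single participant")

    contrib = {}
    n_missing = 0
    for feat, sign in signs.items():
        vals = feature_series[feat].to_numpy(dtype=float)
        z = zscore_within(vals)
        missing = ~np.isfinite(vals) | ~np.isfinite(z)
        n_missing += int(missing.sum())
        z = np.where(missing, 0.0, z)
        contrib[feat] = sign * z
    if n_missing:
        warnings.warn(f"{n_missing} missing feature values contributed 0 "
                      "to the risk score", stacklevel=2)

    contributions = pd.DataFrame(contrib,
                                 index=range(len(feature_series)))
    scores = contributions.to_numpy().sum(axis=1)
    return RiskSeries(
        participant_id=str(pids[0]),
        measure=MEASURE_ALIASES.get(measure, measure),
        timestamps=list(feature_series["session_timestamp"]),
        scores=scores,
        contributions=contributions,
        feature_signs=signs,
    )


def risk_report(feature_table: pd.DataFrame,
                correlation_results: list[CorrelationResult],
                measures: tuple[str, ...] = ("depression", "fatigue"),
                ) -> pd.DataFrame:
    """Longitudinal risk table for every participant with >= 2 sessions.

    Returns a long DataFrame (participant, measure, session_timestamp,
    risk_score); empty with a diagnostic attribute when nobody is eligible.
    """
    frames = []
    for pid, group in feature_table.groupby("participant_id", sort=True):
        if len(group) < 2:
            continue
        group = group.sort_values("session_timestamp", kind="stable")
        for measure in measures:
            try:
                series = composite_risk(group, correlation_results, measure)
            except ValueError:
                continue
            frames.append(series.to_frame())
    if not frames:
        out = pd.DataFrame(columns=["participant_id", "measure",
                                    "session_timestamp", "risk_score"])
        out.attrs["diagnostic"] = "no eligible participants (>= 2 sessions)"
        return out
    return pd.concat(frames, ignore_index=True)
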