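"""Extract the 66-feature vector from one synthetic check-in session.

Renders a full session (landmark stream, four response audio tracks, timed
transcript) from known generator parameters, runs the three modality
extractors, and compares a few recovered features against the planted
ground truth.
"""

import numpy as np

from convodx.features import extract_features
from convodx.synth import CohortConfig, render_session, simulate_truth

cfg = CohortConfig(n_participants=2, mean_sessions=1.0, seed=7,
                   param_overrides={"response_dur": 4.0})
truth = simulate_truth(cfg)
row = truth.iloc[0]
session = render_session(row, np.random.default_rng(7))
features = extract_features(session)

print(f"session {row['session_id']}: {len(features)} features extracted\n")
print(f"{'feature':<18}{'extracted':>12}{'planted':>12}")
for feat, param in [("pitch_mean", "f0_mean"), ("vol_mean", "rms_level"),
                    ("vol_std", "rms_wander"), ("jitter_local", "jitter_eps"),
                    ("f2_mean", "f2"), ("eyelid_droop", "droop_baseline"),
                    ("blinks_per_s", "blink_rate"),
                    ("words_per_s", "speech_rate")]:
    print(f"{feat:<18}{features[feat]:>12.4f}{row[param]:>12.4f}")

n_missing = sum(np.isnan(v) for v in features.values())
print(f"\n{n_missing} features undefined on this session (reported as "
      "missing, never silent zeros).")
print("Each extracted value estimates the matching generator parameter: "
      "agreement here is the end-to-end extraction round trip.")
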