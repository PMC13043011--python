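"""Synthetic check-in cohort with planted feature-symptom couplings.

The generator emulates the study conditions end to end: per participant it
draws correlated latent severities for depression, fatigue and cognition;
per session it maps the latents (plus AR(1) session-to-session wander)
through a standardized effect matrix into physical generator parameters
(voice pitch and level trajectory, source perturbation, formant targets,
blink/yawn rates, eyelid droop, speech rate, lexical make-up, ...); and it
renders each session as a standard bundle: source-filter audio, an
irregularly sampled 478-landmark / 52-blendshape stream, a timed 5-agent /
4-participant transcript, and clinical scores (PHQ-9, CFS subscales, TMT)
that are monotone noisy maps of the same latents, clipped to instrument
ranges.

Two observation levels are exposed:

* :func:`simulate_cohort` — the session truth table, optionally rendered to
  full bundle directories (used for extraction round-trip testing).
* :func:`feature_table_from_params` — a fast parameter-level feature table
  in which each registry feature is its generator-parameter counterpart
  plus measurement noise (readability indices are derived from the
  sentence-length and long-word parameters through the published formulas).
  This is the level used for statistical calibration experiments, where
  thousands of sessions are needed and waveform rendering adds nothing to
  what is being tested.

Everything is a pure function of the seed: the same config yields
byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, lfilter

from .registry import ALL_FEATURES
from .session import (AudioTrack, ClinicalScores, LandmarkStream, Session,
                      Transcript, TranscriptTurn, N_LANDMARKS, N_BLENDSHAPES,
                      BLENDSHAPE_INDEX, write_session)

logger = logging.getLogger(__name__)

LATENTS = ("depression", "fatigue", "cognition")

# parameter name -> (baseline, natural per-session SD, low clip, high clip)
PARAM_SPECS: dict[str, tuple[float, float, float, float]] = {
    "f0_mean": (120.0, 15.0, 75.0, 400.0),
    "f0_slope": (0.0, 2.0, -20.0, 20.0),
    "rms_level": (0.12, 0.02, 0.03, 0.5),
    "rms_slope": (0.0, 0.008, -0.05, 0.05),
    "rms_wander": (0.025, 0.008, 0.003, 0.1),
    "jitter_eps": (0.012, 0.004, 0.0, 0.06),
    "shimmer_eps": (0.06, 0.02, 0.0, 0.3),
    "f1": (520.0, 40.0, 300.0, 900.0),
    "f2": (1500.0, 120.0, 900.0, 2500.0),
    "f3": (2500.0, 120.0, 2000.0, 3400.0),
    "pause_rate": (0.25, 0.08, 0.0, 1.2),
    "pause_len": (0.45, 0.08, 0.32, 1.5),
    "blink_rate": (0.25, 0.08, 0.0, 1.5),
    "yawn_rate": (0.02, 0.01, 0.0, 0.2),
    "droop_baseline": (0.15, 0.05, 0.0, 0.29),
    "gaze_down_offset": (0.12, 0.05, 0.0, 0.8),
    "gaze_x_offset": (0.0, 0.04, -0.5, 0.5),
    "expressivity": (0.06, 0.02, 0.005, 0.3),
    "filler_rate": (0.10, 0.04, 0.0, 0.8),
    "speech_rate": (2.5, 0.3, 1.0, 5.0),
    "sentence_len": (9.0, 1.5, 4.0, 20.0),
    "long_word_prop": (0.15, 0.04, 0.0, 0.5),
    "sentiment_valence": (0.1, 0.2, -1.0, 1.0),
    "latency_mean": (1.2, 0.3, 0.2, 5.0),
    "response_dur": (7.0, 1.0, 3.0, 15.0),
}

#: default standardized effect matrix; signs follow the couplings the
#: baseline correlation stage is expected to recover (higher pitch, rising
#: volume, reduced volume variability and simpler language with depression;
#: the same voice pattern plus raised F2 and eyelid droop with fatigue;
#: amplitude instability with slower cognitive performance).
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "depression": {
        "f0_mean": 0.5, "rms_slope": 0.5, "rms_wander": -0.5,
        "sentence_len": -0.4, "long_word_prop": -0.4,
        "sentiment_valence": -0.3,
    },
    "fatigue": {
        "f0_mean": 0.5, "rms_slope": 0.5, "rms_wander": -0.5, "f2": 0.5,
        "sentence_len": -0.3, "long_word_prop": -0.3,
        "droop_baseline": 0.5, "yawn_rate": 0.3, "blink_rate": -0.3,
    },
    "cognition": {
        "shimmer_eps": 0.5, "latency_mean": 0.3,
    },
}


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_participants: int = 8
    mean_sessions: float = 3.0       # sessions = 1 + Poisson(mean - 1)
    seed: int = 0
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_EFFECTS.items()})
    latent_corr_dep_fat: float = 0.5
    latent_corr_cog: float = 0.2
    ar1_rho: float = 0.7             # session-level latent wander
    wander_sd: float = 0.3
    meas_noise: float = 0.3          # measurement noise, in param-SD units
    start_date: str = "2025-03-06"
    #: per-parameter baseline overrides (e.g. shorter responses)
    param_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for name in self.param_overrides:
            if name not in PARAM_SPECS:
                raise ValueError(f"unknown generator parameter {name!r}")
        for latent, effs in self.effects.items():
            if latent not in LATENTS:
                raise ValueError(f"unknown latent {latent!r}")
            for p, slope in effs.items():
                if p not in PARAM_SPECS:
                    raise ValueError(f"unknown generator parameter {p!r}")
                if not np.isfinite(slope):
                    raise ValueError(f"effect slope for {p!r} is not finite")


@dataclass
class GeneratorParams:
    """Per-session ground-truth parameters (see :data:`PARAM_SPECS`)."""

    values: dict[str, float]

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None


# ---------------------------------------------------------------------------
# latent -> parameter model

def _latent_chol(config: CohortConfig) -> np.ndarray:
    c, d = config.latent_corr_cog, config.latent_corr_dep_fat
    cov = np.array([[1.0, d, c], [d, 1.0, c], [c, c, 1.0]])
    return np.linalg.cholesky(cov)


def params_from_latents(latents: np.ndarray, config: CohortConfig,
                        rng: np.random.Generator) -> dict[str, float]:
    """One session's GeneratorParams from a (3,) latent vector.

    Each parameter is ``baseline + scale * (sum_l beta_lp * latent_l +
    residual)`` with residual SD chosen so the parameter's total variance
    stays near one (in scale units); values are clipped into their physical
    ranges and clips are counted through the module logger.
    """
    out = {}
    n_clipped = 0
    for name, (base, scale, lo, hi) in PARAM_SPECS.items():
        base = config.param_overrides.get(name, base)
        drift = sum(config.effects.get(latent, {}).get(name, 0.0) * latents[i]
                    for i, latent in enumerate(LATENTS))
        beta2 = sum(config.effects.get(latent, {}).get(name, 0.0) ** 2
                    for latent in LATENTS)
        resid = np.sqrt(max(1.0 - beta2, 0.05))
        raw = base + scale * (drift + resid * rng.standard_normal())
        val = float(np.clip(raw, lo, hi))
        if val != raw:
            n_clipped += 1
        out[name] = val
    if n_clipped:
        logger.warning("clipped %d generator parameters into range",
                       n_clipped)
    return out


def clinical_from_latents(latents: np.ndarray,
                          rng: np.random.Generator) -> ClinicalScores:
    """Noisy monotone instrument maps of the latent severities."""
    dep, fat, cog = latents
    phq9 = int(np.clip(round(8 + 4 * dep + 1.5 * rng.standard_normal()),
                       0, 27))
    phys = int(np.clip(round(12 + 4 * fat + 1.2 * rng.standard_normal()),
                       0, 28))
    aff = int(np.clip(round(7 + 2.5 * fat + 1.0 * rng.standard_normal()),
                      0, 16))
    cogn = int(np.clip(round(7 + 2.5 * (0.6 * fat + 0.4 * cog)
                             + 1.0 * rng.standard_normal()), 0, 16))
    tmt_a = float(np.exp(3.2 + 0.25 * cog + 0.10 * rng.standard_normal()))
    tmt_b = float(np.exp(4.0 + 0.30 * cog + 0.10 * rng.standard_normal()))
    return ClinicalScores(
        phq9_total=phq9, cfs_total=phys + aff + cogn, cfs_physical=phys,
        cfs_affective=aff, cfs_cognitive=cogn,
        tmt_a_seconds=tmt_a, tmt_b_seconds=tmt_b)


# ---------------------------------------------------------------------------
# cohort truth table

def simulate_truth(config: CohortConfig) -> pd.DataFrame:
    """One row per session: latents, generator parameters, clinical scores."""
    rng = np.random.default_rng(config.seed)
    chol = _latent_chol(config)
    t0 = datetime.fromisoformat(config.start_date)
    rows = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:03d}"
        base = chol @ rng.standard_normal(3)
        n_sessions = 1 + rng.poisson(max(config.mean_sessions - 1.0, 0.0))
        wander = np.zeros(3)
        day = float(rng.uniform(0, 10))
        for s in range(n_sessions):
            if s > 0:
                wander = (config.ar1_rho * wander
                          + config.wander_sd
                          * np.sqrt(1 - config.ar1_rho ** 2)
                          * rng.standard_normal(3))
                day += float(rng.uniform(2, 10))
            latents = base + wander
            params = params_from_latents(latents, config, rng)
            clinical = clinical_from_latents(latents, rng)
            rows.append({
                "participant_id": pid,
                "session_id": f"{pid}-s{s + 1:02d}",
                "session_index": s,
                "session_timestamp": (t0 + timedelta(days=day)).isoformat(),
                **{f"latent_{n}": latents[i] for i, n in enumerate(LATENTS)},
                **params,
                **clinical.as_dict(),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fast parameter-level feature table

# feature -> generator parameter it estimates (identity maps)
_DIRECT_MAP: dict[str, str] = {
    "pitch_mean": "f0_mean", "pitch_slope": "f0_slope",
    "vol_mean": "rms_level", "vol_std": "rms_wander",
    "vol_slope": "rms_slope",
    "jitter_local": "jitter_eps", "shimmer_local": "shimmer_eps",
    "f1_mean": "f1", "f2_mean": "f2", "f3_mean": "f3",
    "pause_rate": "pause_rate", "pause_mean_len": "pause_len",
    "transcript_pause_rate": "pause_rate",
    "transcript_pause_mean_len": "pause_len",
    "eyelid_droop": "droop_baseline", "blinks_per_s": "blink_rate",
    "yawns_per_s": "yawn_rate", "gaze_down_dist": "gaze_down_offset",
    "gaze_y_dist": "gaze_down_offset", "affect_measure": "expressivity",
    "words_per_s": "speech_rate", "hesitations_per_s": "filler_rate",
    "response_latency_mean": "latency_mean",
    "mean_sentence_len": "sentence_len", "long_word_prop": "long_word_prop",
    "sentiment_mean": "sentiment_valence",
}

# features without a parameter counterpart: (baseline, SD) of pure noise
_UNMAPPED: dict[str, tuple[float, float]] = {
    "pitch_std": (12.0, 3.0), "pitch_range": (45.0, 10.0),
    "vol_range": (0.09, 0.02), "ealvi": (0.2, 0.05),
    "jitter_rap": (0.008, 0.002), "shimmer_db": (0.5, 0.12),
    "hnr_mean": (12.0, 2.5),
    "spectral_centroid_mean": (1600.0, 150.0),
    "spectral_centroid_std": (250.0, 50.0),
    "spectral_bandwidth_mean": (1400.0, 150.0),
    "spectral_flatness_mean": (0.25, 0.06),
    "spectral_rolloff_mean": (3200.0, 300.0),
    "f1_std": (60.0, 15.0), "f2_std": (140.0, 30.0),
    "voiced_fraction": (0.55, 0.08),
    "mouth_curvature": (0.05, 0.03), "eyebrow_droop": (0.12, 0.04),
    "gaze_x_dist": (0.06, 0.02), "movement_speech_measure": (0.13, 0.03),
    "blink_len": (0.18, 0.04), "yawn_len": (2.2, 0.4),
    "eye_movements_per_s": (0.5, 0.15),
    "response_latency_std": (0.4, 0.12), "sentiment_std": (0.2, 0.06),
    "type_token_ratio": (0.6, 0.06),
    "first_person_singular_prop": (0.08, 0.02),
    "negation_prop": (0.03, 0.01), "content_word_prop": (0.55, 0.05),
}


def feature_table_from_params(truth: pd.DataFrame,
                              config: CohortConfig | None = None,
                              rng: np.random.Generator | None = None
                              ) -> pd.DataFrame:
    """Parameter-level 66-feature table for each session in ``truth``.

    Directly mapped features are the generator parameter plus Gaussian
    measurement noise of ``meas_noise`` parameter-SDs; composite features
    (readability indices, hesitation proportion, keyword proportions, word
    statistics) are deterministic functions of the relevant parameters plus
    noise; the remaining features are pure baseline + noise, uncoupled from
    the latents.
    """
    cfg = config or CohortConfig()
    rng = rng or np.random.default_rng(cfg.seed + 1)
    m = cfg.meas_noise
    n = len(truth)

    def noise(sd: float) -> np.ndarray:
        return sd * rng.standard_normal(n)

    out = pd.DataFrame({
        "participant_id": truth["participant_id"].to_numpy(),
        "session_id": truth["session_id"].to_numpy(),
        "session_timestamp": truth["session_timestamp"].to_numpy(),
    })

    for feat in ALL_FEATURES:
        if feat in _DIRECT_MAP:
            p = _DIRECT_MAP[feat]
            scale = PARAM_SPECS[p][1]
            vals = truth[p].to_numpy(dtype=float)
            if feat in ("gaze_y_dist",):    # shares the downward offset
                vals = vals + 0.02
            out[feat] = vals + noise(m * scale)
        elif feat in _UNMAPPED:
            base, sd = _UNMAPPED[feat]
            out[feat] = base + noise(sd)

    sent_len = truth["sentence_len"].to_numpy(dtype=float)
    lwp = truth["long_word_prop"].to_numpy(dtype=float)
    rate = truth["speech_rate"].to_numpy(dtype=float)
    dur = truth["response_dur"].to_numpy(dtype=float)
    fill = truth["filler_rate"].to_numpy(dtype=float)
    val = truth["sentiment_valence"].to_numpy(dtype=float)

    syl_per_word = 1.0 + 2.2 * lwp
    chars_per_word = 3.2 + 4.0 * lwp
    out["syllables_per_word"] = syl_per_word + noise(0.03)
    out["mean_word_len"] = chars_per_word + noise(0.1)
    out["gunning_fog_complexity"] = (0.4 * (sent_len + 100.0 * lwp)
                                     + noise(0.4))
    out["fk_complexity"] = (0.39 * sent_len + 11.8 * syl_per_word - 15.59
                            + noise(0.4))
    out["ari_complexity"] = (4.71 * chars_per_word + 0.5 * sent_len - 21.43
                             + noise(0.4))
    out["hesitation_prop"] = np.clip(fill / rate + noise(0.01), 0, 1)
    out["transcript_len_words"] = 4 * rate * dur + noise(8.0)
    out["mean_response_len_words"] = rate * dur + noise(2.0)
    pos = np.clip(0.05 * (1 + 0.8 * val) + noise(0.008), 0, 1)
    neg = np.clip(0.05 * (1 - 0.8 * val) + noise(0.008), 0, 1)
    out["positive_emotion_prop"] = pos
    out["negative_emotion_prop"] = neg
    out["emotion_keyword_prop"] = pos + neg
    out["f2_f1_ratio"] = (truth["f2"].to_numpy(dtype=float)
                          / truth["f1"].to_numpy(dtype=float) + noise(0.05))

    missing = set(ALL_FEATURES) - set(out.columns)
    assert not missing, f"feature table incomplete: {missing}"
    return out[["participant_id", "session_id", "session_timestamp",
                *ALL_FEATURES]]


# ---------------------------------------------------------------------------
# waveform / landmark / transcript rendering

_AGENT_PROMPTS = [
    "Hello, it is good to see you again. How are you feeling today?",
    "Thanks for sharing that. What has been on your mind lately?",
    "I hear you. How has your energy been over the past few days?",
    "That makes sense. Is there anything you are looking forward to?",
    "Thank you for checking in today. Take care of yourself.",
]

_MONO_BANK = ("day work time sleep week home walk food rest plan team talk "
              "thing way life road trip desk job task mind pace step goal "
              "note drive lunch break shift friend week car night light "
              "phone room book game run gym train coach test "
              "i my the a and was had not this that with for on it").split()
_POLY_BANK = ("operational exercises responsibilities communication "
              "continuing evaluation performance scheduling organization "
              "preparation opportunity equipment documentation recovery "
              "situation administrative coordination expectation "
              "development assignment").split()
_POS_BANK = ("good great hopeful calm rested motivated confident grateful "
             "positive fine").split()
_NEG_BANK = ("tired stressed worried down exhausted frustrated anxious "
             "drained low upset").split()
_FILLER_BANK = ("um", "uh", "hmm")


def _smooth_noise(n: int, sd: float, corr_len: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise low-passed to a correlation length, rescaled to sd."""
    if n <= 0:
        return np.zeros(0)
    w = np.hanning(max(corr_len, 3))
    x = fftconvolve(rng.standard_normal(n + len(w)), w / w.sum(),
                    mode="same")[:n]
    s = x.std()
    return x / s * sd if s > 0 else np.zeros(n)


def synth_audio(params: GeneratorParams | dict, duration: float,
                rng: np.random.Generator, sample_rate: int = 22050,
                response_index: int = 1) -> AudioTrack:
    """Source-filter synthesis of one participant response.

    A glottal impulse train at the programmed f0 trajectory with per-cycle
    period (jitter) and amplitude (shimmer) perturbations is filtered
    through resonators at the formant targets, gated by silence gaps drawn
    from the pause parameters, and amplitude-shaped to the programmed RMS
    level, slope and wander.
    """
    p = params.values if isinstance(params, GeneratorParams) else params
    sr = sample_rate
    n = int(round(duration * sr))
    t_mid = duration / 2.0

    # impulse train with per-cycle perturbations
    src = np.zeros(n)
    t = 0.0
    while t < duration:
        f0 = p["f0_mean"] + p["f0_slope"] * (t - t_mid)
        f0 = float(np.clip(f0, 40.0, 600.0))
        i = int(t * sr)
        if i < n:
            src[i] = 1.0 + p["shimmer_eps"] * rng.standard_normal()
        t += (1.0 + p["jitter_eps"] * rng.standard_normal()) / f0

    # glottal spectral tilt: two leaky integrators give the source a smooth
    # ~-12 dB/oct roll-off, as in natural voicing
    src = lfilter([1.0], [1.0, -0.93], src)
    src = lfilter([1.0], [1.0, -0.93], src)

    # formant resonator cascade
    y = src
    for f, bw in ((p["f1"], 80.0), (p["f2"], 110.0), (p["f3"], 150.0)):
        r = np.exp(-np.pi * bw / sr)
        theta = 2 * np.pi * f / sr
        y = lfilter([1.0 - r], [1.0, -2 * r * np.cos(theta), r ** 2], y)

    # silence gaps from the pause parameters
    mask = np.ones(n)
    n_pauses = rng.poisson(p["pause_rate"] * duration)
    starts = np.sort(rng.uniform(0.12, 0.82, size=n_pauses)) * duration
    prev_end = 0.0
    ramp = int(0.01 * sr)
    for s in starts:
        L = float(np.clip(rng.normal(p["pause_len"], 0.08), 0.33, 2.0))
        if s < prev_end + 0.4 or s + L > duration - 0.3:
            continue
        i0, i1 = int(s * sr), int((s + L) * sr)
        mask[i0:i1] = 0.0
        mask[max(i0 - ramp, 0):i0] = np.linspace(1, 0, min(ramp, i0))
        mask[i1:i1 + ramp] = np.linspace(0, 1, min(ramp, n - i1))
        prev_end = s + L
    y = y * mask

    # shape to the target RMS envelope
    t_axis = np.arange(n) / sr
    target = (p["rms_level"] + p["rms_slope"] * (t_axis - t_mid)
              + _smooth_noise(n, p["rms_wander"], int(0.5 * sr), rng))
    target = np.clip(target, 0.015, None)
    win = int(0.05 * sr)
    local = np.sqrt(np.clip(
        fftconvolve(y ** 2, np.ones(win) / win, mode="same"), 0, None))
    gain = np.where(local > 1e-4, target / np.maximum(local, 1e-4), 0.0)
    y = y * gain * (mask > 0)

    y += 1e-4 * rng.standard_normal(n)
    peak = np.max(np.abs(y))
    if peak > 0.99:
        y *= 0.99 / peak
    return AudioTrack(samples=y.astype(np.float32), sample_rate=sr,
                      response_index=response_index)


def _event_times(rate: float, duration: float, min_sep: float,
                 rng: np.random.Generator) -> list[float]:
    times = np.sort(rng.uniform(0, duration, size=rng.poisson(rate * duration)))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_sep:
            kept.append(float(t))
    return kept


def synth_landmarks(params: GeneratorParams | dict, duration: float,
                    rng: np.random.Generator,
                    speech_segments: list[tuple[float, float]] | None = None
                    ) -> LandmarkStream:
    """Irregularly sampled landmark stream with programmed ocular behavior.

    Frame times advance with an instantaneous rate uniform in [30, 60] fps.
    Blink and yawn events are Poisson processes driving the eye-blink and
    jaw-open blendshapes on top of the droop baseline; gaze offsets and
    expression variability are as programmed.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    p = params.values if isinstance(params, GeneratorParams) else params

    ts = []
    t = 0.0
    while t <= duration:
        ts.append(t)
        t += 1.0 / rng.uniform(30.0, 60.0)
    times = np.array(ts)
    n = len(times)

    # base face: a ring-and-grid layout inside the image frame
    k = np.arange(N_LANDMARKS)
    ang = 2 * np.pi * k / N_LANDMARKS
    rad = 0.18 + 0.07 * ((k * 37) % 11) / 11.0
    base = np.stack([0.5 + rad * np.cos(ang),
                     0.5 + rad * np.sin(ang),
                     0.02 * np.sin(3 * ang)], axis=1)

    # rigid wander plus speech-locked translation
    wander = np.stack(
        [_smooth_noise(n, 0.004, 25, rng) for _ in range(2)], axis=1)
    speech = np.zeros(n, dtype=bool)
    for s, e in (speech_segments or []):
        speech |= (times >= s) & (times <= e)
    talk = np.stack(
        [_smooth_noise(n, 0.006, 8, rng) * speech for _ in range(2)], axis=1)
    shift = wander + talk
    lms = np.repeat(base[None, :, :], n, axis=0)
    lms[:, :, 0] += shift[:, 0:1]
    lms[:, :, 1] += shift[:, 1:2]
    lms[:, :, :2] = np.clip(lms[:, :, :2], 0.0, 1.0)

    bs = np.zeros((n, N_BLENDSHAPES))
    from .session import BLENDSHAPE_NAMES
    expr_cols = [i for i, name in enumerate(BLENDSHAPE_NAMES)
                 if not name.startswith(("eyeLook", "eyeBlink", "jawOpen"))]
    for c in expr_cols:
        bs[:, c] = np.clip(
            0.1 + _smooth_noise(n, p["expressivity"], 20, rng), 0.0, 1.0)

    # blinks: raised-cosine closures on both eye-blink channels
    blink_sig = np.full(n, p["droop_baseline"])
    for t0 in _event_times(p["blink_rate"], duration, 0.5, rng):
        w = rng.uniform(0.15, 0.35)
        inside = (times >= t0) & (times <= t0 + w)
        phase = (times[inside] - t0) / w
        blink_sig[inside] = np.maximum(
            blink_sig[inside], 0.95 * np.sin(np.pi * phase))
    for name in ("eyeBlinkLeft", "eyeBlinkRight"):
        bs[:, BLENDSHAPE_INDEX[name]] = np.clip(blink_sig, 0.0, 1.0)

    # yawns: trapezoidal jaw openings; light jaw flutter during speech
    jaw = np.clip(0.12 + _smooth_noise(n, 0.05, 10, rng) * speech, 0.0, 0.35)
    for t0 in _event_times(p["yawn_rate"], duration, 4.0, rng):
        w = rng.uniform(2.0, 2.8)
        inside = (times >= t0) & (times <= t0 + w)
        phase = (times[inside] - t0) / w
        jaw[inside] = np.maximum(
            jaw[inside], 0.85 * np.clip(np.sin(np.pi * phase) * 3, 0, 1))
    bs[:, BLENDSHAPE_INDEX["jawOpen"]] = np.clip(jaw, 0.0, 1.0)

    # gaze: downward offset, horizontal offset, saccade-like jumps
    down = np.clip(p["gaze_down_offset"]
                   + _smooth_noise(n, 0.03, 20, rng), 0.0, 1.0)
    for name in ("eyeLookDownLeft", "eyeLookDownRight"):
        bs[:, BLENDSHAPE_INDEX[name]] = down
    horiz = p["gaze_x_offset"] + _smooth_noise(n, 0.02, 20, rng)
    for t0 in _event_times(0.4, duration, 1.0, rng):
        inside = (times >= t0) & (times <= t0 + 0.25)
        horiz[inside] += rng.choice([-0.2, 0.2])
    right = np.clip(horiz, 0.0, 1.0)
    left = np.clip(-horiz, 0.0, 1.0)
    for name in ("eyeLookOutRight", "eyeLookInLeft"):
        bs[:, BLENDSHAPE_INDEX[name]] = right
    for name in ("eyeLookOutLeft", "eyeLookInRight"):
        bs[:, BLENDSHAPE_INDEX[name]] = left

    # quantize to 1e-4 (far below tracker noise); keeps bundles compact
    return LandmarkStream(timestamps=np.round(times, 5),
                          landmarks=np.round(lms, 4),
                          blendshapes=np.round(np.clip(bs, 0, 1), 4))


def synth_transcript(params: GeneratorParams | dict,
                     rng: np.random.Generator,
                     n_exchanges: int = 4) -> Transcript:
    """Alternating transcript: ``n_exchanges + 1`` agent messages and
    ``n_exchanges`` participant responses with word-level timings.

    Participant text is assembled from word banks to hit the programmed
    filler rate, sentence length, long-word proportion and sentiment
    valence; word timings follow the programmed speech rate and the turn
    starts follow the programmed response latency.
    """
    p = params.values if isinstance(params, GeneratorParams) else params
    turns: list[TranscriptTurn] = []
    t = 0.0
    filler_prop = min(p["filler_rate"] / p["speech_rate"], 0.5)
    p_pos = max(0.06 * (1 + 0.8 * p["sentiment_valence"]), 0.0)
    p_neg = max(0.06 * (1 - 0.8 * p["sentiment_valence"]), 0.0)

    for k in range(n_exchanges + 1):
        agent_dur = 3.0 + 0.3 * len(_AGENT_PROMPTS[k].split()) * 0.3
        turns.append(TranscriptTurn("agent", _AGENT_PROMPTS[k],
                                    start=t, end=t + agent_dur))
        t += agent_dur
        if k == n_exchanges:
            break
        latency = max(float(rng.normal(p["latency_mean"], 0.2)), 0.05)
        start = t + latency
        dur = p["response_dur"]
        n_words = max(int(round(p["speech_rate"] * dur)), 3)
        words = []
        for _ in range(n_words):
            u = rng.uniform()
            if u < filler_prop:
                words.append(rng.choice(_FILLER_BANK))
            elif u < filler_prop + p_pos:
                words.append(rng.choice(_POS_BANK))
            elif u < filler_prop + p_pos + p_neg:
                words.append(rng.choice(_NEG_BANK))
            elif rng.uniform() < p["long_word_prop"]:
                words.append(rng.choice(_POLY_BANK))
            else:
                words.append(rng.choice(_MONO_BANK))
        # sentence boundaries every ~sentence_len words
        sent_len = max(int(round(p["sentence_len"])), 2)
        pieces = []
        for i, w in enumerate(words):
            pieces.append(w)
            if (i + 1) % sent_len == 0 or i == n_words - 1:
                pieces[-1] = pieces[-1] + "."
        text = " ".join(pieces)

        # inter-word silent gaps mirroring the audio pause parameters; word
        # slots shrink so the turn still spans exactly response_dur
        gap_at = {}
        for _ in range(rng.poisson(p["pause_rate"] * dur)):
            gap_at[int(rng.integers(1, n_words))] = max(
                float(rng.normal(p["pause_len"], 0.08)), 0.5)
        total_gap = sum(gap_at.values())
        if total_gap > 0.5 * dur:
            gap_at, total_gap = {}, 0.0
        slot = (dur - total_gap) / n_words
        timings = []
        cursor = start
        for i, w in enumerate(words):
            cursor += gap_at.get(i, 0.0)
            timings.append((w, cursor, cursor + 0.75 * slot))
            cursor += slot
        end = start + dur
        turns.append(TranscriptTurn("participant", text, start=start,
                                    end=end, words=timings))
        t = end
    return Transcript(turns)


def render_session(truth_row: pd.Series | dict,
                   rng: np.random.Generator) -> Session:
    """Render one truth-table row into a full in-memory Session."""
    row = dict(truth_row)
    params = {k: float(row[k]) for k in PARAM_SPECS}
    transcript = synth_transcript(GeneratorParams(params), rng)
    p_turns = transcript.participant_turns
    tracks = [
        synth_audio(params, duration=t.end - t.start, rng=rng,
                    response_index=i + 1)
        for i, t in enumerate(p_turns)
    ]
    duration = transcript.turns[-1].end
    stream = synth_landmarks(
        params, duration, rng,
        speech_segments=[(t.start, t.end) for t in p_turns])
    clinical = ClinicalScores(
        phq9_total=int(row["phq9_total"]),
        cfs_total=int(row["cfs_total"]),
        cfs_physical=int(row["cfs_physical"]),
        cfs_affective=int(row["cfs_affective"]),
        cfs_cognitive=int(row["cfs_cognitive"]),
        tmt_a_seconds=float(row["tmt_a_seconds"]),
        tmt_b_seconds=float(row["tmt_b_seconds"]))
    return Session(
        participant_id=row["participant_id"],
        session_timestamp=row["session_timestamp"],
        landmark_stream=stream, audio_tracks=tracks,
        transcript=transcript, clinical_scores=clinical)


def simulate_cohort(config: CohortConfig,
                    out_dir: str | Path | None = None
                    ) -> tuple[pd.DataFrame, list[Path]]:
    """Simulate a cohort; optionally render every session bundle to disk.

    Returns the truth table and the list of bundle directories (empty when
    ``out_dir`` is None).  With ``out_dir`` set, a ``cohort_truth.json``
    with all latents and parameters is written alongside the bundles for
    recovery testing.
    """
    truth = simulate_truth(config)
    paths: list[Path] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        render_rng = np.random.default_rng(config.seed + 10_000)
        for _, row in truth.iterrows():
            session = render_session(row, render_rng)
            paths.append(write_session(session, out / row["session_id"]))
        (out / "cohort_truth.json").write_text(
            json.dumps({"config": {**asdict(config)},
                        "sessions": truth.to_dict(orient="records")},
                       indent=1))
    return truth, paths
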