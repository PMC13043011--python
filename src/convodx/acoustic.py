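"""Acoustic features from resampled participant-response audio.

Per response the module computes 28 features spanning intensity (frame-RMS
volume statistics, slope, and the low-volume fraction ``ealvi``), pitch
(autocorrelation f0 tracking in a configurable search range), voice-source
perturbation (jitter, shimmer, harmonics-to-noise ratio from detected
glottal-cycle peaks), short-time spectral shape (centroid, bandwidth,
flatness, rolloff), vocal-tract resonances (F1-F3 via linear-prediction
root-finding) and silence-based pauses.  Session values are the unweighted
mean over the responses, excluding responses where a feature is undefined.

Undefined values (silent track, no voiced frames, too few glottal cycles)
are ``nan`` — an explicit missing marker handled pairwise downstream.

All analysis is relative to the track's own level (silence threshold in dB
below peak frame RMS, peak picking relative to the waveform maximum), which
makes every feature except the volume statistics invariant to amplitude
scaling.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import butter, find_peaks, lfilter, resample_poly, sosfiltfilt

from .config import AcousticConfig, AnalysisConfig
from .registry import ACOUSTIC_FEATURES
from .session import AudioTrack

_EPS = 1e-12


# ---------------------------------------------------------------------------
# framing helpers

def _frames(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """(n_frames, frame) view of x; zero-pads the tail frame."""
    if len(x) < frame:
        x = np.pad(x, (0, frame - len(x)))
    n = 1 + (len(x) - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def frame_rms(track: AudioTrack,
              config: AcousticConfig | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """(frame_times, rms) for a track; times at frame centers."""
    cfg = config or AcousticConfig()
    x = track.samples.astype(np.float64)
    fr = _frames(x, cfg.frame_length, cfg.hop_length)
    rms = np.sqrt((fr ** 2).mean(axis=1))
    times = (np.arange(len(fr)) * cfg.hop_length
             + cfg.frame_length / 2) / track.sample_rate
    return times, rms


def speech_mask(rms: np.ndarray, config: AcousticConfig | None = None
                ) -> np.ndarray:
    """Frames above the silence threshold (dB relative to peak frame RMS)."""
    cfg = config or AcousticConfig()
    peak = rms.max(initial=0.0)
    if peak <= _EPS:
        return np.zeros(len(rms), dtype=bool)
    return rms > peak * 10 ** (cfg.silence_db / 20.0)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y against t."""
    t = t - t.mean()
    denom = (t ** 2).sum()
    if denom <= _EPS:
        return 0.0
    return float((t * (y - y.mean())).sum() / denom)


# ---------------------------------------------------------------------------
# volume

def volume_features(track: AudioTrack,
                    config: AcousticConfig | None = None) -> dict[str, float]:
    """vol_mean/std/range/slope and ealvi over speech frames."""
    cfg = config or AcousticConfig()
    times, rms = frame_rms(track, cfg)
    mask = speech_mask(rms, cfg)
    if not mask.any():
        return {k: np.nan for k in
                ("vol_mean", "vol_std", "vol_range", "vol_slope", "ealvi")}
    r, t = rms[mask], times[mask]
    return {
        "vol_mean": float(r.mean()),
        "vol_std": float(r.std()),
        "vol_range": float(r.max() - r.min()),
        "vol_slope": _ols_slope(t, r),
        "ealvi": ealvi(r, cfg),
    }


def ealvi(speech_rms: np.ndarray,
          config: AcousticConfig | None = None) -> float:
    """Low-volume index: fraction of speech frames whose RMS falls below
    ``ealvi_factor`` x the median speech-frame RMS."""
    cfg = config or AcousticConfig()
    if len(speech_rms) == 0:
        return np.nan
    med = float(np.median(speech_rms))
    return float((speech_rms < cfg.ealvi_factor * med).mean())


# ---------------------------------------------------------------------------
# pitch

def _acf_f0(frame: np.ndarray, sr: int, cfg: AcousticConfig,
            f_lo: float | None = None, f_hi: float | None = None
            ) -> tuple[float, float]:
    """(f0, periodicity strength) for one frame via normalized
    autocorrelation; f0 is nan when no candidate lies in the search range.
    ``f_lo``/``f_hi`` optionally narrow the search inside the global range.
    """
    x = frame - frame.mean()
    e = float((x ** 2).sum())
    if e <= _EPS:
        return np.nan, 0.0
    n = len(x)
    ac = np.correlate(x, x, mode="full")[n - 1:]
    # normalize by the energies of the overlapping segments
    c = np.cumsum(x ** 2)
    e0 = c[-1] - np.concatenate(([0.0], c[:-1]))   # energy of x[lag:]
    norm = np.sqrt(e * e0) + _EPS
    r = ac / norm

    lag_min = int(np.floor(sr / min(f_hi or cfg.f0_max, cfg.f0_max)))
    lag_max = int(np.ceil(sr / max(f_lo or cfg.f0_min, cfg.f0_min)))
    lag_max = min(lag_max, n - 2)
    if lag_max <= lag_min + 1:
        return np.nan, 0.0
    seg = r[lag_min:lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    strength = float(r[k])
    # parabolic interpolation around the peak for sub-sample lag
    if 1 <= k < len(r) - 1:
        a, b, cc = r[k - 1], r[k], r[k + 1]
        denom = a - 2 * b + cc
        delta = 0.5 * (a - cc) / denom if abs(denom) > _EPS else 0.0
        lag = k + float(np.clip(delta, -0.5, 0.5))
    else:
        lag = float(k)
    return sr / lag, strength


def pitch_track(track: AudioTrack,
                config: AcousticConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(frame_times, f0, voiced_mask).

    A frame is voiced when it is a speech frame and its periodicity strength
    exceeds the voicing threshold; f0 is nan on unvoiced frames.  The signal
    is low-passed (1.2 kHz) before autocorrelation to suppress upper-formant
    ringing, and frames whose first-pass estimate strays more than ~half an
    octave from the track median are re-searched near the median — a simple
    continuity constraint against octave and formant-period errors.
    """
    cfg = config or AcousticConfig()
    x = track.samples.astype(np.float64)
    sr = track.sample_rate
    lp = min(1200.0, 0.45 * sr)
    if len(x) > 30:
        sos = butter(4, lp / (sr / 2), output="sos")
        xf = sosfiltfilt(sos, x)
    else:
        xf = x
    fr = _frames(xf, cfg.frame_length, cfg.hop_length)
    times, rms = frame_rms(track, cfg)
    mask = speech_mask(rms, cfg)

    f0 = np.full(len(fr), np.nan)
    voiced = np.zeros(len(fr), dtype=bool)
    for i in range(len(fr)):
        if not mask[i]:
            continue
        f, s = _acf_f0(fr[i], sr, cfg)
        if s >= cfg.voicing_threshold and np.isfinite(f):
            f0[i] = f
            voiced[i] = True

    # median re-pass for outlying frames
    if voiced.sum() >= 3:
        med = float(np.median(f0[voiced]))
        for i in np.flatnonzero(voiced):
            if abs(np.log2(f0[i] / med)) > 0.4:
                f, s = _acf_f0(fr[i], sr, cfg,
                               f_lo=med / 1.4, f_hi=med * 1.4)
                if s >= cfg.voicing_threshold and np.isfinite(f):
                    f0[i] = f
                else:
                    f0[i] = np.nan
                    voiced[i] = False
    return times, f0, voiced


def pitch_features(track: AudioTrack,
                   config: AcousticConfig | None = None) -> dict[str, float]:
    cfg = config or AcousticConfig()
    times, f0, voiced = pitch_track(track, cfg)
    out = {k: np.nan for k in
           ("pitch_mean", "pitch_std", "pitch_range", "pitch_slope")}
    out["voiced_fraction"] = float(voiced.mean()) if len(voiced) else 0.0
    if voiced.sum() == 0:
        return out
    f, t = f0[voiced], times[voiced]
    out["pitch_mean"] = float(f.mean())
    out["pitch_std"] = float(f.std())
    out["pitch_range"] = float(f.max() - f.min())
    out["pitch_slope"] = _ols_slope(t, f) if voiced.sum() >= 2 else np.nan
    return out


# ---------------------------------------------------------------------------
# perturbation (jitter / shimmer / HNR)

def _cycle_peaks(x: np.ndarray, sr: int, f0_hz: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Glottal-cycle peak positions (samples) and amplitudes.

    Cycle markers are waveform maxima spaced by roughly one period of the
    track's median f0.
    """
    period = sr / f0_hz
    height = 0.3 * np.max(np.abs(x))
    peaks, _ = find_peaks(x, distance=max(int(0.7 * period), 1), height=height)
    # parabolic sub-sample refinement of position and amplitude
    pos = peaks.astype(np.float64)
    amp = x[peaks].astype(np.float64)
    inner = (peaks > 0) & (peaks < len(x) - 1)
    a, b, c = x[peaks[inner] - 1], x[peaks[inner]], x[peaks[inner] + 1]
    denom = a - 2 * b + c
    delta = np.where(np.abs(denom) > _EPS, 0.5 * (a - c) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    pos[inner] = peaks[inner] + delta
    amp[inner] = b - 0.25 * (a - c) * delta
    return pos, amp


def perturbation_features(track: AudioTrack,
                          config: AcousticConfig | None = None
                          ) -> dict[str, float]:
    """jitter_local, jitter_rap, shimmer_local, shimmer_db, hnr_mean.

    Jitter is the mean absolute consecutive-period difference over the mean
    period (RAP uses the deviation from the local 3-period average); shimmer
    is the analogous statistic on cycle peak amplitudes (relative and in
    dB).  HNR averages ``10 log10(r / (1 - r))`` of the per-frame
    periodicity strength r over voiced frames.
    """
    cfg = config or AcousticConfig()
    out = {k: np.nan for k in ("jitter_local", "jitter_rap", "shimmer_local",
                               "shimmer_db", "hnr_mean")}
    times, f0, voiced = pitch_track(track, cfg)
    if voiced.sum() == 0:
        return out

    # HNR from periodicity strength
    x = track.samples.astype(np.float64)
    fr = _frames(x, cfg.frame_length, cfg.hop_length)
    strengths = []
    for i in np.flatnonzero(voiced):
        _, s = _acf_f0(fr[i], track.sample_rate, cfg)
        s = min(max(s, _EPS), 1.0 - _EPS)
        strengths.append(10.0 * np.log10(s / (1.0 - s)))
    out["hnr_mean"] = float(np.mean(strengths))

    med_f0 = float(np.nanmedian(f0[voiced]))
    peaks, amps = _cycle_peaks(x, track.sample_rate, med_f0)
    if len(peaks) < 4:     # need >= 3 periods
        return out
    periods = np.diff(peaks).astype(np.float64)
    # discard spurious inter-peak gaps (pauses, octave errors)
    nominal = track.sample_rate / med_f0
    ok = (periods > 0.5 * nominal) & (periods < 1.5 * nominal)
    # amplitudes of the cycles bounded by kept period markers
    periods = periods[ok]
    if len(periods) < 3:
        return out
    amp_ok = amps[np.concatenate([ok, [False]]) | np.concatenate([[False], ok])]

    mean_T = periods.mean()
    out["jitter_local"] = float(np.abs(np.diff(periods)).mean() / mean_T)
    if len(periods) >= 3:
        local_avg = np.convolve(periods, np.ones(3) / 3.0, mode="valid")
        out["jitter_rap"] = float(
            np.abs(periods[1:-1] - local_avg).mean() / mean_T)

    a = np.abs(amp_ok.astype(np.float64))
    a = a[a > _EPS]
    if len(a) >= 3:
        out["shimmer_local"] = float(np.abs(np.diff(a)).mean() / a.mean())
        out["shimmer_db"] = float(
            np.abs(20.0 * np.log10(a[1:] / a[:-1])).mean())
    return out


# ---------------------------------------------------------------------------
# spectral shape

def spectral_features(track: AudioTrack,
                      config: AcousticConfig | None = None
                      ) -> dict[str, float]:
    """Short-time spectral descriptors over speech frames.

    Centroid, bandwidth and rolloff are per-frame statistics averaged over
    speech frames; flatness is computed on the across-frame mean power
    spectrum (the per-frame estimator is biased low even for white noise).
    """
    cfg = config or AcousticConfig()
    out = {k: np.nan for k in
           ("spectral_centroid_mean", "spectral_centroid_std",
            "spectral_bandwidth_mean", "spectral_flatness_mean",
            "spectral_rolloff_mean")}
    x = track.samples.astype(np.float64)
    _, rms = frame_rms(track, cfg)
    mask = speech_mask(rms, cfg)
    if not mask.any():
        return out
    fr = _frames(x, cfg.frame_length, cfg.hop_length)[mask]
    win = np.hanning(cfg.frame_length)
    spec = np.abs(np.fft.rfft(fr * win, axis=1))
    power = spec ** 2
    freqs = np.fft.rfftfreq(cfg.frame_length, d=1.0 / track.sample_rate)

    tot = spec.sum(axis=1) + _EPS
    centroid = (spec * freqs).sum(axis=1) / tot
    bandwidth = np.sqrt(
        (spec * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1) / tot)

    cum = np.cumsum(power, axis=1)
    targets = cfg.rolloff_percent * cum[:, -1:]
    roll_idx = (cum >= targets).argmax(axis=1)
    rolloff = freqs[roll_idx]

    mean_power = power.mean(axis=0)
    mean_power = mean_power / (mean_power.mean() + _EPS) + _EPS  # scale-free
    flatness = float(np.exp(np.mean(np.log(mean_power))) / mean_power.mean())

    out["spectral_centroid_mean"] = float(centroid.mean())
    out["spectral_centroid_std"] = float(centroid.std())
    out["spectral_bandwidth_mean"] = float(bandwidth.mean())
    out["spectral_flatness_mean"] = flatness
    out["spectral_rolloff_mean"] = float(rolloff.mean())
    return out


# ---------------------------------------------------------------------------
# formants

def _lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    """LPC coefficients (a1..ap) via the autocorrelation method."""
    x = frame * np.hamming(len(frame))
    r = np.correlate(x, x, mode="full")[len(x) - 1:len(x) + order]
    if r[0] <= _EPS:
        return None
    r = r + 1e-9 * r[0] * (np.arange(order + 1) == 0)   # regularize
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return None
    return a


def _frame_formants(frame: np.ndarray, sr: int, cfg: AcousticConfig
                    ) -> list[float]:
    a = _lpc(frame, cfg.lpc_order)
    if a is None:
        return []
    roots = np.roots(np.concatenate(([1.0], -a)))
    roots = roots[np.imag(roots) > 1e-3]
    freqs = np.angle(roots) * sr / (2 * np.pi)
    bws = -np.log(np.abs(roots)) * sr / np.pi
    keep = (freqs > 90) & (freqs < sr / 2 - 50) & (bws < cfg.formant_max_bw)
    return sorted(freqs[keep])


def formant_features(track: AudioTrack,
                     config: AcousticConfig | None = None) -> dict[str, float]:
    """F1-F3 statistics via LPC root-finding on voiced frames.

    Audio is decimated to the formant analysis rate (default 11,025 Hz) and
    pre-emphasized before linear prediction; LPC order 12 matches that rate.
    """
    cfg = config or AcousticConfig()
    out = {k: np.nan for k in ("f1_mean", "f2_mean", "f3_mean",
                               "f1_std", "f2_std", "f2_f1_ratio")}
    _, _, voiced = pitch_track(track, cfg)
    if voiced.sum() == 0:
        return out

    sr = cfg.formant_rate
    g = np.gcd(int(track.sample_rate), sr)
    x = resample_poly(track.samples.astype(np.float64),
                      sr // g, track.sample_rate // g)
    x = lfilter([1.0, -0.97], [1.0], x)     # pre-emphasis

    # 25 ms frames, 10 ms hop, on frames matching the voiced mask timing
    frame = int(0.025 * sr)
    hop = int(0.010 * sr)
    fr = _frames(x, frame, hop)
    rms = np.sqrt((fr ** 2).mean(axis=1))
    active = rms > rms.max(initial=0.0) * 10 ** (cfg.silence_db / 20.0)

    f123 = []
    for i in np.flatnonzero(active):
        fs = _frame_formants(fr[i], sr, cfg)
        if len(fs) >= 3:
            f123.append(fs[:3])
    if not f123:
        return out
    f123 = np.asarray(f123)
    out["f1_mean"] = float(f123[:, 0].mean())
    out["f2_mean"] = float(f123[:, 1].mean())
    out["f3_mean"] = float(f123[:, 2].mean())
    out["f1_std"] = float(f123[:, 0].std())
    out["f2_std"] = float(f123[:, 1].std())
    out["f2_f1_ratio"] = out["f2_mean"] / out["f1_mean"]
    return out


# ---------------------------------------------------------------------------
# pauses

def pause_features(track: AudioTrack,
                   config: AcousticConfig | None = None) -> dict[str, float]:
    """pause_rate (per second of response) and pause_mean_len (s).

    Pauses are maximal sub-threshold frame runs lasting at least
    ``min_pause``, excluding leading and trailing silence.  Zero pauses is a
    valid observation: the rate is 0; the mean length is then undefined
    (``nan``) and excluded from session aggregation like any missing value.
    """
    cfg = config or AcousticConfig()
    times, rms = frame_rms(track, cfg)
    mask = speech_mask(rms, cfg)
    duration = track.duration
    if not mask.any():
        return {"pause_rate": np.nan, "pause_mean_len": np.nan}
    first, last = np.flatnonzero(mask)[[0, -1]]
    silent = ~mask[first:last + 1]
    t = times[first:last + 1]

    lens = []
    start = None
    hop_dt = cfg.hop_length / track.sample_rate
    for i, s in enumerate(silent):
        if s and start is None:
            start = t[i]
        elif not s and start is not None:
            lens.append(t[i] - start)
            start = None
    lens = [L for L in lens if L >= cfg.min_pause - hop_dt / 2]
    return {
        "pause_rate": len(lens) / duration,
        "pause_mean_len": float(np.mean(lens)) if lens else np.nan,
    }


# ---------------------------------------------------------------------------
# session aggregation

def extract_acoustic(tracks: list[AudioTrack],
                     config: AnalysisConfig | None = None) -> dict[str, float]:
    """All 28 acoustic features, averaged over the responses.

    Per-response values are computed independently and combined with an
    unweighted mean; responses where a feature is undefined are excluded
    from that feature's mean.
    """
    if not tracks:
        raise ValueError("at least one response track is required")
    cfg = (config or AnalysisConfig()).acoustic

    rows = []
    for track in tracks:
        row: dict[str, float] = {}
        row.update(volume_features(track, cfg))
        row.update(pitch_features(track, cfg))
        row.update(perturbation_features(track, cfg))
        row.update(spectral_features(track, cfg))
        row.update(formant_features(track, cfg))
        row.update(pause_features(track, cfg))
        rows.append(row)

    out = {}
    for name in ACOUSTIC_FEATURES:
        vals = np.array([r[name] for r in rows], dtype=float)
        out[name] = (float(np.nanmean(vals))
                     if np.isfinite(vals).any() else np.nan)
    assert set(out) == set(ACOUSTIC_FEATURES)
    return out
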