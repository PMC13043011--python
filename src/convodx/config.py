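"""Analysis configuration: every threshold used by the extractors.

A single :class:`AnalysisConfig` governs the visual event detectors, the
acoustic frame analysis and the linguistic features, so a full run is
reproducible from one YAML file.  Defaults are standard speech/ocular
analysis values at the pipeline's working rates (30 fps video, 22,050 Hz
audio).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class VisualConfig:
    # blink detection on mean(eyeBlinkLeft, eyeBlinkRight), with hysteresis
    blink_on: float = 0.5
    blink_off: float = 0.3
    blink_min_dur: float = 0.066   # s; shorter excursions are tracker noise
    blink_max_dur: float = 0.5     # s; longer closures are not blinks
    # yawn detection on jawOpen
    yawn_on: float = 0.6
    yawn_off: float = 0.4
    yawn_min_dur: float = 1.5      # s, sustained opening
    # saccade-like gaze events
    saccade_mad_factor: float = 3.0   # velocity > factor x median |velocity|
    saccade_min_sep: float = 0.1      # s between counted events


@dataclass(frozen=True)
class AcousticConfig:
    frame_length: int = 2048       # samples at 22,050 Hz (~93 ms)
    hop_length: int = 512
    f0_min: float = 75.0           # Hz
    f0_max: float = 500.0          # Hz
    voicing_threshold: float = 0.45   # normalized autocorrelation strength
    silence_db: float = -40.0      # dB rel. peak frame RMS -> non-speech
    min_pause: float = 0.3         # s
    lpc_order: int = 12
    formant_rate: int = 11025      # Hz; formant analysis sample rate
    formant_max_bw: float = 400.0  # Hz; wider LPC roots are not formants
    rolloff_percent: float = 0.85
    ealvi_factor: float = 0.5      # frames below factor x median speech RMS


@dataclass(frozen=True)
class TextConfig:
    fillers: tuple[str, ...] = ("um", "uh", "er", "ah", "hmm", "mhm", "uhm")
    gap_min: float = 0.5           # s; inter-word gap counted as a pause
    long_word_syllables: int = 3


@dataclass(frozen=True)
class AnalysisConfig:
    target_fps: float = 30.0
    target_sample_rate: int = 22050
    visual: VisualConfig = field(default_factory=VisualConfig)
    acoustic: AcousticConfig = field(default_factory=AcousticConfig)
    text: TextConfig = field(default_factory=TextConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; missing keys keep defaults."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sub = {}
    for name, cls in (("visual", VisualConfig), ("acoustic", AcousticConfig),
                      ("text", TextConfig)):
        d = dict(raw.pop(name, {}) or {})
        if name == "text" and "fillers" in d:
            d["fillers"] = tuple(d["fillers"])
        sub[name] = cls(**d)
    return AnalysisConfig(**raw, **sub)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    d = config.to_dict()
    d["text"]["fillers"] = list(d["text"]["fillers"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
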