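"""End-to-end pipeline: simulate -> extract -> correlate -> risk score.

A single run config (YAML or dict) drives all stages; every output CSV row
is traceable to a session id recorded in the run manifest, and re-running
with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig, load_config
from .correlate import correlate_all, results_frame, select_baseline
from .features import extract_bundles, missing_count, wide_to_long
from .risk import risk_report
from .synth import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    out_dir: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "out_dir": self.out_dir,
             "stages": self.stages}, indent=1))


def _default_run_config() -> dict:
    return {
        "seed": 0,
        "cohort": {"n_participants": 8, "mean_sessions": 3.0},
        "alpha": 0.05,
        "bh": False,
        "measures": ["depression", "fatigue"],
    }


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 bundles: list[Path] | None = None) -> RunManifest:
    """Execute the full pipeline into ``out_dir``; returns the manifest.

    ``config`` may be a dict or a YAML path with keys ``seed``, ``cohort``
    (CohortConfig fields), ``analysis`` (AnalysisConfig YAML), ``alpha``,
    ``bh`` and ``measures``.  When ``bundles`` is given, the simulate stage
    is skipped and the listed session bundles are extracted instead.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = {**_default_run_config(), **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
        seed=int(cfg["seed"]), version=__version__, out_dir=str(out))
    analysis = (AnalysisConfig() if "analysis" not in cfg
                else load_config(cfg["analysis"]))

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest.record(name, status="failed", error=str(exc))
                manifest.write(out / "manifest.json")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest.stages.setdefault(name, {})
            manifest.stages[name].update(
                status="ok",
                seconds=round(time.perf_counter() - t0, 3))
            return result
        return wrap

    # --- simulate -----------------------------------------------------
    if bundles is None:
        def _simulate():
            ccfg = CohortConfig(seed=int(cfg["seed"]),
                                **cfg.get("cohort", {}))
            truth, paths = simulate_cohort(ccfg, out_dir=out / "cohort")
            truth.to_csv(out / "cohort_truth.csv", index=False)
            manifest.record("simulate", n_sessions=len(truth),
                            n_participants=truth["participant_id"].nunique(),
                            bundle_dir=str(out / "cohort"))
            return paths
        bundles = stage("simulate")(_simulate)
    else:
        manifest.record("simulate", status="skipped (external bundles)",
                        n_bundles=len(bundles))

    # --- extract ------------------------------------------------------
    def _extract():
        wide, scores, errors = extract_bundles(list(bundles), analysis)
        if wide.empty:
            raise ValueError("no session could be extracted")
        for err in errors:
            logger.warning("skipped session: %s", err)
        wide.to_csv(out / "features_wide.csv", index=False)
        wide_to_long(wide).to_csv(out / "features.csv", index=False)
        scores.to_csv(out / "scores.csv", index=False)
        manifest.record("extract", n_sessions=len(wide),
                        n_missing_values=missing_count(wide),
                        n_skipped=len(errors), skipped=errors)
        return wide, scores
    wide, scores = stage("extract")(_extract)

    # --- correlate ----------------------------------------------------
    def _correlate():
        base_feat = select_baseline(wide)
        base_scores = scores.set_index("session_id") \
            .loc[base_feat["session_id"]].reset_index()
        results, table = correlate_all(
            base_feat, base_scores, alpha=float(cfg["alpha"]),
            bh=bool(cfg["bh"]))
        rf = results_frame(results)
        rf.to_csv(out / "correlations.csv", index=False)
        table.to_csv(out / "significance_table.csv")
        manifest.record("correlate", n_results=len(rf),
                        n_significant=int(rf["significant"].sum()),
                        n_baseline=len(base_feat))
        return results
    results = stage("correlate")(_correlate)

    # --- risk score ---------------------------------------------------
    def _risk():
        report = risk_report(wide, results,
                             measures=tuple(cfg["measures"]))
        report.to_csv(out / "risk_scores.csv", index=False)
        manifest.record("riskscore", n_rows=len(report),
                        n_participants=(report["participant_id"].nunique()
                                        if len(report) else 0))
        return report
    stage("riskscore")(_risk)

    manifest.write(out / "manifest.json")
    return manifest
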