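"""Baseline correlation analysis of features against clinical measures.

The statistical stage mirrors a baseline cross-sectional design: only the
earliest session per participant enters; per feature, values more than
``k`` sample SDs from the mean are removed (single pass, mean and SD from
the full set); each surviving feature sample is Pearson-correlated with
each clinical measure and subscale, pairwise complete, with the two-sided
p-value from the t transform on ``n_used - 2`` degrees of freedom.  No
multiple-testing correction is applied by default (a Benjamini-Hochberg
option exists); the summary table counts significant features per measure
and modality against the 13/28/25 modality denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .registry import ALL_FEATURES, FEATURE_MODALITY, MODALITY_COUNTS

#: clinical measures and subscales correlated against every feature
MEASURES: dict[str, str] = {
    "phq9": "phq9_total",
    "cfs_total": "cfs_total",
    "cfs_physical": "cfs_physical",
    "cfs_affective": "cfs_affective",
    "cfs_cognitive": "cfs_cognitive",
    "tmt_a": "tmt_a_seconds",
    "tmt_b": "tmt_b_seconds",
    "tmt_total": None,     # sum of part A and part B times
}


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    measure: str
    n_used: int
    r: float
    p: float
    significant: bool

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def select_baseline(sessions: pd.DataFrame) -> pd.DataFrame:
    """Earliest session per participant.

    Ties on timestamp break to the lowest session_id (documented,
    deterministic).
    """
    df = sessions.sort_values(["session_timestamp", "session_id"],
                              kind="stable")
    return (df.groupby("participant_id", sort=True).head(1)
            .reset_index(drop=True))


def remove_outliers(values: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Boolean retention mask: drop values more than k sample SDs from the
    mean.  Mean and SD are computed once on the full sample (no
    re-iteration); a zero-SD sample retains everything.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise ValueError("outlier removal needs >= 3 non-missing values")
    mean = v[finite].mean()
    sd = v[finite].std(ddof=1)
    if sd == 0:
        return finite.copy()
    return finite & (np.abs(v - mean) <= k * sd)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """(r, two-sided p, n_used) on pairwise-complete observations.

    Returns (nan, nan, n) when fewer than 3 complete pairs remain or either
    variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p), n


def measure_values(scores: pd.DataFrame, measure: str) -> np.ndarray:
    col = MEASURES[measure]
    if col is None:    # tmt_total
        return (scores["tmt_a_seconds"].to_numpy(dtype=float)
                + scores["tmt_b_seconds"].to_numpy(dtype=float))
    return scores[col].to_numpy(dtype=float)


def correlate_all(feature_table: pd.DataFrame, score_table: pd.DataFrame,
                  alpha: float = 0.05, outlier_k: float = 2.0,
                  bh: bool = False,
                  ) -> tuple[list[CorrelationResult], pd.DataFrame]:
    """Correlate every feature with every measure on baseline rows.

    ``feature_table`` and ``score_table`` must share ``participant_id``
    ordering (one baseline row per participant).  Outlier removal is applied
    to each feature's values, independently per feature-measure pair over
    the pairwise-complete observations.  With ``bh=True``, significance is
    decided by Benjamini-Hochberg within each measure instead of raw
    ``p < alpha``.

    Returns the result list and the significance-count table (measure x
    modality, with denominators from the registry partition).
    """
    assert (feature_table["participant_id"].to_numpy()
            == score_table["participant_id"].to_numpy()).all(), \
        "feature and score tables must be aligned on participant_id"

    results: list[CorrelationResult] = []
    features_present = [f for f in ALL_FEATURES if f in feature_table.columns]
    for measure in MEASURES:
        y_all = measure_values(score_table, measure)
        m_results: list[CorrelationResult] = []
        for feat in features_present:
            x_all = feature_table[feat].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            if ok.sum() < 3:
                continue   # skipped: not enough complete pairs
            keep = np.zeros(len(x_all), dtype=bool)
            keep[ok] = remove_outliers(x_all[ok], k=outlier_k)
            r, p, n = pearson(x_all[keep], y_all[keep])
            m_results.append(CorrelationResult(
                feature=feat, measure=measure, n_used=n, r=r, p=p,
                significant=bool(np.isfinite(p) and p < alpha)))
        if bh:
            m_results = _apply_bh(m_results, alpha)
        results.extend(m_results)

    return results, significance_table(results)


def _apply_bh(results: list[CorrelationResult],
              alpha: float) -> list[CorrelationResult]:
    defined = [r for r in results if np.isfinite(r.p)]
    if not defined:
        return results
    ps = np.array([r.p for r in defined])
    order = np.argsort(ps)
    m = len(ps)
    passed = np.zeros(m, dtype=bool)
    max_k = -1
    for rank, idx in enumerate(order, start=1):
        if ps[idx] <= alpha * rank / m:
            max_k = rank
    if max_k > 0:
        passed[order[:max_k]] = True
    sig = {id(r): bool(passed[i]) for i, r in enumerate(defined)}
    return [CorrelationResult(r.feature, r.measure, r.n_used, r.r, r.p,
                              sig.get(id(r), False)) for r in results]


def significance_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Counts of significant features per measure x modality.

    Columns carry the modality denominators; every count is bounded by its
    denominator by construction.
    """
    rows = {}
    for measure in MEASURES:
        counts = {m: 0 for m in MODALITY_COUNTS}
        for r in results:
            if r.measure == measure and r.significant:
                counts[FEATURE_MODALITY[r.feature]] += 1
        rows[measure] = counts
    table = pd.DataFrame(rows).T
    table.columns = [f"{m} (n={MODALITY_COUNTS[m]})" for m in table.columns]
    table.index.name = "measure"
    return table


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature,
        "modality": FEATURE_MODALITY[r.feature],
        "measure": r.measure,
        "n_used": r.n_used,
        "r": r.r,
        "p": r.p,
        "significant": r.significant,
    } for r in results])
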