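"""Multi-day aggregation: onset detection, progression, score correlation.

Daily per-image senescence percentages become trajectories per plant; the
onset is the first day the overall percentage persistently exceeds a
threshold, the progression rate is the least-squares slope of percentage
versus day from onset onward, and treatment groups are summarized by mean
and standard deviation. Image-based percentages are related to manual
1-10 senescence scores (1 = fully green ... 10 = plant death) through an
ordinary least-squares fit of score on the natural log of the percentage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeSeriesRecord",
    "OnsetResult",
    "ScoreFit",
    "detect_onset",
    "fit_score_relationship",
    "aggregate_treatment",
    "records_from_frame",
    "load_chickpea_scores",
]

SERIES_COLUMNS = [
    "plant_id",
    "day",
    "area_px",
    "pct_overall",
    "pct_top",
    "pct_mid",
    "pct_bottom",
]


@dataclass
class TimeSeriesRecord:
    """One plant on one day (day = days after sowing)."""

    plant_id: str
    day: int
    area_px: int
    pct_overall: float
    pct_top: float = 0.0
    pct_mid: float = 0.0
    pct_bottom: float = 0.0


@dataclass
class OnsetResult:
    """Onset day (None if the threshold is never persistently exceeded),
    the decision parameters used, post-onset progression rate in percent
    per day, and the final senescent percentage."""

    plant_id: str
    onset_day: int | None
    threshold: float
    persistence: int
    progression_rate: float | None
    final_pct: float


@dataclass
class ScoreFit:
    """OLS fit of manual score s on ln(percentage p): s = a + b ln p."""

    intercept: float
    slope: float
    r_squared: float
    n: int


def records_from_frame(frame: pd.DataFrame) -> dict[str, list[TimeSeriesRecord]]:
    """Group a series table (SERIES_COLUMNS) into per-plant record lists."""
    out: dict[str, list[TimeSeriesRecord]] = {}
    for pid, sub in frame.groupby("plant_id", sort=True):
        out[str(pid)] = [
            TimeSeriesRecord(
                plant_id=str(pid),
                day=int(r.day),
                area_px=int(r.area_px),
                pct_overall=float(r.pct_overall),
                pct_top=float(getattr(r, "pct_top", 0.0)),
                pct_mid=float(getattr(r, "pct_mid", 0.0)),
                pct_bottom=float(getattr(r, "pct_bottom", 0.0)),
            )
            for r in sub.sort_values("day").itertuples()
        ]
    return out


def detect_onset(
    series: list[TimeSeriesRecord],
    threshold: float = 1.0,
    persistence: int = 2,
) -> OnsetResult:
    """Find the first day the senescent percentage persistently exceeds
    ``threshold``.

    Onset is the first observed day whose overall percentage is above the
    threshold and stays above it for the following ``persistence - 1``
    observed days; persistence suppresses single-frame noise. The
    progression rate is the least-squares slope of percentage vs day from
    onset to the last observation (None when fewer than two post-onset
    points exist or no onset is found).
    """
    if not series:
        raise ValueError("series is empty")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    days = np.array([r.day for r in series], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("series days must be strictly increasing")
    pct = np.array([r.pct_overall for r in series], dtype=float)
    above = pct > threshold
    onset_idx = None
    for i in range(len(series) - persistence + 1):
        if above[i : i + persistence].all():
            onset_idx = i
            break
    rate = None
    onset_day = None
    if onset_idx is not None:
        onset_day = int(series[onset_idx].day)
        if len(series) - onset_idx >= 2:
            rate = float(
                stats.linregress(days[onset_idx:], pct[onset_idx:]).slope
            )
    return OnsetResult(
        plant_id=series[0].plant_id,
        onset_day=onset_day,
        threshold=threshold,
        persistence=persistence,
        progression_rate=rate,
        final_pct=float(pct[-1]),
    )


def fit_score_relationship(pairs) -> ScoreFit:
    """OLS of manual score on ln(image-estimated senescent percentage).

    ``pairs`` is an iterable of (percentage, score) with percentage > 0.
    R-squared equals the squared Pearson correlation of (ln p, s), so the
    value is unchanged if the regression roles are exchanged.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (percentage, score) pairs")
    p, s = arr[:, 0], arr[:, 1]
    if np.any(p <= 0):
        raise ValueError("percentages must be > 0 for the logarithmic fit")
    lp = np.log(p)
    if np.ptp(lp) == 0:
        raise ValueError("ln(percentage) is constant; fit is degenerate")
    res = stats.linregress(lp, s)
    return ScoreFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=arr.shape[0],
    )


def aggregate_treatment(groups: dict[str, list[OnsetResult]]) -> pd.DataFrame:
    """Per-treatment summary of onset day and final senescent percentage.

    Means and sample standard deviations (n-1 denominator; 0 for
    singletons) are computed over results with a detected onset; results
    without onset are excluded from the onset statistics and counted in
    ``n_no_onset``. Final percentages are summarized over all results.
    """
    rows = []
    for name, results in groups.items():
        if not results:
            raise ValueError(f"treatment group {name!r} is empty")
        onsets = np.array(
            [r.onset_day for r in results if r.onset_day is not None], dtype=float
        )
        finals = np.array([r.final_pct for r in results], dtype=float)
        if onsets.size == 0:
            onset_mean, onset_sd = float("nan"), float("nan")
        elif onsets.size == 1:
            onset_mean, onset_sd = float(onsets[0]), 0.0
        else:
            onset_mean, onset_sd = float(onsets.mean()), float(onsets.std(ddof=1))
        rows.append(
            {
                "treatment": name,
                "n": len(results),
                "n_no_onset": len(results) - onsets.size,
                "onset_mean": onset_mean,
                "onset_sd": onset_sd,
                "final_pct_mean": float(finals.mean()),
                "final_pct_sd": float(finals.std(ddof=1)) if finals.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("treatment")


def load_chickpea_scores() -> pd.DataFrame:
    """Packaged chickpea salt-stress evaluation table.

    Columns: treatment_mM, genotype, senescent_pct (image estimate from
    the last image in each sequence), score_2day and score_3day (manual
    1-10 scores taken 2 and 3 days after the last imaging day). Rows are
    kept exactly as published, including the repeated 0.91/11.81 row.
    """
    ref = importlib.resources.files("leafsen") / "data" / "chickpea_scores.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
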