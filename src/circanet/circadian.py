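"""Circadian (minute-of-day) profiles of network metrics and day/night
bootstrap tests.

Each usable 300-s window contributes one value per metric, tagged with the
wall-clock minute of the window start and the window's behavioural state
(assigned only when at least 90% of the window shares one state).  Profiles
pool values by minute bin across subjects; a bin mean is reported only when
the bin holds at least five values.  The day/night test resamples the
"daytime" (11:00-13:00) and "nighttime" (23:00-01:00) pools with replacement
1,000 times and reports the percentile CI of the night-minus-day difference
of means; the effect is significant when the CI excludes 0.  By default the
pools are decimated to non-overlapping windows so the resampled values are
approximately independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import NetworkSeries, proportional_strength
from .graphs import clustering_onnela, normalize_by_max, shortest_paths, \
    weighted_degree
from .hypnogram import Hypnogram
from .recording import Recording

METRICS = ("strength", "degree", "clustering", "path_length")
DAY_MINUTES = (11 * 60, 13 * 60)  # [11:00, 13:00)
NIGHT_MINUTES = (23 * 60, 1 * 60)  # [23:00, 01:00), wrapping midnight
PURITY_FLOOR = 0.9
MIN_BIN_COUNT = 5


def _window_metric(W: np.ndarray, metric: str) -> float:
    if metric == "strength":
        # mean of all connections == proportional strength of the full set
        return proportional_strength(W, top_fraction=1.0)
    if metric == "degree":
        return float(weighted_degree(W).mean())
    if W.max() <= 0:
        return np.nan  # empty network: clustering/paths undefined
    Wn = normalize_by_max(W)
    if metric == "clustering":
        return float(clustering_onnela(Wn).mean())
    if metric == "path_length":
        return shortest_paths(Wn)[1]
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def metric_timecourse(series: NetworkSeries, hypnogram: Hypnogram,
                      metric: str, recording: Recording | None = None,
                      clock_start=None) -> pd.DataFrame:
    """Per-window metric values tagged with clock minute and state.

    Windows whose state purity (fraction of seconds in the majority state)
    falls below 90% are dropped.  ``clock_start`` (datetime) may be given
    directly instead of a recording.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if clock_start is None:
        if recording is None:
            raise ValueError("need the recording or its clock_start")
        clock_start = recording.clock_start
    start_of_day = (clock_start.hour * 3600 + clock_start.minute * 60
                    + clock_start.second)
    rows = []
    for w in np.flatnonzero(series.usable):
        t0 = series.window_starts[w]
        sleep_frac = hypnogram.sleep_fraction(t0, series.window_s)
        purity = max(sleep_frac, 1 - sleep_frac)
        if purity < PURITY_FLOOR:
            continue
        state = "sleep" if sleep_frac > 0.5 else "wake"
        minute = int(((start_of_day + t0) % 86400) // 60)
        value = _window_metric(series.matrix(w), metric)
        if np.isnan(value):
            continue
        rows.append({"window_start": t0, "minute": minute, "state": state,
                     "metric": metric, "value": value})
    return pd.DataFrame(rows, columns=["window_start", "minute", "state",
                                       "metric", "value"])


def build_profile(timecourses: pd.DataFrame,
                  min_count: int = MIN_BIN_COUNT) -> pd.DataFrame:
    """Minute-of-day group profile: per (state, metric, minute) count and mean.

    ``timecourses`` is the concatenation of :func:`metric_timecourse` outputs
    across subjects.  Bins with fewer than ``min_count`` values carry no mean.
    """
    if timecourses.empty:
        return pd.DataFrame(columns=["state", "metric", "minute", "count", "mean"])
    g = timecourses.groupby(["state", "metric", "minute"])["value"]
    out = g.agg(count="count", mean="mean").reset_index()
    out.loc[out["count"] < min_count, "mean"] = np.nan
    return out


def _in_wrapped_interval(minute: np.ndarray, interval: tuple) -> np.ndarray:
    lo, hi = interval
    minute = np.asarray(minute)
    if lo <= hi:
        return (minute >= lo) & (minute < hi)
    return (minute >= lo) | (minute < hi)


def select_pools(timecourse: pd.DataFrame, state: str,
                 day: tuple = DAY_MINUTES, night: tuple = NIGHT_MINUTES,
                 window_s: float | None = None,
                 decimate: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Day and night value pools for one state.

    With ``decimate`` (default), overlapping windows are thinned so that kept
    window starts are at least one window length apart, making the pooled
    values approximately independent for the iid bootstrap.
    """
    df = timecourse[timecourse["state"] == state]
    if decimate:
        if window_s is None:
            window_s = 300.0
        kept_rows = []
        last = -np.inf
        for _, row in df.sort_values("window_start").iterrows():
            if row["window_start"] >= last + window_s:
                kept_rows.append(row)
                last = row["window_start"]
        df = pd.DataFrame(kept_rows) if kept_rows else df.iloc[:0]
    day_pool = df.loc[_in_wrapped_interval(df["minute"], day), "value"].to_numpy()
    night_pool = df.loc[_in_wrapped_interval(df["minute"], night), "value"].to_numpy()
    return day_pool, night_pool


@dataclass
class DayNightTest:
    """Bootstrap difference-of-means test (night minus day)."""

    difference: float  # plain difference of pool means
    ci_low: float
    ci_high: float
    significant: bool
    n_day: int
    n_night: int
    n_boot: int
    seed: int
    sign_convention: str = "night_minus_day"


def day_night_test(day_pool: np.ndarray, night_pool: np.ndarray,
                   n_boot: int = 1000, seed: int = 0,
                   confidence: float = 0.95) -> DayNightTest:
    """Percentile bootstrap CI for the night-day difference of pool means."""
    day_pool = np.asarray(day_pool, dtype=float)
    night_pool = np.asarray(night_pool, dtype=float)
    if len(day_pool) == 0 or len(night_pool) == 0:
        raise ValueError("both day and night pools must be nonempty")
    rng = np.random.default_rng([int(seed), 31])
    diffs = np.empty(n_boot)
    for m in range(n_boot):
        d = day_pool[rng.integers(0, len(day_pool), len(day_pool))]
        n = night_pool[rng.integers(0, len(night_pool), len(night_pool))]
        diffs[m] = n.mean() - d.mean()
    alpha = 1 - confidence
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return DayNightTest(difference=float(night_pool.mean() - day_pool.mean()),
                        ci_low=float(lo), ci_high=float(hi),
                        significant=bool(lo > 0 or hi < 0),
                        n_day=len(day_pool), n_night=len(night_pool),
                        n_boot=n_boot, seed=int(seed))
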