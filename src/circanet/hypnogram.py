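"""Sleep-stage annotations (hypnograms).

A hypnogram is an ordered list of ``(onset_s, duration_s, stage)`` intervals
covering a recording.  Stages follow the clinical vocabulary ``W`` (wake),
``N1``/``N2``/``N3`` (non-REM) and ``REM``.  For the two-state analyses the
four sleep stages are pooled into a single ``sleep`` category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES = frozenset({"N1", "N2", "N3", "REM"})


@dataclass
class Hypnogram:
    """Ordered, contiguous stage intervals.

    Parameters
    ----------
    onsets : array of float
        Interval onsets in seconds from the start of the recording.
    durations : array of float
        Interval durations in seconds (strictly positive).
    stages : sequence of str
        One stage label per interval, drawn from ``STAGES``.
    """

    onsets: np.ndarray
    durations: np.ndarray
    stages: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.stages = list(self.stages)
        if len(self.onsets) == 0:
            raise ValueError("hypnogram must contain at least one interval")
        if not (len(self.onsets) == len(self.durations) == len(self.stages)):
            raise ValueError("onsets, durations and stages must have equal length")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}; allowed: {STAGES}")
        if np.any(self.durations <= 0):
            raise ValueError("interval durations must be positive")
        ends = self.onsets + self.durations
        if not np.allclose(self.onsets[1:], ends[:-1]):
            raise ValueError("intervals must be contiguous and non-overlapping")

    @property
    def total_duration(self) -> float:
        return float(self.onsets[-1] + self.durations[-1])

    def covers(self, duration: float, tol: float = 1e-9) -> bool:
        """Whether the intervals tile ``[0, duration]``."""
        return abs(self.onsets[0]) <= tol and self.total_duration >= duration - tol

    def stage_at(self, t) -> np.ndarray:
        """Stage label at each time ``t`` (seconds).  Vectorized."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.onsets, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.onsets) - 1)
        out = np.array(self.stages, dtype=object)[idx]
        return out

    def is_sleep_at(self, t) -> np.ndarray:
        """Boolean array: True where the stage at ``t`` is any sleep stage."""
        return np.isin(self.stage_at(t), list(SLEEP_STAGES))

    def sleep_fraction(self, start: float, duration: float, resolution: float = 1.0) -> float:
        """Fraction of ``[start, start + duration)`` spent asleep.

        Sampled on a grid of ``resolution`` seconds (mid-bin), which is exact
        for integer-second interval boundaries at the default resolution.
        """
        n = max(int(round(duration / resolution)), 1)
        ts = start + (np.arange(n) + 0.5) * resolution
        return float(np.mean(self.is_sleep_at(ts)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets, "duration_s": self.durations, "stage": self.stages}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Hypnogram":
        df = pd.read_csv(path)
        return cls(df["onset_s"].to_numpy(), df["duration_s"].to_numpy(), list(df["stage"]))
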