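"""In-memory container for a multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np


@dataclass
class Recording:
    """Multichannel voltage recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in volts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel names.
    clock_start : datetime
        Wall-clock time of sample 0 (used for circadian binning).
    """

    data: np.ndarray
    fs: float
    labels: list = field(default_factory=list)
    clock_start: datetime = datetime(2018, 1, 1, 10, 30, 0)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data=data, fs=self.fs, labels=list(self.labels),
                         clock_start=self.clock_start)

    def clock_seconds_of_day(self, t: float) -> float:
        """Seconds since midnight of the wall-clock time at offset ``t`` s."""
        start = (self.clock_start.hour * 3600 + self.clock_start.minute * 60
                 + self.clock_start.second)
        return (start + t) % 86400.0
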