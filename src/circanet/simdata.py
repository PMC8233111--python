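"""Ground-truthed synthetic recordings.

The generator produces EEG-like multichannel signals with the structure the
downstream pipeline is designed to detect:

* polyphasic alternation between two latent behavioural states ("wake" and
  "sleep"), with bout durations drawn from an exponential law truncated below
  at 60 s;
* state-dependent lagged coupling between channel pairs, realized as a shared
  band-limited source added to both channels with a per-pair lag of at least
  one sample (so true coupling never peaks at zero lag);
* a smooth 24-hour multiplicative modulation of the coupling gain;
* additive private band-limited noise per channel; and
* sparse extreme-amplitude transient artifacts.

Every random draw is controlled by ``SimulationConfig.seed``; identical
configurations yield bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import numpy as np
from scipy import signal as sps

from .hypnogram import Hypnogram
from .io import write_edf  # noqa: F401  (re-exported: simulator output format)
from .recording import Recording

_SOURCE_BAND = (0.5, 30.0)  # Hz, band of private noise and shared sources
_ARTIFACT_DUR = 0.2  # s, raised-cosine transient length


def ring_coupling(n_channels: int, weight: float) -> np.ndarray:
    """Symmetric coupling matrix linking each channel to its ring neighbours."""
    w = np.zeros((n_channels, n_channels))
    for i in range(n_channels):
        j = (i + 1) % n_channels
        if i != j:
            w[i, j] = w[j, i] = weight
    return w


def default_lags(n_channels: int, lo: int = 2, hi: int = 8) -> np.ndarray:
    """Deterministic per-pair lags (samples) cycling through ``lo..hi``."""
    lags = np.zeros((n_channels, n_channels), dtype=int)
    k = 0
    for i in range(n_channels):
        for j in range(i + 1, n_channels):
            lag = lo + (k % (hi - lo + 1))
            lags[i, j] = lags[j, i] = lag
            k += 1
    return lags


def _check_coupling(w: np.ndarray, name: str) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(w, w.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diag(w) != 0):
        raise ValueError(f"{name} must have zero diagonal")
    if np.any((w < 0) | (w > 1)):
        raise ValueError(f"{name} entries must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    Coupling weights are unitless gains in [0, 1] applied to a shared source
    whose standard deviation equals ``noise_sd``; a weight ``w`` therefore
    yields an expected pairwise correlation of roughly ``w**2 / (1 + w**2)``
    against the private noise floor.
    """

    n_channels: int = 19
    fs: float = 200.0
    duration: float = 72000.0  # 20 h
    clock_start: datetime = datetime(2018, 1, 1, 10, 30, 0)
    seed: int = 0
    wake_coupling: Optional[np.ndarray] = None
    sleep_coupling: Optional[np.ndarray] = None
    coupling_lag: Optional[np.ndarray] = None
    bout_mean_wake: float = 3600.0
    bout_mean_sleep: float = 3600.0
    circadian_amplitude: float = 0.3
    circadian_phase: float = 0.0  # hour of day at which coupling gain peaks
    artifact_rate: float = 2.0  # expected artifacts per hour
    artifact_amplitude: float = 25.0  # in units of background SD
    noise_sd: float = 20e-6  # volts
    wake_weight: float = 0.4  # used only when wake_coupling is None
    sleep_weight: float = 0.8  # used only when sleep_coupling is None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least two channels")
        if self.wake_coupling is None:
            self.wake_coupling = ring_coupling(self.n_channels, self.wake_weight)
        if self.sleep_coupling is None:
            self.sleep_coupling = ring_coupling(self.n_channels, self.sleep_weight)
        self.wake_coupling = np.asarray(self.wake_coupling, dtype=float)
        self.sleep_coupling = np.asarray(self.sleep_coupling, dtype=float)
        _check_coupling(self.wake_coupling, "wake_coupling")
        _check_coupling(self.sleep_coupling, "sleep_coupling")
        if self.wake_coupling.shape != (self.n_channels, self.n_channels):
            raise ValueError("coupling matrix shape must match n_channels")
        if self.sleep_coupling.shape != (self.n_channels, self.n_channels):
            raise ValueError("coupling matrix shape must match n_channels")
        if self.coupling_lag is None:
            self.coupling_lag = default_lags(self.n_channels)
        self.coupling_lag = np.asarray(self.coupling_lag, dtype=int)
        coupled = (self.wake_coupling > 0) | (self.sleep_coupling > 0)
        if np.any(self.coupling_lag[coupled] < 1):
            raise ValueError("coupled pairs must have lag >= 1 sample")
        if min(self.bout_mean_wake, self.bout_mean_sleep) <= 60:
            raise ValueError("mean bout durations must exceed the 60-s floor")
        if not 0 <= self.circadian_amplitude < 1:
            raise ValueError("circadian_amplitude must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    hypnogram: Hypnogram
    wake_coupling: np.ndarray
    sleep_coupling: np.ndarray
    circadian_gain: np.ndarray  # per-second multiplicative gain
    artifact_intervals: list = field(default_factory=list)  # (onset_s, duration_s)


def generate_schedule(config: SimulationConfig) -> Hypnogram:
    """Alternating wake/sleep bouts covering the full recording.

    Bout durations are 60 s plus an exponential variate with mean
    ``bout_mean - 60``, i.e. an exponential law truncated below at 60 s whose
    mean equals the configured bout mean.  The final bout is clipped to the
    recording end.  Sleep bouts are labelled ``N2`` (the two-state analyses
    pool all sleep stages, so one representative label suffices).
    """
    rng = np.random.default_rng([int(config.seed), 11])
    onsets, durations, stages = [], [], []
    t, awake = 0.0, True
    while t < config.duration:
        mean = config.bout_mean_wake if awake else config.bout_mean_sleep
        d = 60.0 + rng.exponential(mean - 60.0)
        d = min(d, config.duration - t)
        onsets.append(t)
        durations.append(d)
        stages.append("W" if awake else "N2")
        t += d
        awake = not awake
    return Hypnogram(np.array(onsets), np.array(durations), stages)


def circadian_gain(config: SimulationConfig, t_seconds: np.ndarray) -> np.ndarray:
    """Multiplicative coupling gain 1 + A*cos(2*pi*(clock - phase)/24 h)."""
    start = (config.clock_start.hour * 3600 + config.clock_start.minute * 60
             + config.clock_start.second)
    clock = (start + np.asarray(t_seconds, dtype=float)) / 3600.0
    return 1.0 + config.circadian_amplitude * np.cos(
        2 * np.pi * (clock - config.circadian_phase) / 24.0)


def _band_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Band-limited Gaussian noise with exact sample SD ``sd``."""
    sos = sps.butter(4, _SOURCE_BAND, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    if s == 0:
        raise ValueError("degenerate noise segment")
    return x * (sd / s)


def generate_recording(config: SimulationConfig,
                       schedule: Hypnogram) -> tuple[Recording, GroundTruth]:
    """Render the multichannel signal for a given wake/sleep schedule."""
    if not schedule.covers(config.duration):
        raise ValueError("schedule does not cover the recording duration")
    fs = config.fs
    n = int(round(config.duration * fs))
    n_ch = config.n_channels
    rng = np.random.default_rng([int(config.seed), 23])

    data = np.empty((n_ch, n))
    for ch in range(n_ch):
        data[ch] = _band_noise(rng, n, fs, config.noise_sd)

    t = np.arange(n) / fs
    asleep = schedule.is_sleep_at(t)
    gain = circadian_gain(config, t)

    coupled = np.argwhere(
        np.triu((config.wake_coupling > 0) | (config.sleep_coupling > 0), k=1))
    for i, j in coupled:
        lag = int(config.coupling_lag[i, j])
        w = np.where(asleep, config.sleep_coupling[i, j], config.wake_coupling[i, j])
        env = w * gain
        src = _band_noise(rng, n + lag, fs, config.noise_sd)
        data[i] += env * src[lag:]
        data[j] += env * src[:n]  # channel j trails channel i by `lag` samples

    artifact_intervals = []
    n_art = rng.poisson(config.artifact_rate * config.duration / 3600.0)
    width = int(round(_ARTIFACT_DUR * fs))
    window = np.hanning(width)
    for _ in range(n_art):
        onset = rng.uniform(0, config.duration - _ARTIFACT_DUR)
        ch = rng.integers(0, n_ch)
        sign = rng.choice([-1.0, 1.0])
        start = int(round(onset * fs))
        amp = sign * config.artifact_amplitude * config.noise_sd
        data[ch, start:start + width] += amp * window[: n - start]
        artifact_intervals.append((onset, _ARTIFACT_DUR))

    rec = Recording(data=data, fs=fs, clock_start=config.clock_start)
    truth = GroundTruth(
        hypnogram=schedule,
        wake_coupling=config.wake_coupling.copy(),
        sleep_coupling=config.sleep_coupling.copy(),
        circadian_gain=circadian_gain(config, np.arange(math.ceil(config.duration))),
        artifact_intervals=artifact_intervals,
    )
    return rec, truth


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    """Write stage intervals as CSV with columns onset_s, duration_s, stage."""
    hypnogram.to_csv(path)


def read_hypnogram(path) -> Hypnogram:
    return Hypnogram.from_csv(path)
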