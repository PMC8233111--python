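"""Re-referencing, artifact detection, filtering and epoching.

The preprocessing chain mirrors standard long-term clinical EEG practice:
common-average re-referencing, an extreme-value artifact detector on
1.5-40 Hz filtered data (threshold 7.5 per-channel standard deviations, with
a 0.9-s buffer around each flagged run, unioned across channels), a
zero-phase 0.5-55 Hz broadband filter for the connectivity analysis, and
division into non-overlapping 1-s epochs from which any epoch containing a
flagged sample in any channel is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import Recording

ARTIFACT_BAND = (1.5, 40.0)
CONNECTIVITY_BAND = (0.5, 55.0)
ARTIFACT_THRESHOLD_SD = 7.5
ARTIFACT_BUFFER_S = 0.9
FILTER_ORDER = 4


@dataclass
class ArtifactMask:
    """Per-sample boolean artifact flags, shared across channels."""

    flags: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def flagged_fraction(self) -> float:
        return float(self.flags.mean()) if self.flags.size else 0.0


@dataclass
class EpochSet:
    """Non-overlapping 1-s epochs of a filtered recording.

    ``data`` holds the filtered signal; ``starts`` are epoch start indices on
    a contiguous grid anchored at sample 0; ``valid`` marks epochs free of
    flagged samples in every channel.
    """

    data: np.ndarray  # channels x samples, filtered
    fs: float
    starts: np.ndarray  # sample index of each epoch start
    valid: np.ndarray  # bool per epoch
    labels: list = field(default_factory=list)
    reference: np.ndarray | None = None  # common-average series, filtered

    @property
    def n_epochs(self) -> int:
        return len(self.starts)

    @property
    def epoch_len(self) -> int:
        return int(round(self.fs))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def epoch_times(self) -> np.ndarray:
        """Epoch start times in seconds from recording start."""
        return self.starts / self.fs

    def get(self, k: int) -> np.ndarray:
        """Raw (unstandardized) channels x samples view of epoch ``k``."""
        s = self.starts[k]
        return self.data[:, s:s + self.epoch_len]

    def index_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(self.n_epochs),
                             "start_s": self.epoch_times(), "valid": self.valid})


def rereference_common_average(recording: Recording) -> tuple[Recording, np.ndarray]:
    """Subtract the instantaneous mean across channels.

    Returns the re-referenced recording together with the common-average time
    series itself, which the connectivity stage uses for the partial
    -correlation reference check.
    """
    if recording.n_channels < 2:
        raise ValueError("common-average reference requires at least 2 channels")
    ref = recording.data.mean(axis=0)
    return recording.copy_with(recording.data - ref), ref


def _bandpass_sos(band: tuple[float, float], fs: float):
    if band[1] >= fs / 2:
        raise ValueError(
            f"upper band edge {band[1]} Hz at or above Nyquist ({fs / 2} Hz)")
    return sps.butter(FILTER_ORDER, band, btype="bandpass", fs=fs, output="sos")


def detect_artifacts(recording: Recording,
                     threshold_sd: float = ARTIFACT_THRESHOLD_SD,
                     buffer_s: float = ARTIFACT_BUFFER_S,
                     bad_intervals=None) -> ArtifactMask:
    """Extreme-value artifact detector.

    The recording is band-passed 1.5-40 Hz (zero-phase Butterworth), each
    channel is demeaned, and samples whose absolute value exceeds
    ``threshold_sd`` times that channel's standard deviation are flagged.
    Each contiguous flagged run is extended by ``buffer_s`` on both sides and
    channel masks are unioned.  ``bad_intervals`` (iterable of
    ``(onset_s, duration_s)``, e.g. impedance checks) are unioned in as-is.
    """
    sos = _bandpass_sos(ARTIFACT_BAND, recording.fs)
    filt = sps.sosfiltfilt(sos, recording.data, axis=1)
    filt -= filt.mean(axis=1, keepdims=True)
    sd = filt.std(axis=1, ddof=0)
    sd[sd == 0] = np.inf  # an all-zero channel has no extreme values
    exceeds = np.abs(filt) > threshold_sd * sd[:, None]

    buf = int(round(buffer_s * recording.fs))
    flags = np.zeros(recording.n_samples, dtype=bool)
    union = exceeds.any(axis=0)
    if union.any() and buf > 0:
        # dilate every flagged run by `buf` samples on each side
        kernel_hits = np.flatnonzero(union)
        lo = np.maximum(kernel_hits - buf, 0)
        hi = np.minimum(kernel_hits + buf + 1, recording.n_samples)
        delta = np.zeros(recording.n_samples + 1, dtype=int)
        np.add.at(delta, lo, 1)
        np.add.at(delta, hi, -1)
        flags = np.cumsum(delta[:-1]) > 0
    else:
        flags = union.copy()

    if bad_intervals is not None:
        for onset, dur in bad_intervals:
            a = max(int(np.floor(onset * recording.fs)), 0)
            b = min(int(np.ceil((onset + dur) * recording.fs)), recording.n_samples)
            flags[a:b] = True
    return ArtifactMask(flags=flags, fs=recording.fs)


def filter_for_connectivity(recording: Recording) -> Recording:
    """Zero-phase 0.5-55 Hz Butterworth band-pass of every channel."""
    if recording.fs <= 2 * CONNECTIVITY_BAND[1]:
        raise ValueError("sampling rate too low for the 55-Hz band edge")
    sos = _bandpass_sos(CONNECTIVITY_BAND, recording.fs)
    return recording.copy_with(sps.sosfiltfilt(sos, recording.data, axis=1))


def filter_reference(ref: np.ndarray, fs: float) -> np.ndarray:
    """Apply the connectivity band-pass to the common-average series."""
    sos = _bandpass_sos(CONNECTIVITY_BAND, fs)
    return sps.sosfiltfilt(sos, ref)


def cut_epochs(recording: Recording, mask: ArtifactMask,
               reference: np.ndarray | None = None) -> EpochSet:
    """Cut non-overlapping 1-s epochs; drop epochs touching flagged samples."""
    if len(mask.flags) != recording.n_samples:
        raise ValueError("mask length does not match recording")
    epoch_len = int(round(recording.fs))
    n_epochs = recording.n_samples // epoch_len
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    starts = np.arange(n_epochs) * epoch_len
    used = mask.flags[: n_epochs * epoch_len].reshape(n_epochs, epoch_len)
    valid = ~used.any(axis=1)
    if valid.sum() == 0:
        warnings.warn("no valid epochs remain after artifact removal")
    return EpochSet(data=recording.data, fs=recording.fs, starts=starts,
                    valid=valid, labels=list(recording.labels),
                    reference=reference)


def preprocess(recording: Recording, rereference: bool = True,
               bad_intervals=None) -> EpochSet:
    """Full chain: re-reference, detect artifacts, filter, cut epochs."""
    ref = None
    if rereference:
        recording, ref_raw = rereference_common_average(recording)
        ref = filter_reference(ref_raw, recording.fs)
    mask = detect_artifacts(recording, bad_intervals=bad_intervals)
    filtered = filter_for_connectivity(recording)
    return cut_epochs(filtered, mask, reference=ref)
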