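"""Per-epoch significance-thresholded cross-correlation networks.

For every 1-s epoch and channel pair the statistic is the maximum over lags
of the absolute normalized cross-correlation between the standardized epoch
signals.  Its Fisher z-transform is divided by a Bartlett-type standard
deviation that accounts for within-epoch autocorrelation,

    s^2 = (1/N) * sum_{|tau| < N} rho_xx(tau) * rho_yy(tau),

so that autocorrelated but uncoupled channels are not spuriously flagged.
The standardized score is compared per pair against the 95th percentile
(nearest rank) of a permutation null built from 500 time-mismatched epoch
pairs of the same two channels.  Epoch-pair entries whose correlation peaks
at zero lag are excluded (volume conduction), and significant entries whose
partial correlation given the common-average reference falls below the null
threshold are excluded as referencing artifact.  The result is a binary
tensor Q over (pair, epoch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len

from .hypnogram import Hypnogram, SLEEP_STAGES
from .preprocess import EpochSet

DEFAULT_MAX_LAG_MS = 200.0
DEFAULT_NULL_ITERS = 500
DEFAULT_ALPHA_PERCENTILE = 95.0

# exclusion reason codes stored alongside Q
REASON_NONE = 0
REASON_ZERO_LAG = 1
REASON_REFERENCE = 2
REASON_EPOCH_ARTIFACT = 3
REASON_LABELS = {REASON_NONE: "none", REASON_ZERO_LAG: "zero-lag",
                 REASON_REFERENCE: "reference-artifact",
                 REASON_EPOCH_ARTIFACT: "epoch-artifact"}

_MIN_S2_FACTOR = 1e-4  # floor on s^2 (in units of 1/N) against degenerate epochs


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance signal: standardization undefined")
    return (x - x.mean()) / sd


def _lag_order(max_lag: int) -> list[int]:
    """Lags ordered for tie-breaking: smaller |lag| first, negative before positive."""
    return sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l))


def max_crosscorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[float, int]:
    """Maximum absolute normalized cross-correlation and its lag.

    Both signals are standardized to zero mean and unit variance; the
    cross-correlation at lag ``tau`` is ``(1/N) * sum_t x[t] * y[t + tau]``
    (positive lag = ``y`` delayed relative to ``x``).  Returns the signed
    correlation value at the lag maximizing ``|r|``; ties break toward
    smaller ``|lag|``, then toward the negative lag.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("signals must be equal-length 1-D arrays of length >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("signals must be finite")
    xs, ys = _standardize(x), _standardize(y)
    n = len(xs)
    best_r, best_lag = 0.0, 0
    for lag in _lag_order(int(max_lag)):
        if lag >= 0:
            r = float(xs[: n - lag] @ ys[lag:]) / n
        else:
            r = float(xs[-lag:] @ ys[: n + lag]) / n
        if abs(r) > abs(best_r):
            best_r, best_lag = r, lag
    return best_r, best_lag


def _autocorr(x: np.ndarray) -> np.ndarray:
    """Biased autocorrelation of a standardized signal, lags 0..N-1."""
    n = len(x)
    nfft = next_fast_len(2 * n)
    f = np.fft.rfft(x, n=nfft)
    ac = np.fft.irfft(f * np.conj(f), n=nfft)[:n] / n
    return ac


def bartlett_sd(x: np.ndarray, y: np.ndarray) -> float:
    """Autocorrelation-corrected SD of the Fisher-transformed correlation."""
    xs, ys = _standardize(x), _standardize(y)
    n = len(xs)
    s2 = (2.0 * float(_autocorr(xs) @ _autocorr(ys)) - 1.0) / n
    if s2 <= 0:
        raise ValueError("non-positive variance estimate: degenerate epoch")
    return math.sqrt(s2)


def corrected_z(r: float, x: np.ndarray, y: np.ndarray) -> float:
    """Fisher-transformed correlation standardized by the Bartlett SD."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    return math.atanh(r) / bartlett_sd(x, y)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt(float(a @ a) * float(b @ b))
    if den == 0:
        return 0.0
    return float(a @ b) / den


def _partial_corr_at_lag(x: np.ndarray, y: np.ndarray, ref: np.ndarray,
                         lag: int) -> float:
    """Partial correlation of x, y given the reference, at the selected lag.

    The epoch segments are aligned at ``lag``; each is partialized against
    the co-temporal segment of the reference series.
    """
    n = len(x)
    if lag >= 0:
        xs, ys = x[: n - lag], y[lag:]
        rx, ry = ref[: n - lag], ref[lag:]
    else:
        xs, ys = x[-lag:], y[: n + lag]
        rx, ry = ref[-lag:], ref[: n + lag]
    r_xy = _pearson(xs, ys)
    r_xr = _pearson(xs, rx)
    r_yr = _pearson(ys, ry)
    den = math.sqrt(max((1 - r_xr ** 2) * (1 - r_yr ** 2), 1e-12))
    return (r_xy - r_xr * r_yr) / den


def reference_check(x: np.ndarray, y: np.ndarray, ref: np.ndarray,
                    lag: int, z_threshold: float) -> bool:
    """Decide whether a significant correlation survives partialization.

    Returns False only when the pairwise corrected z exceeds the null
    threshold but the corrected z of the partial correlation (given the
    common-average reference, at the selected lag) does not - the signature
    of a correlation induced by the shared reference.
    """
    r, found_lag = max_crosscorr(x, y, max_lag=max(abs(lag), 1))
    xs, ys = _standardize(x), _standardize(y)
    s = bartlett_sd(x, y)
    z = math.atanh(min(abs(r), 1 - 1e-12)) / s
    if z <= z_threshold:
        return True  # not significant to begin with; nothing to discard
    rp = _partial_corr_at_lag(xs, ys, _standardize(ref), lag)
    zp = math.atanh(min(abs(rp), 1 - 1e-12)) / s
    return zp > z_threshold


@dataclass
class PairNull:
    """Permutation null for one channel pair."""

    pair: tuple
    values: np.ndarray  # sorted standardized scores, length n_iter
    percentile: float = DEFAULT_ALPHA_PERCENTILE

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    @property
    def threshold(self) -> float:
        """Nearest-rank percentile of the null sample."""
        n = len(self.values)
        rank = math.ceil(self.percentile / 100.0 * n)
        return float(self.values[rank - 1])


@dataclass
class NullBank:
    """Null thresholds for every channel pair (upper-triangle order)."""

    pairs: np.ndarray  # (P, 2) channel index pairs, i < j
    thresholds: np.ndarray  # (P,)
    n_iter: int

    @classmethod
    def from_pairnulls(cls, nulls: list) -> "NullBank":
        pairs = np.array([pn.pair for pn in nulls])
        thr = np.array([pn.threshold for pn in nulls])
        return cls(pairs=pairs, thresholds=thr, n_iter=len(nulls[0].values))


@dataclass
class EpochTensor:
    """Binary connection tensor Q over (pair, epoch) with exclusion reasons."""

    Q: np.ndarray  # (P, E) uint8
    reason: np.ndarray  # (P, E) int8, REASON_* codes
    valid: np.ndarray  # (E,) epoch validity
    times: np.ndarray  # (E,) epoch start seconds
    pairs: np.ndarray  # (P, 2)
    labels: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.Q.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.Q.shape[1]

    def state_masks(self, hypnogram: Hypnogram) -> tuple[np.ndarray, np.ndarray]:
        """(wake, sleep) boolean masks over *valid* epochs (by epoch midpoint)."""
        mid = self.times + 0.5
        asleep = np.isin(hypnogram.stage_at(mid), list(SLEEP_STAGES))
        return self.valid & ~asleep, self.valid & asleep

    def state_counts(self, hypnogram: Hypnogram) -> tuple[int, int]:
        """(N_w, N_s): valid epoch counts in wakefulness and sleep."""
        w, s = self.state_masks(hypnogram)
        return int(w.sum()), int(s.sum())

    def index_frame(self) -> pd.DataFrame:
        """Long-format (pair, epoch, value, reason) table."""
        p, e = np.nonzero((self.Q > 0) | (self.reason > 0))
        return pd.DataFrame({
            "channel_i": self.pairs[p, 0], "channel_j": self.pairs[p, 1],
            "epoch": e, "value": self.Q[p, e],
            "reason": [REASON_LABELS[c] for c in self.reason[p, e]]})


def _gather_epochs(epochs: EpochSet, idx: np.ndarray) -> np.ndarray:
    """Stack epochs ``idx`` into an (E, C, N) array."""
    n = epochs.epoch_len
    starts = epochs.starts[idx]
    take = starts[:, None] + np.arange(n)[None, :]
    return epochs.data[:, take].transpose(1, 0, 2)


def _standardize_batch(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize (E, C, N) per channel-epoch; also return per-epoch ok mask."""
    mu = X.mean(axis=2, keepdims=True)
    sd = X.std(axis=2, ddof=0, keepdims=True)
    ok = (sd[:, :, 0] > 0).all(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, ok


def _batch_max_xcorr(X: np.ndarray, max_lag: int,
                     iu: np.ndarray, ju: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Signed max-|xcorr| value and argmax lag for all pairs of all epochs."""
    E, C, N = X.shape
    L = int(max_lag)
    P = len(iu)
    vals = np.empty((E, P, 2 * L + 1))
    Xt = X.transpose(0, 2, 1)
    for tau in range(L + 1):
        if tau == 0:
            M = (X @ Xt) / N
            vals[:, :, L] = M[:, iu, ju]
        else:
            M = (X[:, :, : N - tau] @ Xt[:, tau:, :]) / N
            vals[:, :, L + tau] = M[:, iu, ju]
            vals[:, :, L - tau] = M[:, ju, iu]
    order = _lag_order(L)
    cols = [L + l for l in order]
    a = np.abs(vals[:, :, cols])
    k = np.argmax(a, axis=2)  # first max in tie-break order
    lags = np.asarray(order)[k]
    r = np.take_along_axis(vals, (L + lags)[:, :, None], axis=2)[:, :, 0]
    return r, lags


def _batch_bartlett_sd(X: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    """Bartlett SD for every pair of every epoch; X standardized (E, C, N)."""
    E, C, N = X.shape
    nfft = next_fast_len(2 * N)
    f = np.fft.rfft(X, n=nfft, axis=2)
    ac = np.fft.irfft(f * np.conj(f), n=nfft, axis=2)[:, :, :N] / N
    G = ac @ ac.transpose(0, 2, 1)
    s2 = (2.0 * G[:, iu, ju] - 1.0) / N
    return np.sqrt(np.maximum(s2, _MIN_S2_FACTOR / N))


def build_null(epochs: EpochSet, i: int, j: int,
               n_iter: int = DEFAULT_NULL_ITERS, seed: int = 0,
               max_lag: int | None = None,
               percentile: float = DEFAULT_ALPHA_PERCENTILE) -> PairNull:
    """Permutation null for channels ``(i, j)``.

    Each iteration pairs a 1-s epoch of channel ``i`` with a 1-s epoch of
    channel ``j`` drawn from a different time, the two windows separated by
    at least 1 s, and records the corrected z of the max absolute
    cross-correlation.
    """
    if max_lag is None:
        max_lag = int(round(DEFAULT_MAX_LAG_MS / 1000.0 * epochs.fs))
    valid_idx = np.flatnonzero(epochs.valid)
    if len(valid_idx) < 3:
        raise ValueError("need at least 3 s of valid data to build a null")
    rng = np.random.default_rng([int(seed), 101, int(i), int(j)])
    a = rng.integers(0, len(valid_idx), size=n_iter)
    b = rng.integers(0, len(valid_idx), size=n_iter)
    # enforce >= 1 s separation between the two windows (start gap >= 2 epochs)
    while True:
        bad = np.abs(valid_idx[a] - valid_idx[b]) < 2
        if not bad.any():
            break
        b[bad] = rng.integers(0, len(valid_idx), size=int(bad.sum()))

    Xa = _gather_epochs(epochs, valid_idx[a])[:, i, :]
    Xb = _gather_epochs(epochs, valid_idx[b])[:, j, :]
    X = np.stack([Xa, Xb], axis=1)
    Xs, ok = _standardize_batch(X)
    iu, ju = np.array([0]), np.array([1])
    r, _ = _batch_max_xcorr(Xs, max_lag, iu, ju)
    s = _batch_bartlett_sd(Xs, iu, ju)
    z = np.arctanh(np.minimum(np.abs(r[:, 0]), 1 - 1e-12)) / s[:, 0]
    z[~ok] = 0.0
    return PairNull(pair=(int(i), int(j)), values=z, percentile=percentile)


def build_all_nulls(epochs: EpochSet, n_iter: int = DEFAULT_NULL_ITERS,
                    seed: int = 0, max_lag: int | None = None,
                    percentile: float = DEFAULT_ALPHA_PERCENTILE) -> NullBank:
    """Per-pair permutation nulls for every channel pair."""
    C = epochs.data.shape[0]
    nulls = [build_null(epochs, i, j, n_iter=n_iter, seed=seed,
                        max_lag=max_lag, percentile=percentile)
             for i in range(C) for j in range(i + 1, C)]
    return NullBank.from_pairnulls(nulls)


def epoch_networks(epochs: EpochSet, nulls: NullBank,
                   max_lag: int | None = None,
                   chunk_bytes: int = 64_000_000) -> EpochTensor:
    """Binary per-epoch connectivity tensor Q.

    For every valid epoch and channel pair: the max-|cross-correlation| lag
    is found; zero-lag maxima are excluded (volume conduction); remaining
    correlations are standardized and compared with the pair's null
    threshold; significant entries are then partialized against the
    common-average reference (when available) and discarded as referencing
    artifact if the partialized score no longer exceeds the threshold.
    """
    if max_lag is None:
        max_lag = int(round(DEFAULT_MAX_LAG_MS / 1000.0 * epochs.fs))
    C = epochs.data.shape[0]
    iu, ju = np.triu_indices(C, 1)
    P = len(iu)
    if nulls.thresholds.shape[0] != P:
        raise ValueError("null bank does not cover all channel pairs")
    E = epochs.n_epochs
    Q = np.zeros((P, E), dtype=np.uint8)
    reason = np.zeros((P, E), dtype=np.int8)
    reason[:, ~epochs.valid] = REASON_EPOCH_ARTIFACT

    ref = epochs.reference
    thr = nulls.thresholds[None, :]  # (1, P)
    valid_idx = np.flatnonzero(epochs.valid)
    n = epochs.epoch_len
    per_epoch = P * (2 * max_lag + 1) * 8
    step = max(int(chunk_bytes // max(per_epoch, 1)), 16)

    for lo in range(0, len(valid_idx), step):
        idx = valid_idx[lo:lo + step]
        X = _gather_epochs(epochs, idx)
        Xs, ok = _standardize_batch(X)
        if not ok.all():
            reason[:, idx[~ok]] = REASON_EPOCH_ARTIFACT
        r, lags = _batch_max_xcorr(Xs, max_lag, iu, ju)
        s = _batch_bartlett_sd(Xs, iu, ju)
        z = np.arctanh(np.minimum(np.abs(r), 1 - 1e-12)) / s
        sig = (z > thr) & ok[:, None]
        zero = (lags == 0) & sig
        keep = sig & ~zero

        if ref is not None and keep.any():
            refs = ref[epochs.starts[idx][:, None] + np.arange(n)[None, :]]
            mu = refs.mean(axis=1, keepdims=True)
            sd = refs.std(axis=1, ddof=0, keepdims=True)
            refs = (refs - mu) / np.where(sd > 0, sd, 1.0)
            for tau in np.unique(lags[keep]):
                ee, pp = np.nonzero(keep & (lags == tau))
                if tau >= 0:
                    xs = Xs[ee, iu[pp], : n - tau]
                    ys = Xs[ee, ju[pp], tau:]
                    rx = refs[ee, : n - tau]
                    ry = refs[ee, tau:]
                else:
                    xs = Xs[ee, iu[pp], -tau:]
                    ys = Xs[ee, ju[pp], : n + tau]
                    rx = refs[ee, -tau:]
                    ry = refs[ee, : n + tau]
                r_xy = _rowwise_pearson(xs, ys)
                r_xr = _rowwise_pearson(xs, rx)
                r_yr = _rowwise_pearson(ys, ry)
                den = np.sqrt(np.maximum((1 - r_xr ** 2) * (1 - r_yr ** 2), 1e-12))
                rp = (r_xy - r_xr * r_yr) / den
                zp = np.arctanh(np.minimum(np.abs(rp), 1 - 1e-12)) / s[ee, pp]
                dropped = zp <= nulls.thresholds[pp]
                keep[ee[dropped], pp[dropped]] = False
                reason[pp[dropped], idx[ee[dropped]]] = REASON_REFERENCE

        # write results back in (pair, epoch) orientation
        Q[:, idx] = keep.T.astype(np.uint8)
        zp_, ze_ = np.nonzero(zero.T)
        reason[zp_, idx[ze_]] = REASON_ZERO_LAG

    times = epochs.epoch_times()
    return EpochTensor(Q=Q, reason=reason, valid=epochs.valid.copy(),
                       times=times, pairs=np.column_stack([iu, ju]),
                       labels=list(epochs.labels))


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    den = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    den = np.where(den > 0, den, 1.0)
    return np.einsum("ij,ij->i", a, b) / den
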