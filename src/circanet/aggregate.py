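"""State-averaged networks, sliding-window series, strength, stability, and
per-connection state comparisons.

Connection strength between two channels is the fraction of valid 1-s epochs
in which their correlation was significant.  Because the numbers of wake and
sleep epochs differ, state networks are bootstrap averages: per iteration,
``N_samp`` epochs are drawn with replacement from the state's valid epochs
(default 11,000 epochs, 1,000 iterations) and the per-pair significant
fraction is computed; the final network is the mean over iterations.
Epoch-pair entries excluded as zero-lag or referencing artifact count as 0
in numerators but remain in denominators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import EpochTensor
from .hypnogram import Hypnogram

DEFAULT_N_SAMP = 11_000
DEFAULT_N_BOOT = 1_000
DEFAULT_WINDOW_S = 300
DEFAULT_STEP_S = 30
DEFAULT_MIN_VALID = 150  # valid epochs required for a usable 300-s window
STABILITY_SIZES = (10, 30, 60, 120, 200)


def pairs_to_matrix(values: np.ndarray, pairs: np.ndarray, n_nodes: int) -> np.ndarray:
    """Expand an upper-triangle pair vector into a symmetric matrix."""
    W = np.zeros((n_nodes, n_nodes))
    W[pairs[:, 0], pairs[:, 1]] = values
    W[pairs[:, 1], pairs[:, 0]] = values
    return W


def _check_fraction_network(W: np.ndarray) -> None:
    if np.any((W < 0) | (W > 1)):
        raise ValueError("network entries must be fractions in [0, 1]")
    if not np.allclose(W, W.T) or np.any(np.diag(W) != 0):
        raise ValueError("network must be symmetric with zero diagonal")


def state_average(tensor: EpochTensor, hypnogram: Hypnogram, state: str,
                  n_samp: int = DEFAULT_N_SAMP, n_boot: int = DEFAULT_N_BOOT,
                  seed: int = 0) -> np.ndarray:
    """Bootstrap state-averaged network Q_w or Q_s.

    ``state`` is ``"wake"`` or ``"sleep"``.  Returns the symmetric channel x
    channel matrix of mean significant-connection fractions.
    """
    wake, sleep = tensor.state_masks(hypnogram)
    mask = {"wake": wake, "sleep": sleep}.get(state)
    if mask is None:
        raise ValueError("state must be 'wake' or 'sleep'")
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"no valid epochs in state {state!r}")
    Q = tensor.Q[:, idx].astype(np.float64)
    rng = np.random.default_rng([int(seed), 7, 0 if state == "wake" else 1])
    acc = np.zeros(tensor.n_pairs)
    for _ in range(n_boot):
        draw = rng.integers(0, len(idx), size=n_samp)
        acc += Q[:, draw].mean(axis=1)
    frac = acc / n_boot
    n_nodes = len(tensor.labels) or int(tensor.pairs.max()) + 1
    W = pairs_to_matrix(frac, tensor.pairs, n_nodes)
    _check_fraction_network(W)
    return W


def plain_state_fraction(tensor: EpochTensor, hypnogram: Hypnogram,
                         state: str) -> np.ndarray:
    """Non-bootstrapped per-pair significant fraction over state epochs."""
    wake, sleep = tensor.state_masks(hypnogram)
    mask = {"wake": wake, "sleep": sleep}[state]
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"no valid epochs in state {state!r}")
    frac = tensor.Q[:, idx].mean(axis=1)
    n_nodes = len(tensor.labels) or int(tensor.pairs.max()) + 1
    return pairs_to_matrix(frac, tensor.pairs, n_nodes)


@dataclass
class NetworkSeries:
    """Sliding-window averaged networks Q_n."""

    values: np.ndarray  # (n_windows, P) fractions
    window_starts: np.ndarray  # seconds
    window_s: int
    step_s: int
    valid_counts: np.ndarray  # valid epochs per window
    usable: np.ndarray  # bool per window
    pairs: np.ndarray
    labels: list = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def matrix(self, w: int) -> np.ndarray:
        n_nodes = len(self.labels) or int(self.pairs.max()) + 1
        return pairs_to_matrix(self.values[w], self.pairs, n_nodes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in range(self.n_windows):
            rows.append(pd.DataFrame({
                "window_start": self.window_starts[w],
                "channel_i": self.pairs[:, 0], "channel_j": self.pairs[:, 1],
                "value": self.values[w], "usable": self.usable[w]}))
        return pd.concat(rows, ignore_index=True)


def windowed_series(tensor: EpochTensor, window_s: int = DEFAULT_WINDOW_S,
                    step_s: int = DEFAULT_STEP_S,
                    min_valid: int | None = None) -> NetworkSeries:
    """Per-window per-pair significant fractions (e.g. Q_300, 30-s steps)."""
    if window_s < 1 or step_s <= 0:
        raise ValueError("window must be >= 1 s and step positive")
    E = tensor.n_epochs
    if E < window_s:
        raise ValueError("recording shorter than one window")
    if min_valid is None:
        min_valid = max(int(math.ceil(window_s / 2)), 1)
    n_win = (E - window_s) // step_s + 1
    starts = np.arange(n_win) * step_s

    vq = tensor.Q.astype(np.float64) * tensor.valid[None, :]
    csum = np.concatenate([np.zeros((tensor.n_pairs, 1)), np.cumsum(vq, axis=1)],
                          axis=1)
    vsum = np.concatenate([[0], np.cumsum(tensor.valid.astype(int))])
    counts = vsum[starts + window_s] - vsum[starts]
    sums = csum[:, starts + window_s] - csum[:, starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0).T
    usable = counts >= min_valid
    return NetworkSeries(values=values, window_starts=tensor.times[0] + starts,
                         window_s=window_s, step_s=step_s,
                         valid_counts=counts, usable=usable,
                         pairs=tensor.pairs, labels=list(tensor.labels))


def proportional_strength(W: np.ndarray, top_fraction: float = 0.10) -> float:
    """Mean of the strongest ``top_fraction`` of connections.

    Uses the floor of ``top_fraction * n_pairs`` largest upper-triangle
    entries (at least one).
    """
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise ValueError("empty network")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    vals = W[np.triu_indices(W.shape[0], 1)]
    k = max(int(math.floor(top_fraction * len(vals))), 1)
    top = np.sort(vals, kind="stable")[::-1][:k]
    return float(top.mean())


def network_corr2d(A: np.ndarray, B: np.ndarray) -> float:
    """Product-moment correlation over upper-triangle off-diagonal entries."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("networks must have equal dimensions")
    iu = np.triu_indices(A.shape[0], 1)
    a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _vector_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def stability_curve(tensor: EpochTensor, hypnogram: Hypnogram, state: str,
                    sizes=STABILITY_SIZES) -> dict:
    """Mean 2-D correlation between successive non-overlapping Q_n.

    Valid epochs of the requested state are concatenated in time order; for
    each window size ``n`` the per-pair fraction is computed over consecutive
    blocks of ``n`` epochs and the mean correlation between successive blocks
    is returned.  Sizes yielding fewer than two windows are omitted with a
    warning.
    """
    wake, sleep = tensor.state_masks(hypnogram)
    mask = {"wake": wake, "sleep": sleep}[state]
    idx = np.flatnonzero(mask)
    Q = tensor.Q[:, idx].astype(np.float64)
    out = {}
    for n in sizes:
        n_win = Q.shape[1] // n
        if n_win < 2:
            warnings.warn(f"window size {n}: fewer than 2 windows; omitted")
            continue
        blocks = Q[:, : n_win * n].reshape(Q.shape[0], n_win, n).mean(axis=2)
        rs = []
        for w in range(n_win - 1):
            a, b = blocks[:, w], blocks[:, w + 1]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"window size {n}: constant network skipped")
                continue
            rs.append(_vector_corr(a, b))
        if rs:
            out[int(n)] = float(np.mean(rs))
    return out


def stability_group_ci(curves: list, confidence: float = 0.95) -> pd.DataFrame:
    """Mean and t-based CI of per-subject stability curves, per window size."""
    sizes = sorted(set().union(*[c.keys() for c in curves]))
    rows = []
    for n in sizes:
        vals = np.array([c[n] for c in curves if n in c])
        m = vals.mean()
        if len(vals) > 1:
            half = stats.t.ppf(0.5 + confidence / 2, len(vals) - 1) * stats.sem(vals)
        else:
            half = np.nan
        rows.append({"window_s": n, "mean": m, "ci_low": m - half,
                     "ci_high": m + half, "n_subjects": len(vals)})
    return pd.DataFrame(rows)


def pairwise_state_tests(Q_w_list: list, Q_s_list: list,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Paired two-tailed Wilcoxon sign-rank per connection across subjects,
    Benjamini-Hochberg adjusted.

    ``Q_w_list`` and ``Q_s_list`` are per-subject wake/sleep networks in the
    same subject order.  Returns one row per channel pair with the adjusted
    p-value and the direction of any significant difference.
    """
    if len(Q_w_list) != len(Q_s_list):
        raise ValueError("unequal subject sets")
    if len(Q_w_list) < 5:
        raise ValueError("need at least 5 subjects for the paired test")
    n = Q_w_list[0].shape[0]
    iu = np.triu_indices(n, 1)
    Wv = np.array([W[iu] for W in Q_w_list])  # (subjects, pairs)
    Sv = np.array([S[iu] for S in Q_s_list])
    pvals = np.ones(Wv.shape[1])
    for p in range(Wv.shape[1]):
        d = Wv[:, p] - Sv[:, p]
        if np.all(d == 0):
            pvals[p] = 1.0
        else:
            pvals[p] = stats.wilcoxon(Wv[:, p], Sv[:, p],
                                      alternative="two-sided").pvalue
    rej, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    wake_mean = Wv.mean(axis=0)
    sleep_mean = Sv.mean(axis=0)
    return pd.DataFrame({
        "channel_i": iu[0], "channel_j": iu[1],
        "p_raw": pvals, "p_adj": p_adj, "significant": rej,
        "stronger_in": np.where(~rej, "ns",
                                np.where(wake_mean > sleep_mean, "wake", "sleep")),
    })
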