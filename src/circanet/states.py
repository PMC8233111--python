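"""Recurring network states: PCA decomposition of the windowed connectivity
series, two-component Gaussian-mixture classification, and correspondence
scoring against a hypnogram.

The windowed per-pair connection fractions are assembled into a matrix C
(pairs x windows): each window's column is standardized to zero mean and
unit variance, then each row (channel pair) is demeaned.  The first
principal axis of C captures the dominant network contrast; its time course
is bimodal when the recording alternates between two network states.  A
two-component univariate Gaussian mixture on the PC1 time course yields a
threshold at the point where the two weighted component densities are equal
(their PDF ratio closest to 1, searched between the component means to
avoid tail intersections), which splits the windows into two states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .aggregate import NetworkSeries
from .hypnogram import Hypnogram


def build_connection_matrix(series: NetworkSeries) -> tuple[np.ndarray, np.ndarray]:
    """Normalized connection matrix C and the kept window indices.

    Only usable windows enter; windows with zero variance across pairs are
    dropped with a warning.  Columns are standardized, then rows demeaned.
    """
    keep = np.flatnonzero(series.usable)
    if len(keep) < 2:
        raise ValueError("need at least 2 usable windows")
    C = series.values[keep].T.astype(float)  # (pairs, windows)
    sd = C.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance windows dropped")
        keep = keep[~degenerate]
        C = C[:, ~degenerate]
        sd = sd[~degenerate]
        if C.shape[1] < 2:
            raise ValueError("fewer than 2 non-degenerate windows remain")
    C = (C - C.mean(axis=0)) / sd
    C = C - C.mean(axis=1, keepdims=True)
    return C, keep


def pca_first(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First principal axis of the row-demeaned matrix C.

    Returns (loadings, timecourse, explained-variance fractions).  Loadings
    are unit-norm, one per channel pair; the time course is the projection of
    each window's column onto the axis.  Sign convention: the largest-
    magnitude loading is positive (the downstream correspondence score is
    invariant to this choice).
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("C must be finite")
    U, S, _ = np.linalg.svd(C, full_matrices=False)
    if S[0] == 0:
        raise ValueError("rank-0 matrix: no principal axis")
    loadings = U[:, 0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    timecourse = loadings @ C
    explained = S ** 2 / np.sum(S ** 2)
    return loadings, timecourse, explained


@dataclass
class StateModel:
    """PC1 decomposition plus the fitted mixture and state threshold."""

    loadings: np.ndarray
    timecourse: np.ndarray
    explained_variance: np.ndarray
    means: np.ndarray  # component means, ascending
    sds: np.ndarray
    weights: np.ndarray
    threshold: float
    window_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def to_dict(self) -> dict:
        return {"loadings": self.loadings.tolist(),
                "explained_variance": self.explained_variance.tolist(),
                "gmm": {"means": self.means.tolist(), "sds": self.sds.tolist(),
                        "weights": self.weights.tolist()},
                "threshold": self.threshold}


def fit_two_gmm(timecourse: np.ndarray, seed: int = 0) -> GaussianMixture:
    """Two-component univariate Gaussian mixture (EM, best of 10 restarts)."""
    x = np.asarray(timecourse, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 windows to fit a mixture")
    gmm = GaussianMixture(n_components=2, n_init=10,
                          random_state=int(seed) % (2 ** 31)).fit(x)
    if np.min(gmm.covariances_) < 1e-12:
        raise ValueError("degenerate mixture component; more data needed")
    return gmm


def _gmm_params(gmm: GaussianMixture) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    return means[order], sds[order], weights[order]


def mixture_overlap(gmm: GaussianMixture, n_grid: int = 4001) -> float:
    """Overlap of the two weighted component densities, in [0, 1].

    The integral of ``min(w1*phi1, w2*phi2)`` scaled by ``min(w1, w2)``:
    1 when the components coincide (unimodal data, low-confidence
    threshold), near 0 for well-separated states.
    """
    means, sds, weights = _gmm_params(gmm)
    lo = means[0] - 6 * sds[0]
    hi = means[1] + 6 * sds[1]
    grid = np.linspace(lo, hi, n_grid)
    pdf1 = weights[0] * np.exp(-0.5 * ((grid - means[0]) / sds[0]) ** 2) \
        / (sds[0] * np.sqrt(2 * np.pi))
    pdf2 = weights[1] * np.exp(-0.5 * ((grid - means[1]) / sds[1]) ** 2) \
        / (sds[1] * np.sqrt(2 * np.pi))
    return float(np.trapezoid(np.minimum(pdf1, pdf2), grid) / min(weights))


def gmm_threshold(gmm: GaussianMixture, n_grid: int = 2001) -> float:
    """State threshold: weighted-PDF ratio closest to 1, between the means."""
    means, sds, weights = _gmm_params(gmm)
    if np.isclose(means[0], means[1]):
        raise ValueError("component means coincide; no threshold exists")
    grid = np.linspace(means[0], means[1], n_grid)[1:-1]
    pdf1 = weights[0] / sds[0] * np.exp(-0.5 * ((grid - means[0]) / sds[0]) ** 2)
    pdf2 = weights[1] / sds[1] * np.exp(-0.5 * ((grid - means[1]) / sds[1]) ** 2)
    ratio = pdf1 / np.maximum(pdf2, 1e-300)
    return float(grid[np.argmin(np.abs(ratio - 1.0))])


@dataclass
class StateLabels:
    """Window labels and correspondence with the hypnogram."""

    frame: pd.DataFrame  # window_start, pc1, label, truth_sleep, match
    correspondence_pct: float
    sleep_label: int  # which binary label was mapped to sleep


def classify_and_score(timecourse: np.ndarray, threshold: float,
                       window_starts: np.ndarray, window_s: float,
                       hypnogram: Hypnogram) -> StateLabels:
    """Label windows by thresholded PC1 and score against the hypnogram.

    A window's ground-truth state is the majority stage (sleep vs wake)
    within it.  Correspondence is the better of the two label-to-state
    mappings, in percent, so it is invariant to the PC1 sign convention.
    """
    timecourse = np.asarray(timecourse, dtype=float)
    window_starts = np.asarray(window_starts, dtype=float)
    if len(timecourse) != len(window_starts):
        raise ValueError("one window start per PC1 value required")
    in_hyp = (window_starts >= hypnogram.onsets[0] - 1e-9) & \
             (window_starts + window_s <= hypnogram.total_duration + 1e-9)
    if not in_hyp.all():
        warnings.warn(f"{int((~in_hyp).sum())} windows outside the hypnogram "
                      "excluded from scoring")
    label = (timecourse > threshold).astype(int)
    truth = np.array([hypnogram.sleep_fraction(s, window_s) > 0.5
                      for s in window_starts])
    lab_u, tru_u = label[in_hyp], truth[in_hyp]
    match_as_is = float(np.mean(lab_u.astype(bool) == tru_u))
    corr = max(match_as_is, 1 - match_as_is) * 100.0
    sleep_label = 1 if match_as_is >= 0.5 else 0
    frame = pd.DataFrame({"window_start": window_starts, "pc1": timecourse,
                          "label": label, "truth_sleep": truth,
                          "scored": in_hyp,
                          "match": (label == (truth if sleep_label == 1
                                              else ~truth)).astype(bool)})
    return StateLabels(frame=frame, correspondence_pct=corr,
                       sleep_label=sleep_label)


def decompose_states(series: NetworkSeries, hypnogram: Hypnogram | None = None,
                     seed: int = 0) -> tuple[StateModel, StateLabels | None]:
    """Full state decomposition of a windowed network series."""
    C, keep = build_connection_matrix(series)
    loadings, tc, explained = pca_first(C)
    gmm = fit_two_gmm(tc, seed=seed)
    means, sds, weights = _gmm_params(gmm)
    thr = gmm_threshold(gmm)
    model = StateModel(loadings=loadings, timecourse=tc,
                       explained_variance=explained, means=means, sds=sds,
                       weights=weights, threshold=thr, window_indices=keep)
    labels = None
    if hypnogram is not None:
        labels = classify_and_score(tc, thr, series.window_starts[keep],
                                    series.window_s, hypnogram)
    return model, labels
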