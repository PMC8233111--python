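"""State averaging, windowed series, strength, stability, paired state tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from circanet import aggregate as ag
from circanet.connectivity import EpochTensor
from circanet.hypnogram import Hypnogram


def _tensor(Q, valid=None, n_channels=None):
    P, E = Q.shape
    if n_channels is None:
        n_channels = int(np.ceil((1 + np.sqrt(1 + 8 * P)) / 2))
    pairs = np.column_stack(np.triu_indices(n_channels, 1))[:P]
    if valid is None:
        valid = np.ones(E, dtype=bool)
    return EpochTensor(Q=Q.astype(np.uint8), reason=np.zeros_like(Q, np.int8),
                       valid=valid, times=np.arange(E, dtype=float),
                       pairs=pairs, labels=[f"c{i}" for i in range(n_channels)])


def _all_wake(E):
    return Hypnogram([0.0], [float(E)], ["W"])


class TestStateAverage:
    def test_half_significant_pair_converges_to_half(self, rng):
        Q = np.zeros((3, 2000), dtype=np.uint8)
        Q[0, ::2] = 1  # significant in exactly half the epochs
        t = _tensor(Q)
        W = ag.state_average(t, _all_wake(2000), "wake",
                             n_samp=1000, n_boot=200, seed=1)
        assert abs(W[0, 1] - 0.5) < 0.01

    def test_all_zero_tensor_gives_zero_network(self):
        t = _tensor(np.zeros((3, 100), dtype=np.uint8))
        W = ag.state_average(t, _all_wake(100), "wake", n_samp=50, n_boot=20)
        assert not W.any()

    def test_bootstrap_converges_to_plain_fraction(self, rng):
        Q = (rng.random((6, 800)) < 0.3).astype(np.uint8)
        t = _tensor(Q)
        hyp = _all_wake(800)
        W = ag.state_average(t, hyp, "wake", n_samp=800, n_boot=500, seed=2)
        plain = ag.plain_state_fraction(t, hyp, "wake")
        assert np.abs(W - plain).max() < 0.005

    def test_no_epochs_in_state_rejected(self):
        t = _tensor(np.zeros((3, 50), dtype=np.uint8))
        with pytest.raises(ValueError):
            ag.state_average(t, _all_wake(50), "sleep", n_samp=10, n_boot=5)

    def test_result_is_valid_fraction_network(self, rng):
        Q = (rng.random((10, 300)) < 0.4).astype(np.uint8)
        W = ag.state_average(_tensor(Q, n_channels=5), _all_wake(300), "wake",
                             n_samp=100, n_boot=50, seed=0)
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert W.min() >= 0 and W.max() <= 1


class TestWindowedSeries:
    def test_window_count_arithmetic(self):
        t = _tensor(np.zeros((1, 18000), dtype=np.uint8), n_channels=2)
        s = ag.windowed_series(t, window_s=300, step_s=30)
        assert s.n_windows == 591

    def test_overlap_is_90pct(self):
        assert (300 - 30) / 300 == 0.9

    def test_fraction_uses_valid_epochs_only(self):
        Q = np.zeros((1, 400), dtype=np.uint8)
        Q[0, :200] = 1
        valid = np.ones(400, dtype=bool)
        valid[100:200] = False  # significant but invalid: must not count
        t = _tensor(Q, valid=valid, n_channels=2)
        s = ag.windowed_series(t, window_s=400, step_s=400, min_valid=1)
        assert s.values[0, 0] == pytest.approx(100 / 300)

    def test_sparse_windows_flagged_unusable(self):
        valid = np.ones(600, dtype=bool)
        valid[300:] = False
        t = _tensor(np.zeros((1, 600), dtype=np.uint8), valid=valid,
                    n_channels=2)
        s = ag.windowed_series(t, window_s=300, step_s=300)
        assert s.usable[0] and not s.usable[1]

    def test_bad_parameters_rejected(self):
        t = _tensor(np.zeros((1, 600), dtype=np.uint8), n_channels=2)
        with pytest.raises(ValueError):
            ag.windowed_series(t, window_s=0)
        with pytest.raises(ValueError):
            ag.windowed_series(t, window_s=300, step_s=0)


class TestProportionalStrength:
    def test_171_pairs_average_top_17(self, rng):
        W = rng.uniform(0, 1, (19, 19))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        vals = np.sort(W[np.triu_indices(19, 1)])[::-1]
        assert ag.proportional_strength(W, 0.10) == pytest.approx(vals[:17].mean())

    def test_uniform_network_returns_the_weight(self):
        W = np.full((6, 6), 0.37)
        np.fill_diagonal(W, 0)
        assert ag.proportional_strength(W, 0.10) == pytest.approx(0.37)

    @given(hnp.arrays(np.float64, (8, 8), elements=st.floats(0, 1)),
           st.floats(0.05, 1.0))
    def test_matches_full_sort_oracle(self, A, frac):
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0)
        vals = np.sort(W[np.triu_indices(8, 1)])[::-1]
        k = max(int(np.floor(frac * len(vals))), 1)
        assert ag.proportional_strength(W, frac) == pytest.approx(vals[:k].mean())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ag.proportional_strength(np.zeros((3, 3)), 0.0)


class TestNetworkCorr2d:
    def test_identity_is_one(self, rng):
        from conftest import symmetric_network
        W = symmetric_network(rng, 6)
        assert ag.network_corr2d(W, W) == pytest.approx(1.0)

    def test_positive_affine_transform_is_one(self, rng):
        from conftest import symmetric_network
        W = symmetric_network(rng, 6)
        assert ag.network_corr2d(W, 0.3 * W + 0.1) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        from conftest import symmetric_network
        A = symmetric_network(rng, 7)
        B = symmetric_network(rng, 7)
        iu = np.triu_indices(7, 1)
        expect = np.corrcoef(A[iu], B[iu])[0, 1]
        assert ag.network_corr2d(A, B) == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        W = np.zeros((4, 4))
        with pytest.raises(ValueError):
            ag.network_corr2d(W, W)


class TestStability:
    def test_iid_tensor_correlation_increases_with_window(self, rng):
        # larger windows average out sampling noise, raising the correlation
        p = rng.uniform(0.1, 0.6, size=20)
        Q = (rng.random((20, 6000)) < p[:, None]).astype(np.uint8)
        curve = ag.stability_curve(_tensor(Q, n_channels=7), _all_wake(6000),
                                   "wake", sizes=(10, 30, 60, 120, 200))
        vals = [curve[n] for n in (10, 30, 60, 120, 200)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_constant_tensor_windows_skipped(self):
        Q = np.ones((4, 300), dtype=np.uint8)
        with pytest.warns(UserWarning):
            curve = ag.stability_curve(_tensor(Q, n_channels=4),
                                       _all_wake(300), "wake", sizes=(50,))
        assert curve == {}

    def test_short_state_omits_large_windows(self, rng):
        Q = (rng.random((4, 150)) < 0.4).astype(np.uint8)
        with pytest.warns(UserWarning):
            curve = ag.stability_curve(_tensor(Q, n_channels=4),
                                       _all_wake(150), "wake", sizes=(50, 100))
        assert 50 in curve and 100 not in curve

    def test_group_ci_contains_mean(self):
        curves = [{10: 0.2, 50: 0.5}, {10: 0.3, 50: 0.6}, {10: 0.25, 50: 0.55}]
        df = ag.stability_group_ci(curves)
        row = df[df.window_s == 50].iloc[0]
        assert row.ci_low <= row["mean"] <= row.ci_high


class TestPairwiseStateTests:
    def test_identical_states_yield_no_significant_pairs(self, rng):
        from conftest import symmetric_network
        nets = [symmetric_network(rng, 6) for _ in range(8)]
        res = ag.pairwise_state_tests(nets, [w.copy() for w in nets])
        assert not res.significant.any()

    def test_benjamini_hochberg_hand_example(self, monkeypatch):
        # p-values (0.01, 0.02, 0.04, 0.5) at q = 0.05: BH thresholds are
        # i/m*q = (0.0125, 0.025, 0.0375, 0.05), so the first two reject
        from statsmodels.stats.multitest import multipletests
        rej, _, _, _ = multipletests(np.array([0.01, 0.02, 0.04, 0.5]),
                                     alpha=0.05, method="fdr_bh")
        assert list(rej) == [True, True, False, False]

    def test_designated_pairs_detected(self, rng):
        # 19 synthetic subjects; 5 designated pairs stronger in sleep
        n, subjects = 8, 19
        iu = np.triu_indices(n, 1)
        designated = [0, 3, 7, 12, 20]
        Qw, Qs = [], []
        for _ in range(subjects):
            base = rng.uniform(0.05, 0.2, size=len(iu[0]))
            wake = base + rng.normal(0, 0.01, len(base))
            sleep = base + rng.normal(0, 0.01, len(base))
            sleep[designated] += 0.15
            for vals, out in ((wake, Qw), (sleep, Qs)):
                W = np.zeros((n, n))
                W[iu] = np.clip(vals, 0, 1)
                out.append(W + W.T)
        res = ag.pairwise_state_tests(Qw, Qs)
        hits = res.iloc[designated]
        others = res.drop(index=designated)
        assert (hits.significant & (hits.stronger_in == "sleep")).mean() >= 0.8
        assert others.significant.mean() < 0.05

    def test_unequal_subject_sets_rejected(self, rng):
        from conftest import symmetric_network
        nets = [symmetric_network(rng, 5) for _ in range(6)]
        with pytest.raises(ValueError):
            ag.pairwise_state_tests(nets, nets[:-1])
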