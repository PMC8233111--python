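"""Cross-correlation statistic, corrected z, permutation null, epoch tensor."""

import numpy as np
import pytest
from scipy import signal as sps

from circanet import connectivity as cn
from circanet import preprocess as pp
from circanet.recording import Recording


def brute_force_max_xcorr(x, y, max_lag):
    """Exhaustive per-lag oracle with the same tie-break convention."""
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    n = len(x)
    best_r, best_lag = 0.0, 0
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            r = float(xs[: n - lag] @ ys[lag:]) / n
        else:
            r = float(xs[-lag:] @ ys[: n + lag]) / n
        if abs(r) > abs(best_r):
            best_r, best_lag = r, lag
    return best_r, best_lag


class TestMaxCrosscorr:
    def test_pure_shift_recovers_lag(self, rng):
        x = rng.standard_normal(200)
        y = np.roll(x, 5)  # y trails x by 5 samples
        r, lag = cn.max_crosscorr(x, y, 40)
        assert lag == 5
        assert abs(abs(r) - 1) < 0.05  # biased estimator shrinks by (N-5)/N

    def test_identity_gives_zero_lag_unit_r(self, rng):
        x = rng.standard_normal(200)
        r, lag = cn.max_crosscorr(x, x, 40)
        assert lag == 0 and abs(r - 1) < 1e-12

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            x = rng.standard_normal(150)
            y = rng.standard_normal(150)
            r1, l1 = cn.max_crosscorr(x, y, 40)
            r2, l2 = brute_force_max_xcorr(x, y, 40)
            assert l1 == l2
            assert abs(r1 - r2) < 1e-10

    def test_swapping_inputs_negates_lag(self, rng):
        x = rng.standard_normal(200)
        y = np.roll(x, 7) + 0.3 * rng.standard_normal(200)
        r1, l1 = cn.max_crosscorr(x, y, 40)
        r2, l2 = cn.max_crosscorr(y, x, 40)
        assert l2 == -l1
        assert abs(abs(r1) - abs(r2)) < 1e-12

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            cn.max_crosscorr(np.ones(100), rng.standard_normal(100), 10)


class TestCorrectedZ:
    def test_zero_correlation_gives_zero_z(self, rng):
        assert cn.corrected_z(0.0, rng.standard_normal(200),
                              rng.standard_normal(200)) == 0.0

    def test_white_noise_sd_near_inverse_sqrt_n(self, rng):
        # for white noise only tau=0 contributes, so s ~ 1/sqrt(200) ~ 0.0707
        s = np.mean([cn.bartlett_sd(rng.standard_normal(200),
                                    rng.standard_normal(200))
                     for _ in range(300)])
        assert abs(s - 1 / np.sqrt(200)) < 0.01

    def test_autocorrelated_signals_inflate_sd(self, rng):
        t = np.arange(200) / 200.0
        slow_x = np.sin(2 * np.pi * 3 * t) + 0.1 * rng.standard_normal(200)
        slow_y = np.sin(2 * np.pi * 3 * t + 1.0) + 0.1 * rng.standard_normal(200)
        s_slow = cn.bartlett_sd(slow_x, slow_y)
        s_white = cn.bartlett_sd(rng.standard_normal(200),
                                 rng.standard_normal(200))
        assert s_slow > 3 * s_white

    def test_r_at_or_beyond_one_rejected(self, rng):
        with pytest.raises(ValueError):
            cn.corrected_z(1.0, rng.standard_normal(100), rng.standard_normal(100))


def _white_epochs(rng, n_channels, n_seconds, fs=200):
    rec = Recording(data=rng.standard_normal((n_channels, n_seconds * fs)), fs=fs)
    mask = pp.ArtifactMask(flags=np.zeros(rec.n_samples, dtype=bool), fs=fs)
    return pp.cut_epochs(rec, mask)


class TestNull:
    def test_threshold_is_nearest_rank_95th(self, rng):
        eps = _white_epochs(rng, 2, 30)
        null = cn.build_null(eps, 0, 1, n_iter=500, seed=1)
        assert len(null.values) == 500
        # 475 of 500 values sit at or below the threshold
        assert (null.values <= null.threshold).sum() == 475
        assert null.threshold == null.values[474]

    def test_same_seed_same_threshold(self, rng):
        eps = _white_epochs(rng, 2, 30)
        t1 = cn.build_null(eps, 0, 1, n_iter=200, seed=5).threshold
        t2 = cn.build_null(eps, 0, 1, n_iter=200, seed=5).threshold
        assert t1 == t2

    def test_too_little_data_rejected(self, rng):
        eps = _white_epochs(rng, 2, 2)
        with pytest.raises(ValueError):
            cn.build_null(eps, 0, 1, n_iter=100, seed=0)

    def test_fresh_epoch_false_positive_rate_near_5pct(self, rng):
        # independent white noise: applying the threshold to fresh epochs
        # flags close to the nominal 5% (6 pairs x 1,500 epochs)
        eps = _white_epochs(rng, 4, 1500)
        nulls = cn.build_all_nulls(eps, n_iter=500, seed=3)
        tensor = cn.epoch_networks(eps, nulls)
        rate = tensor.Q.mean()
        assert 0.035 <= rate <= 0.065


class TestReferenceCheck:
    def _bandnoise(self, rng, n, fs=200):
        sos = sps.butter(4, [3, 8], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(n + 400))[200:-200]
        return x / x.std()

    def test_reference_contamination_discarded(self, rng):
        thr = 2.0
        sig, kept = 0, 0
        for _ in range(300):
            ref = self._bandnoise(rng, 200)
            x = 0.5 * rng.standard_normal(200) + ref
            y = 0.5 * rng.standard_normal(200) + ref
            r, lag = cn.max_crosscorr(x, y, 40)
            z = cn.corrected_z(min(abs(r), 1 - 1e-12), x, y)
            if lag != 0 and z > thr:
                sig += 1
                kept += cn.reference_check(x, y, ref, lag, thr)
        assert sig > 50
        assert 1 - kept / sig > 0.8  # discarded in > 80% of significant epochs

    def test_genuine_coupling_survives_independent_reference(self, rng):
        thr = 2.0
        sig, kept = 0, 0
        for _ in range(300):
            src = self._bandnoise(rng, 203)
            x = 0.5 * rng.standard_normal(200) + src[3:]
            y = 0.5 * rng.standard_normal(200) + src[:200]
            ref = self._bandnoise(rng, 200)
            r, lag = cn.max_crosscorr(x, y, 40)
            z = cn.corrected_z(min(abs(r), 1 - 1e-12), x, y)
            if lag != 0 and z > thr:
                sig += 1
                kept += cn.reference_check(x, y, ref, lag, thr)
        assert sig > 100
        assert kept / sig > 0.95

    def test_orthogonal_reference_is_noop(self, rng):
        # a reference uncorrelated with both leaves the decision unchanged
        src = self._bandnoise(rng, 204)
        x = 0.2 * rng.standard_normal(200) + src[4:]
        y = 0.2 * rng.standard_normal(200) + src[:200]
        ref = self._bandnoise(rng, 200)
        r, lag = cn.max_crosscorr(x, y, 40)
        assert lag != 0
        assert cn.reference_check(x, y, ref, lag, z_threshold=2.0)


class TestEpochNetworks:
    def test_19_channels_yield_171_pairs(self, rng):
        eps = _white_epochs(rng, 19, 12)
        nulls = cn.build_all_nulls(eps, n_iter=50, seed=0)
        tensor = cn.epoch_networks(eps, nulls)
        assert tensor.n_pairs == 171

    def test_all_invalid_epochs_give_empty_tensor(self, rng):
        rec = Recording(data=rng.standard_normal((3, 10 * 200)), fs=200)
        # enough valid epochs to build nulls, then invalidate everything
        clean = pp.cut_epochs(rec, pp.ArtifactMask(
            flags=np.zeros(rec.n_samples, dtype=bool), fs=200))
        nulls = cn.build_all_nulls(clean, n_iter=50, seed=0)
        with pytest.warns(UserWarning):
            eps = pp.cut_epochs(rec, pp.ArtifactMask(
                flags=np.ones(rec.n_samples, dtype=bool), fs=200))
        tensor = cn.epoch_networks(eps, nulls)
        assert tensor.Q.sum() == 0
        assert (tensor.reason == cn.REASON_EPOCH_ARTIFACT).all()

    def test_coupled_pair_detected_uncoupled_near_nominal(self, small_subject):
        tensor = small_subject["tensor"]
        truth = small_subject["truth"]
        coupled = truth.sleep_coupling[tensor.pairs[:, 0], tensor.pairs[:, 1]] > 0
        rates = tensor.Q[:, tensor.valid].mean(axis=1)
        assert rates[coupled].min() > 2 * rates[~coupled].max()
        assert np.all(rates[~coupled] < 0.10)

    def test_zero_lag_entries_excluded_with_reason(self, rng):
        # identical channels: max |xcorr| at lag 0 in every epoch
        x = rng.standard_normal(10 * 200)
        rec = Recording(data=np.vstack([x, x, rng.standard_normal(10 * 200)]),
                        fs=200)
        eps = pp.cut_epochs(rec, pp.ArtifactMask(
            flags=np.zeros(rec.n_samples, dtype=bool), fs=200))
        nulls = cn.build_all_nulls(eps, n_iter=50, seed=0)
        tensor = cn.epoch_networks(eps, nulls)
        pair01 = 0  # (0, 1) in upper-triangle order
        assert tensor.Q[pair01].sum() == 0
        assert (tensor.reason[pair01] == cn.REASON_ZERO_LAG).all()

    def test_state_counts_from_hypnogram(self, small_subject):
        tensor = small_subject["tensor"]
        n_w, n_s = tensor.state_counts(small_subject["schedule"])
        assert n_w + n_s == int(tensor.valid.sum())
        assert n_w > 0 and n_s > 0
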