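"""Boosting TRF estimation, cross-validated encoding, transfer, word epochs."""

import numpy as np
import pandas as pd
import pytest

from predtend.simulate import canonical_trf, make_word_schedule
from predtend.trf import (
    EncodingScore,
    TRFKernel,
    boost_trf,
    crossval_encoding,
    lag_matrix,
    lag_samples,
    pearson_r,
    transfer_encoding,
    word_epoch_encoding,
)

FS = 100.0


def envelope_like(n, seed=0):
    rng = np.random.default_rng(seed)
    from scipy import signal as sp

    sos = sp.butter(4, [2.0, 8.0], btype="bandpass", fs=FS, output="sos")
    x = sp.sosfiltfilt(sos, rng.standard_normal(n + 200))[100 : 100 + n]
    return np.clip(1.0 + x / x.std(), 0, None)


def convolve_truth(env, kernel):
    x = env - env.mean()
    return np.convolve(x, kernel)[: len(env)]


class TestBoostTrf:
    def test_lag_axis_has_61_coefficients_at_100hz(self):
        assert len(lag_samples(FS)) == 61
        k = boost_trf(envelope_like(3000), np.random.default_rng(0).standard_normal(3000), FS)
        assert k.weights.shape == (1, 61)
        assert k.lags_s[0] == pytest.approx(-0.1) and k.lags_s[-1] == pytest.approx(0.5)

    def test_pure_delay_recovered(self):
        env = envelope_like(4000, seed=1)
        true = np.zeros(61)
        true[lag_samples(FS).tolist().index(10)] = 1.0  # 100 ms delay
        y = np.roll(env - env.mean(), 10)
        y[:10] = 0
        k = boost_trf(env, y, FS)
        w = k.weights[0]
        assert k.lags_s[np.argmax(np.abs(w))] == pytest.approx(0.1)
        assert pearson_r(w, true) > 0.99

    def test_smooth_kernel_recovered_noiselessly(self):
        # broadband stimulus: a narrowband envelope leaves the kernel's
        # null-space component unidentifiable (predictions unaffected)
        env = np.abs(np.random.default_rng(2).standard_normal(4000))
        truth = canonical_trf()
        y = convolve_truth(env, truth)
        k = boost_trf(env, y, FS)
        mask = (k.lags_s >= 0) & (k.lags_s < 0.4)
        assert pearson_r(k.weights[0][mask], truth) > 0.99

    def test_unrelated_noise_yields_near_zero_kernel(self):
        rng = np.random.default_rng(3)
        k = boost_trf(envelope_like(3000, seed=3), rng.standard_normal(3000), FS)
        assert np.abs(k.weights).max() < 0.1

    def test_training_mse_never_worse_than_zero_kernel(self):
        env = envelope_like(2000, seed=4)
        y = convolve_truth(env, canonical_trf()) + 0.5 * np.random.default_rng(4).standard_normal(2000)
        k = boost_trf(env, y, FS)
        x = (env - env.mean()) / env.std()
        yz = (y - y.mean()) / y.std()
        pred = (lag_matrix(x, lag_samples(FS)) @ k.weights[0])
        assert np.mean((yz - pred) ** 2) < np.mean(yz**2)

    def test_near_least_squares_in_noiseless_limit(self):
        # oracle equivalence on a small instance with few lags
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        truth = np.array([0.0, 1.0, 0.5, -0.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        lags = np.arange(10)
        y = lag_matrix(x, lags) @ truth
        k = boost_trf(x, y, FS, lags_s=(0.0, 0.09), patience=50, max_iter=20000)
        X = lag_matrix((x - x.mean()) / x.std(), lags)
        yz = (y - y.mean()) / y.std()
        w_ls, *_ = np.linalg.lstsq(X, yz, rcond=None)
        r_boost = pearson_r(X @ k.weights[0], yz)
        r_ls = pearson_r(X @ w_ls, yz)
        assert r_ls - r_boost < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            boost_trf(np.ones(1000), np.random.default_rng(0).standard_normal(1000), FS)
        bad = np.random.default_rng(0).standard_normal(1000)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            boost_trf(bad, np.random.default_rng(1).standard_normal(1000), FS)


class TestCrossvalEncoding:
    def test_noiseless_generative_data_scores_high(self):
        env = envelope_like(6000, seed=6)
        truth = canonical_trf()
        resp = np.stack([convolve_truth(env, truth), convolve_truth(env, 0.5 * truth)])
        score, kernel = crossval_encoding(env, resp, FS)
        assert np.all(score.r > 0.95)
        assert kernel.weights.shape == (2, 61)

    def test_independent_noise_scores_near_zero_over_seeds(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            env = envelope_like(1500, seed=seed)
            score, _ = crossval_encoding(env, rng.standard_normal(1500), FS)
            rs.append(score.r[0])
        assert abs(np.nanmean(rs)) < 0.05

    def test_shifted_response_destroys_encoding(self):
        env = envelope_like(4000, seed=7)
        y = convolve_truth(env, canonical_trf())
        shifted = np.roll(y, 100)  # 1 s >> max lag
        score, _ = crossval_encoding(env, shifted, FS)
        assert abs(score.r[0]) < 0.1

    def test_scale_invariance(self):
        env = envelope_like(3000, seed=8)
        y = convolve_truth(env, canonical_trf()) + 0.3 * np.random.default_rng(8).standard_normal(3000)
        r1, _ = crossval_encoding(env, y, FS)
        r2, _ = crossval_encoding(5.0 * env, 3.0 * y, FS)
        assert r1.r[0] == pytest.approx(r2.r[0], abs=1e-9)

    def test_invalid_folds_rejected(self):
        env = envelope_like(1000, seed=9)
        with pytest.raises(ValueError, match="k >= 2"):
            crossval_encoding(env, env, FS, k=1)
        with pytest.raises(ValueError, match="lag span"):
            crossval_encoding(envelope_like(200, seed=9), np.random.default_rng(0).standard_normal(200), FS, k=4)


class TestTransferEncoding:
    def test_transfer_matches_crossval_on_fresh_data(self):
        truth = canonical_trf()
        env_a, env_b = envelope_like(5000, seed=10), envelope_like(5000, seed=11)
        rng = np.random.default_rng(10)
        ya = convolve_truth(env_a, truth) + 0.5 * rng.standard_normal(5000)
        yb = convolve_truth(env_b, truth) + 0.5 * rng.standard_normal(5000)
        cv, kernel = crossval_encoding(env_a, ya, FS)
        tr = transfer_encoding(kernel, env_b, yb, FS)
        assert abs(tr.r[0] - cv.r[0]) < 0.1

    def test_zero_kernel_flagged_not_silent_zero(self):
        kernel = TRFKernel(np.zeros((2, 61)), lag_samples(FS) / FS, FS)
        env = envelope_like(1000, seed=12)
        score = transfer_encoding(kernel, env, np.zeros((2, 1000)) + np.random.default_rng(0).standard_normal((2, 1000)), FS)
        assert np.all(np.isnan(score.r))
        assert not score.valid.any()

    def test_rate_mismatch_rejected(self):
        kernel = TRFKernel(np.ones((1, 61)), lag_samples(FS) / FS, FS)
        with pytest.raises(ValueError, match="rate mismatch"):
            transfer_encoding(kernel, envelope_like(500), np.zeros((1, 500)), 200.0)


class TestWordEpochEncoding:
    def _session(self, gain_high=1.0, seed=0, duration=120.0):
        rng = np.random.default_rng(seed)
        env = envelope_like(int(duration * FS), seed=seed)
        events = make_word_schedule(duration, seed=seed)
        truth = canonical_trf()
        gainvec = np.ones(len(env))
        for o in events.loc[events.category == "high", "onset_s"]:
            s = int(round(o * FS))
            gainvec[s : s + 200] = gain_high
        y = gainvec * convolve_truth(env, truth) + 2.5 * rng.standard_normal(len(env))
        return env, y[None, :], events

    def test_word_epochs_are_200_samples(self):
        env, y, events = self._session()
        from predtend.trf import _category_segments

        segs = _category_segments(env, y, events, "high", FS)
        assert all(b - a == 200 for a, b in segs)

    def test_equal_gain_gives_equal_scores_on_average(self):
        diffs = []
        for seed in range(5):
            env, y, events = self._session(gain_high=1.0, seed=seed)
            scores = word_epoch_encoding(env, y, events, FS)
            diffs.append(scores["high"].r[0] - scores["low"].r[0])
        assert abs(np.mean(diffs)) < 0.1

    def test_surprisal_gain_boost_raises_high_scores(self):
        diffs = []
        for seed in range(5):
            env, y, events = self._session(gain_high=3.0, seed=seed)
            scores = word_epoch_encoding(env, y, events, FS)
            diffs.append(scores["high"].r[0] - scores["low"].r[0])
        assert np.mean(diffs) > 0.05

    def test_empty_category_named_in_error(self):
        env, y, events = self._session()
        events = events[events.category != "low"]
        with pytest.raises(ValueError, match="'low'"):
            word_epoch_encoding(env, y, events, FS)


def test_encoding_score_validates_correlation_range():
    with pytest.raises(ValueError, match=r"\[-1, 1\]"):
        EncodingScore(r=np.array([1.5]))
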