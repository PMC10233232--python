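"""Time-resolved LDA decoding, transition relabelling and tendency scalars."""

import numpy as np
import pandas as pd
import pytest

from predtend.decoding import (
    DecisionValues,
    apply_decoder,
    contrast_forward_vs_repetition,
    decoding_accuracy,
    dvals_to_transitions,
    estimate_tendency,
    fit_timeresolved_decoder,
    prediction_tendency,
    restrict_times,
    updating_tendency,
)
from predtend.paradigm import TRANSITION_LABELS
from predtend.preprocessing import SensorEpochs


def gaussian_epochs(n_per_class=40, n_channels=6, n_times=5, sep=4.0, seed=0):
    """Four well-separated Gaussian classes, constant over timepoints."""
    rng = np.random.default_rng(seed)
    means = sep * np.eye(4, n_channels)
    data, tones = [], []
    for c in range(4):
        x = means[c] + rng.standard_normal((n_per_class, n_channels))
        data.append(np.repeat(x[:, :, None], n_times, axis=2))
        tones += [c + 1] * n_per_class
    labels = pd.DataFrame({"tone": tones})
    times = np.arange(n_times) / 100.0
    return SensorEpochs(data=np.concatenate(data), times_s=times, labels=labels)


class TestDecoder:
    def test_separable_classes_decoded_above_95(self):
        train = gaussian_epochs(seed=0)
        test = gaussian_epochs(seed=1)
        model = fit_timeresolved_decoder(train)
        _, acc = decoding_accuracy(model, test)
        assert acc > 0.95

    def test_shuffled_labels_fall_to_chance(self):
        train = gaussian_epochs(seed=0)
        rng = np.random.default_rng(5)
        shuffled = train.labels["tone"].to_numpy().copy()
        rng.shuffle(shuffled)
        model = fit_timeresolved_decoder(train, labels=shuffled)
        _, acc = decoding_accuracy(model, gaussian_epochs(seed=2))
        assert abs(acc - 0.25) < 0.1

    def test_duplicating_trials_leaves_model_unchanged(self):
        train = gaussian_epochs(seed=0)
        doubled = SensorEpochs(
            data=np.concatenate([train.data, train.data]),
            times_s=train.times_s,
            labels=pd.concat([train.labels] * 2, ignore_index=True),
        )
        test = gaussian_epochs(seed=3)
        # fixed shrinkage: the auto (Ledoit-Wolf) intensity adapts to the
        # trial count, so duplication invariance holds for fixed intensity
        dv1 = apply_decoder(fit_timeresolved_decoder(train, shrinkage=0.1), test)
        dv2 = apply_decoder(fit_timeresolved_decoder(doubled, shrinkage=0.1), test)
        assert np.allclose(dv1.dvals, dv2.dvals, atol=1e-8)

    def test_training_trial_classified_as_own_class(self):
        train = gaussian_epochs(seed=0)
        model = fit_timeresolved_decoder(train)
        dv = apply_decoder(model, train, dval_scale="raw")
        pred = model.classes[np.argmax(dv.dvals, axis=1)]
        truth = train.labels["tone"].to_numpy()[:, None]
        assert np.mean(pred == truth) > 0.99

    def test_missing_class_named_in_error(self):
        train = gaussian_epochs(seed=0)
        keep = train.labels["tone"] != 3
        with pytest.raises(ValueError, match=r"\[3\]"):
            fit_timeresolved_decoder(train.select(keep.to_numpy()))

    def test_time_axis_mismatch_rejected(self):
        model = fit_timeresolved_decoder(gaussian_epochs(n_times=5))
        test = gaussian_epochs(n_times=4)
        with pytest.raises(ValueError, match="time axis"):
            apply_decoder(model, test)

    def test_agrees_with_bruteforce_bayes_on_small_instance(self):
        # plug-in Bayes rule with shared pooled covariance, built by hand
        rng = np.random.default_rng(7)
        train = gaussian_epochs(n_per_class=5, n_channels=3, n_times=1, sep=4.0, seed=8)
        test = gaussian_epochs(n_per_class=10, n_channels=3, n_times=1, sep=4.0, seed=9)
        model = fit_timeresolved_decoder(train)
        dv = apply_decoder(model, test, dval_scale="raw")
        pred = model.classes[np.argmax(dv.dvals[:, :, 0], axis=1)]

        X = train.data[:, :, 0]
        y = train.labels["tone"].to_numpy()
        means = np.stack([X[y == c].mean(axis=0) for c in (1, 2, 3, 4)])
        resid = np.concatenate([X[y == c] - means[c - 1] for c in (1, 2, 3, 4)])
        cov = resid.T @ resid / (len(X) - 4)
        icov = np.linalg.inv(cov)
        Xt = test.data[:, :, 0]
        scores = Xt @ icov @ means.T - 0.5 * np.einsum("ci,ij,cj->c", means, icov, means)
        bayes = np.argmax(scores, axis=1) + 1
        assert np.mean(pred == bayes) >= 0.9

    def test_chance_level_accuracy_bounds(self):
        model = fit_timeresolved_decoder(gaussian_epochs(seed=0))
        acc_tc, acc = decoding_accuracy(model, gaussian_epochs(seed=4))
        assert np.all((acc_tc >= 0) & (acc_tc <= 1)) and 0 <= acc <= 1
        with pytest.raises(ValueError, match="empty"):
            decoding_accuracy(model, gaussian_epochs(seed=4).select(np.zeros(160, bool)))


class TestTransitions:
    def _dv(self, dvals, prev):
        n, _, t = dvals.shape
        return DecisionValues(
            dvals=dvals,
            times_s=np.arange(t) / 100,
            prev_tone=np.asarray(prev),
            condition=np.array(["ordered"] * n),
        )

    def test_relabelling_follows_preceding_tone(self):
        dvals = np.arange(4, dtype=float).reshape(1, 4, 1)  # d1..d4 = 0..3
        trans, _ = dvals_to_transitions(self._dv(dvals, [1]))
        by_name = dict(zip(TRANSITION_LABELS, trans[0, :, 0]))
        assert by_name["repetition"] == 0.0  # d1 | prev f1
        assert by_name["forward"] == 1.0  # d2 | prev f1
        trans4, _ = dvals_to_transitions(self._dv(dvals, [4]))
        by_name4 = dict(zip(TRANSITION_LABELS, trans4[0, :, 0]))
        assert by_name4["forward"] == 0.0  # d1 | prev f4 wraps forward
        assert by_name4["repetition"] == 3.0

    def test_relabelling_is_a_pure_permutation(self):
        rng = np.random.default_rng(0)
        dvals = rng.random((7, 4, 3))
        trans, kept = dvals_to_transitions(self._dv(dvals, [1, 2, 3, 4, 1, 2, 3]))
        assert kept.all()
        assert np.allclose(trans.sum(axis=1), dvals.sum(axis=1))

    def test_unknown_preceding_tone_excluded(self):
        dvals = np.ones((3, 4, 2))
        trans, kept = dvals_to_transitions(self._dv(dvals, [1, 0, 2]))
        assert kept.tolist() == [True, False, True]
        assert trans.shape[0] == 2


class TestContrast:
    def test_hand_computed_constant_contrast(self):
        trans = np.zeros((10, 4, 6))
        trans[:, TRANSITION_LABELS.index("forward"), :] = 0.6
        trans[:, TRANSITION_LABELS.index("repetition"), :] = 0.4
        c = contrast_forward_vs_repetition(trans)
        assert np.allclose(c, 0.2)

    def test_equal_evidence_gives_zero(self):
        trans = np.full((5, 4, 4), 0.25)
        assert np.allclose(contrast_forward_vs_repetition(trans), 0.0)

    def test_swapping_labels_flips_sign(self):
        rng = np.random.default_rng(1)
        trans = rng.random((8, 4, 5))
        c = contrast_forward_vs_repetition(trans)
        i_f, i_r = TRANSITION_LABELS.index("forward"), TRANSITION_LABELS.index("repetition")
        swapped = trans.copy()
        swapped[:, [i_f, i_r], :] = swapped[:, [i_r, i_f], :]
        assert np.allclose(contrast_forward_vs_repetition(swapped), -c)

    def test_empty_trial_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contrast_forward_vs_repetition(np.zeros((0, 4, 3)))


class TestTendencyScalars:
    def _times(self):
        # 61 samples, -0.3 .. 0.3 s at 100 Hz
        return np.round(np.arange(-30, 31) / 100.0, 10)

    def test_identical_conditions_give_zero(self):
        t = self._times()
        c = np.random.default_rng(0).random(len(t))
        assert prediction_tendency(t, c, c) == 0.0
        assert updating_tendency(t, c, c) == 0.0

    def test_hand_computed_prediction_tendency(self):
        t = self._times()
        ordered = np.full(len(t), 0.2)
        random = np.full(len(t), 0.1)
        # 30 pre-stimulus samples in [-0.3, 0) each contributing 0.1
        assert prediction_tendency(t, ordered, random) == pytest.approx(3.0)

    def test_hand_computed_updating_tendency_sign_convention(self):
        t = self._times()
        ordered = np.full(len(t), -0.2)
        random = np.full(len(t), -0.1)
        # repetition-directed: more negative ordered contrast -> positive value
        assert updating_tendency(t, ordered, random) == pytest.approx(3.0)

    def test_boundary_sample_excluded_from_both_windows(self):
        t = self._times()
        diff = np.zeros(len(t))
        diff[np.argmin(np.abs(t))] = 5.0  # only t = 0 differs
        assert prediction_tendency(t, diff, np.zeros(len(t))) == 0.0
        assert updating_tendency(t, diff, np.zeros(len(t))) == 0.0

    def test_window_outside_axis_rejected(self):
        t = np.arange(0.1, 0.3, 0.01)
        with pytest.raises(ValueError, match="window"):
            prediction_tendency(t, np.zeros(len(t)), np.zeros(len(t)))


class TestEndToEnd:
    def test_tendency_increases_with_preactivation_gain(self, tiny_cohort):
        # two subjects with different g_pred: estimates should order like them
        subs = [tiny_cohort.subject(i, include=("tone",)) for i in range(2)]
        results = [estimate_tendency(s.tone_runs) for s in subs]
        g = [s.ground_truth.g_pred for s in subs]
        est = [r.prediction_tendency for r in results]
        assert (est[0] < est[1]) == (g[0] < g[1])
        for r in results:
            assert np.isfinite(r.updating_tendency)
            assert 0 <= r.decoding_accuracy <= 1

    def test_rotation_invariance_of_prediction_tendency(self, tiny_cohort):
        from scipy.stats import ortho_group

        sub = tiny_cohort.subject(0, include=("tone",))
        base = estimate_tendency(sub.tone_runs).prediction_tendency
        q = ortho_group.rvs(sub.ground_truth.n_channels, random_state=0)
        rotated = {
            cond: type(rec)(data=q @ rec.data, fs_hz=rec.fs_hz, events=rec.events)
            for cond, rec in sub.tone_runs.items()
        }
        rotated_est = estimate_tendency(rotated).prediction_tendency
        # shrinkage toward the scaled identity is rotation-equivariant up to
        # the numerics of the auto intensity estimate
        assert rotated_est == pytest.approx(base, rel=1e-2)
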