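"""Time-resolved tone decoding and the prediction-tendency measure.

A multiclass LDA (with automatic covariance shrinkage) is fit at every
epoch timepoint on *ordered forward-transition* trials only, then applied
to *self-repetition* trials of both entropy conditions.  The per-class
decision values are relabelled into transition types relative to the
preceding tone, the forward-vs-repetition evidence is contrasted over
trials, and the subject's **prediction tendency** is the summed
pre-stimulus ([-0.3, 0) s) excess of that contrast in the ordered over the
random context.  Testing on the same trial type (repetitions) in both
conditions equates the carry-over of the preceding tone's response, so the
contrast isolates anticipatory preactivation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .paradigm import TRANSITION_LABELS, N_TONES
from .preprocessing import SensorEpochs

logger = logging.getLogger(__name__)


@dataclass
class TimeResolvedDecoder:
    """One shrinkage-LDA model per epoch timepoint."""

    models: list
    times_s: np.ndarray
    classes: np.ndarray


@dataclass
class DecisionValues:
    """Per-trial, per-class, per-timepoint classifier evidence."""

    dvals: np.ndarray  # trials x 4 x timepoints, class axis ordered f1..f4
    times_s: np.ndarray
    prev_tone: np.ndarray
    condition: np.ndarray  # per-trial entropy label


@dataclass
class TendencyResult:
    times_s: np.ndarray
    contrast_ordered: np.ndarray
    contrast_random: np.ndarray
    prediction_tendency: float
    updating_tendency: float
    n_trials: dict
    decoding_accuracy: float | None = None


def restrict_times(epochs: SensorEpochs, tmin_s: float, tmax_s: float) -> SensorEpochs:
    """Keep samples with tmin <= t <= tmax (inclusive window)."""
    mask = (epochs.times_s >= tmin_s - 1e-9) & (epochs.times_s <= tmax_s + 1e-9)
    return SensorEpochs(
        data=epochs.data[:, :, mask], times_s=epochs.times_s[mask], labels=epochs.labels
    )


def fit_timeresolved_decoder(
    epochs: SensorEpochs,
    labels: np.ndarray | None = None,
    shrinkage: str | float = "auto",
) -> TimeResolvedDecoder:
    """Fit an independent shrinkage LDA at each timepoint.

    ``labels`` defaults to the epochs' ``tone`` column.  All four tone
    classes must be present.  ``shrinkage`` is the covariance shrinkage
    intensity toward the scaled identity ("auto" = Ledoit-Wolf).
    """
    y = np.asarray(labels if labels is not None else epochs.labels["tone"].to_numpy())
    present = np.unique(y)
    missing = sorted(set(range(1, N_TONES + 1)) - set(present.tolist()))
    if missing:
        raise ValueError(f"training set lacks tone class(es): {missing}")
    counts = np.bincount(y, minlength=N_TONES + 1)[1:]
    if counts.min() < 2:
        raise ValueError("need >= 2 training trials per class")
    models = []
    for t in range(epochs.data.shape[2]):
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        lda.fit(epochs.data[:, :, t], y)
        models.append(lda)
    return TimeResolvedDecoder(models=models, times_s=epochs.times_s.copy(), classes=present)


def apply_decoder(
    model: TimeResolvedDecoder, epochs: SensorEpochs, dval_scale: str = "softmax"
) -> DecisionValues:
    """Evaluate the decoder on test epochs, one dval per class and timepoint.

    ``dval_scale="softmax"`` (default) normalises the discriminant scores
    per trial/timepoint so evidence is amplitude-comparable across
    conditions; ``"raw"`` returns the scores themselves.
    """
    if len(model.times_s) != len(epochs.times_s) or not np.allclose(
        model.times_s, epochs.times_s, atol=1e-9
    ):
        raise ValueError("epoch time axis does not match the decoder's")
    if dval_scale not in ("softmax", "raw"):
        raise ValueError("dval_scale must be 'softmax' or 'raw'")
    n_trials = epochs.n_trials
    dvals = np.empty((n_trials, N_TONES, len(model.times_s)))
    for t, lda in enumerate(model.models):
        scores = lda.decision_function(epochs.data[:, :, t])
        if dval_scale == "softmax":
            scores = softmax(scores, axis=1)
        dvals[:, :, t] = scores
    prev = (
        epochs.labels["prev_tone"].to_numpy()
        if "prev_tone" in epochs.labels
        else np.zeros(n_trials, dtype=int)
    )
    cond = (
        epochs.labels["condition"].to_numpy()
        if "condition" in epochs.labels
        else np.array([""] * n_trials)
    )
    return DecisionValues(dvals=dvals, times_s=model.times_s.copy(), prev_tone=prev, condition=cond)


def dvals_to_transitions(dv: DecisionValues) -> tuple[np.ndarray, np.ndarray]:
    """Relabel the class axis into transition types given the preceding tone.

    Returns ``(trans_dvals, kept)`` where ``trans_dvals`` is
    trials x 4 x timepoints with the transition axis ordered as
    ``TRANSITION_LABELS`` (repetition, forward, two_step, backward) and
    ``kept`` flags trials with a known preceding tone; excluded trials are
    logged.  Values are untouched — this is a pure permutation per trial.
    """
    kept = (dv.prev_tone >= 1) & (dv.prev_tone <= N_TONES)
    n_excluded = int(np.sum(~kept))
    if n_excluded:
        logger.warning("excluded %d trials without a preceding tone", n_excluded)
    prev = dv.prev_tone[kept]
    sub = dv.dvals[kept]
    out = np.empty_like(sub)
    for step in range(N_TONES):
        # transition `step` corresponds to tone class (prev - 1 + step) mod 4
        cls = (prev - 1 + step) % N_TONES
        out[:, step, :] = sub[np.arange(len(prev)), cls, :]
    return out, kept


def contrast_forward_vs_repetition(
    trans_dvals: np.ndarray, centering: str = "per_timepoint"
) -> np.ndarray:
    """Zero-centred forward-vs-repetition evidence timecourse.

    Per trial and timepoint the two used dvals are centred on their mean,
    then the (forward - repetition) difference is averaged over trials —
    positive values mean forward (prediction-consistent) evidence.  With
    ``centering="across_time"`` the trial-averaged timecourse is
    additionally centred on its temporal mean.
    """
    if trans_dvals.shape[0] == 0:
        raise ValueError("empty trial set")
    i_rep = TRANSITION_LABELS.index("repetition")
    i_fwd = TRANSITION_LABELS.index("forward")
    fwd, rep = trans_dvals[:, i_fwd, :], trans_dvals[:, i_rep, :]
    center = (fwd + rep) / 2.0
    contrast = np.mean((fwd - center) - (rep - center), axis=0)
    if centering == "across_time":
        contrast = contrast - contrast.mean()
    elif centering != "per_timepoint":
        raise ValueError("centering must be 'per_timepoint' or 'across_time'")
    return contrast


def _window_sum(
    times_s: np.ndarray, diff: np.ndarray, lo: float, hi: float, include_lo: bool, include_hi: bool
) -> float:
    lo_ok = times_s >= lo - 1e-9 if include_lo else times_s > lo + 1e-9
    hi_ok = times_s <= hi + 1e-9 if include_hi else times_s < hi - 1e-9
    mask = lo_ok & hi_ok
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] s outside the contrast time axis")
    return float(np.sum(diff[mask]))


def prediction_tendency(
    times_s: np.ndarray,
    contrast_ordered: np.ndarray,
    contrast_random: np.ndarray,
    window_s: tuple[float, float] = (-0.3, 0.0),
) -> float:
    """Summed pre-stimulus (ordered - random) forward contrast, [-0.3, 0) s."""
    diff = np.asarray(contrast_ordered) - np.asarray(contrast_random)
    return _window_sum(times_s, diff, window_s[0], window_s[1], True, False)


def updating_tendency(
    times_s: np.ndarray,
    contrast_ordered: np.ndarray,
    contrast_random: np.ndarray,
    window_s: tuple[float, float] = (0.0, 0.3),
) -> float:
    """Summed post-stimulus repetition-directed contrast, (0, 0.3] s.

    The sign convention is repetition-directed: a more negative
    (repetition-favouring) ordered-minus-random contrast yields a more
    positive updating tendency.
    """
    diff = np.asarray(contrast_ordered) - np.asarray(contrast_random)
    return -_window_sum(times_s, diff, window_s[0], window_s[1], False, True)


def estimate_tendency(
    tone_runs: dict,
    analysis_window_s: tuple[float, float] = (-0.3, 0.3),
    tmin_s: float = -0.4,
    tmax_s: float = 0.8,
    dval_scale: str = "softmax",
    centering: str = "per_timepoint",
    accuracy_holdout: float = 0.2,
) -> TendencyResult:
    """Full per-subject tendency estimate from ordered and random tone runs.

    Trains the time-resolved decoder on ordered forward trials, tests on
    self-repetition trials of both conditions, contrasts forward-vs-
    repetition evidence and integrates the condition difference pre- and
    post-stimulus.  A frequency-decoding-accuracy control is computed on a
    held-out fraction of the forward trials (mean accuracy over the
    post-stimulus half of the analysis window).
    """
    from .preprocessing import epoch as _epoch

    epochs = {}
    for cond in ("ordered", "random"):
        rec = tone_runs[cond]
        ep = _epoch(rec, rec.events["onset_s"].to_numpy(), tmin_s, tmax_s, labels=rec.events)
        epochs[cond] = restrict_times(ep, *analysis_window_s)

    fwd_mask = (epochs["ordered"].labels["transition_label"] == "forward").to_numpy()
    train = epochs["ordered"].select(fwd_mask)
    model = fit_timeresolved_decoder(train)

    contrasts = {}
    n_trials = {"ordered_forward_train": int(fwd_mask.sum())}
    for cond in ("ordered", "random"):
        rep_mask = (epochs[cond].labels["transition_label"] == "repetition").to_numpy()
        test = epochs[cond].select(rep_mask)
        n_trials[f"{cond}_repetition_test"] = int(rep_mask.sum())
        dv = apply_decoder(model, test, dval_scale=dval_scale)
        trans, _ = dvals_to_transitions(dv)
        contrasts[cond] = contrast_forward_vs_repetition(trans, centering=centering)

    times = epochs["ordered"].times_s
    pred = prediction_tendency(times, contrasts["ordered"], contrasts["random"])
    upd = updating_tendency(times, contrasts["ordered"], contrasts["random"])

    # control variable: 4-class decoding accuracy on held-out forward trials
    # random (seeded) holdout: periodic subsampling would alias the
    # near-period-4 forward cycling of ordered sequences
    n_train = train.n_trials
    n_hold = max(int(round(accuracy_holdout * n_train)), 8)
    hold_idx = np.zeros(n_train, dtype=bool)
    hold_idx[np.random.default_rng(n_train).permutation(n_train)[:n_hold]] = True
    acc = None
    try:
        sub_model = fit_timeresolved_decoder(train.select(~hold_idx))
        acc_tc, _ = decoding_accuracy(sub_model, train.select(hold_idx))
        post = (times > 0) & (times <= analysis_window_s[1] + 1e-9)
        acc = float(acc_tc[post].mean())
    except ValueError:
        logger.warning("decoding-accuracy control skipped (too few trials)")

    return TendencyResult(
        times_s=times,
        contrast_ordered=contrasts["ordered"],
        contrast_random=contrasts["random"],
        prediction_tendency=pred,
        updating_tendency=upd,
        n_trials=n_trials,
        decoding_accuracy=acc,
    )


def decoding_accuracy(
    model: TimeResolvedDecoder, epochs: SensorEpochs, labels: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-timepoint and mean fraction of trials whose argmax dval is correct."""
    if epochs.n_trials == 0:
        raise ValueError("empty test set")
    y = np.asarray(labels if labels is not None else epochs.labels["tone"].to_numpy())
    dv = apply_decoder(model, epochs, dval_scale="raw")
    pred = model.classes[np.argmax(dv.dvals, axis=1)]  # trials x timepoints
    acc = np.mean(pred == y[:, None], axis=0)
    return acc, float(acc.mean())
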