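"""Synthetic cohort generator with known ground truth.

Two kinds of sessions are simulated per subject, mirroring the two
paradigms the pipeline analyses:

* **Tone runs** — multichannel responses to 4-tone Markov sequences.  Each
  tone evokes a channel-space pattern convolved with a gamma-shaped kernel
  peaking ~100 ms after onset.  In *ordered* runs only, the pattern of the
  forward successor of the preceding tone is additionally injected into the
  300 ms before each onset with amplitude ``g_pred`` — the subject's
  anticipatory preactivation gain, the generative counterpart of
  "prediction tendency".  Carry-over of the previous tone's evoked response
  into the pre-stimulus window arises naturally from the 333-ms SOA.

* **Speech trials** — per channel, the response is the ground-truth TRF
  convolved with a target-speaker envelope, scaled by a tracking gain that
  follows the linear model the statistics stage later estimates:
  ``gain = intercept + b_ndist*n + b_tendency*g_pred + b_interaction*n*g_pred
  + subject_intercept``, plus leaked distractor-envelope responses and
  noise.  High/low word-surprisal epochs reuse bitwise-identical envelope
  segments, so surprisal effects are purely response-side.

All randomness flows from a single seed through ``numpy`` SeedSequences, so
cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import gamma as gamma_dist

from .paradigm import (
    DEFAULT_SOA_S,
    ToneSequence,
    build_transition_matrix,
    classify_transition,
    forward_successor,
    generate_sequence,
)
from .preprocessing import ContinuousRecording

# ---------------------------------------------------------------------------
# sensor grid


@dataclass(frozen=True)
class SensorGrid:
    """Regular 2-D channel grid with rook (4-neighbour) adjacency."""

    nx: int = 6
    ny: int = 6

    @property
    def n_channels(self) -> int:
        return self.nx * self.ny

    @property
    def positions(self) -> np.ndarray:
        xs, ys = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)

    def adjacency(self) -> list[list[int]]:
        neigh: list[list[int]] = []
        for i in range(self.nx):
            for j in range(self.ny):
                cur: list[int] = []
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    a, b = i + di, j + dj
                    if 0 <= a < self.nx and 0 <= b < self.ny:
                        cur.append(a * self.ny + b)
                neigh.append(cur)
        return neigh

    def block_mask(self, x0: int, x1: int, y0: int, y1: int) -> np.ndarray:
        """Boolean mask over channels for a rectangular blob [x0,x1) x [y0,y1)."""
        mask = np.zeros((self.nx, self.ny), dtype=bool)
        mask[x0:x1, y0:y1] = True
        return mask.ravel()


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SubjectGroundTruth:
    """Generative parameters for one synthetic subject."""

    subject_id: str
    g_pred: float
    tone_patterns: np.ndarray  # 4 x channels, unit norm rows
    true_trf: np.ndarray  # channels x lags (causal, at fs)
    trf_lags_s: np.ndarray
    beta: dict[str, float | np.ndarray]
    subject_intercept: float
    noise_sd: float
    speech_noise_sd: float | None = None  # defaults to noise_sd

    def __post_init__(self) -> None:
        if self.g_pred < 0:
            raise ValueError("g_pred must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        norms = np.linalg.norm(self.tone_patterns, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("tone patterns must have unit norm")

    @property
    def n_channels(self) -> int:
        return self.tone_patterns.shape[1]

    @property
    def effective_speech_noise_sd(self) -> float:
        return self.noise_sd if self.speech_noise_sd is None else self.speech_noise_sd


DEFAULT_BETA = {
    "intercept": 1.0,
    "b_ndist": -0.25,
    "b_tendency": 0.4,
    "b_interaction": 0.0,
    "b_surprisal": 0.3,
    "b_surprisal_tendency": 0.0,
}


def evoked_kernel(fs_hz: float, peak_s: float = 0.1, shape: float = 3.0) -> np.ndarray:
    """Gamma-shaped evoked pulse, unit peak, ~400 ms support at the default."""
    scale = peak_s / (shape - 1.0)
    t = np.arange(0, 5 * shape * scale, 1.0 / fs_hz)
    k = gamma_dist.pdf(t, a=shape, scale=scale)
    return k / k.max()


def canonical_trf(fs_hz: float = 100.0, n_lags: int = 40) -> np.ndarray:
    """Biphasic causal kernel (positive ~80 ms, negative ~180 ms), unit max."""
    t = np.arange(n_lags) / fs_hz
    k = gamma_dist.pdf(t, a=3, scale=0.03) - 0.6 * gamma_dist.pdf(t, a=4, scale=0.045)
    return k / np.abs(k).max()


def make_subject_ground_truth(
    subject_id: str,
    n_channels: int,
    g_pred: float,
    rng: np.random.Generator,
    beta: dict | None = None,
    noise_sd: float = 1.0,
    speech_noise_sd: float | None = 8.0,
    subject_intercept_sd: float = 0.1,
    fs_hz: float = 100.0,
) -> SubjectGroundTruth:
    """Draw a subject's patterns, TRF and random intercept."""
    # orthonormal tone patterns -> classes are separable in channel space
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, 4)))
    patterns = q.T.copy()
    base = canonical_trf(fs_hz)
    # moderate per-channel amplitude heterogeneity; wider spreads drown
    # between-subject tracking effects in weight-driven SNR differences
    ch_weight = 0.75 + 0.5 * rng.random(n_channels)
    trf = ch_weight[:, None] * base[None, :]
    return SubjectGroundTruth(
        subject_id=subject_id,
        g_pred=g_pred,
        tone_patterns=patterns,
        true_trf=trf,
        trf_lags_s=np.arange(trf.shape[1]) / fs_hz,
        beta=dict(DEFAULT_BETA if beta is None else beta),
        subject_intercept=float(rng.normal(0.0, subject_intercept_sd)),
        noise_sd=noise_sd,
        speech_noise_sd=speech_noise_sd,
    )


# ---------------------------------------------------------------------------
# tone runs


def simulate_tone_run(
    ground_truth: SubjectGroundTruth,
    sequence: ToneSequence,
    fs_hz: float = 100.0,
    seed: int | None = None,
    pad_s: float = 0.6,
    preactivation_window_s: tuple[float, float] = (-0.3, 0.0),
) -> ContinuousRecording:
    """Simulate a continuous sensor run for one tone sequence.

    Every tone adds its channel pattern times the evoked kernel.  In
    ordered runs, the pattern of the *expected next tone* (forward
    successor of the previous tone) is added in the pre-stimulus window
    with amplitude ``g_pred``.  White Gaussian noise with ``noise_sd`` is
    added throughout.  Events are padded by ``pad_s`` so -400/+800 ms
    epochs never overlap the run edges.
    """
    if fs_hz < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    rng = np.random.default_rng(seed)
    gt = ground_truth
    n_ch = gt.n_channels
    onsets = sequence.onsets_s + pad_s
    n_samples = int(round((onsets[-1] + 1.0) * fs_hz))
    if int(round((onsets[0] - 0.4) * fs_hz)) < 0:
        raise ValueError("padding too short for the epoch window")
    data = rng.normal(0.0, gt.noise_sd, size=(n_ch, n_samples))
    kernel = evoked_kernel(fs_hz)
    klen = len(kernel)
    pre_lo = int(round(preactivation_window_s[0] * fs_hz))
    pre_hi = int(round(preactivation_window_s[1] * fs_hz))
    ordered = sequence.condition == "ordered"
    for i, (tone, onset) in enumerate(zip(sequence.tones, onsets)):
        s = int(round(onset * fs_hz))
        seg = min(klen, n_samples - s)
        data[:, s : s + seg] += np.outer(gt.tone_patterns[tone - 1], kernel[:seg])
        if ordered and i > 0 and gt.g_pred > 0:
            expected = forward_successor(int(sequence.tones[i - 1]))
            a, b = max(s + pre_lo, 0), max(s + pre_hi, 0)
            data[:, a:b] += gt.g_pred * gt.tone_patterns[expected - 1][:, None]
    prev = np.concatenate([[0], sequence.tones[:-1]])
    labels = np.array(
        [""] + [classify_transition(p, c) for p, c in zip(sequence.tones[:-1], sequence.tones[1:])],
        dtype=object,
    )
    events = pd.DataFrame(
        {
            "onset_s": onsets,
            "tone": sequence.tones,
            "prev_tone": prev,
            "transition_label": labels,
            "condition": sequence.condition,
        }
    )
    return ContinuousRecording(data=data, fs_hz=fs_hz, events=events)


# ---------------------------------------------------------------------------
# speech trials


@dataclass
class SimulatedSession:
    """One multi-speaker listening trial with ground-truth envelope."""

    brain: np.ndarray  # channels x samples
    envelope: np.ndarray  # target-speaker envelope, same length
    distractor_envelopes: np.ndarray  # n_dist x samples
    n_distractors: int
    word_events: pd.DataFrame  # onset_s, category
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.brain.shape[1] != len(self.envelope):
            raise ValueError("brain and envelope must share length")
        dur = len(self.envelope) / self.sample_rate_hz
        if len(self.word_events) and (self.word_events["onset_s"].max() + 2.0) > dur + 1e-9:
            raise ValueError("2-s word epochs must fit within the session")


def _positive_envelope(n: int, fs_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Positive 2-8 Hz modulated signal, unit SD, mean ~1."""
    white = rng.standard_normal(n + 2 * int(fs_hz))
    sos = sp_signal.butter(4, [2.0, 8.0], btype="bandpass", fs=fs_hz, output="sos")
    x = sp_signal.sosfiltfilt(sos, white)[int(fs_hz) : int(fs_hz) + n]
    x = x / x.std()
    return np.clip(1.0 + x, 0.0, None)


def make_word_schedule(
    duration_s: float,
    n_high: int | None = None,
    n_low: int | None = None,
    n_remaining: int | None = None,
    epoch_s: float = 2.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Non-overlapping 2-s word epochs on a grid; categories shuffled.

    Counts default to ~60% slot occupancy with a 1:1:4 high/low/remaining
    split (semantic violations are rare relative to ordinary words).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if n_high is None or n_low is None or n_remaining is None:
        total = max(int(0.6 * (int(duration_s // epoch_s) - 1)), 6)
        pair = max(total // 6, 2)
        n_high = pair if n_high is None else n_high
        n_low = pair if n_low is None else n_low
        n_remaining = total - n_high - n_low if n_remaining is None else n_remaining
    n_total = n_high + n_low + n_remaining
    n_slots = int(duration_s // epoch_s) - 1
    if n_slots < n_total:
        raise ValueError(
            f"duration {duration_s}s provides only {n_slots} epoch slots, need {n_total}"
        )
    slots = rng.choice(n_slots, size=n_total, replace=False) * epoch_s
    cats = np.array(["high"] * n_high + ["low"] * n_low + ["remaining"] * n_remaining)
    rng.shuffle(cats)
    df = pd.DataFrame({"onset_s": np.sort(slots), "category": cats[np.argsort(slots)]})
    return df.sort_values("onset_s").reset_index(drop=True)


def tracking_gain(gt: SubjectGroundTruth, n_distractors: int) -> np.ndarray:
    """Per-channel generative tracking gain for a distractor condition."""
    b = gt.beta
    gain = (
        np.asarray(b["intercept"], dtype=float)
        + np.asarray(b["b_ndist"], dtype=float) * n_distractors
        + np.asarray(b["b_tendency"], dtype=float) * gt.g_pred
        + np.asarray(b.get("b_interaction", 0.0), dtype=float) * n_distractors * gt.g_pred
        + gt.subject_intercept
    )
    return np.broadcast_to(np.atleast_1d(gain), (gt.n_channels,)).astype(float)


def simulate_speech_trial(
    ground_truth: SubjectGroundTruth,
    n_distractors: int,
    duration_s: float = 180.0,
    word_schedule: pd.DataFrame | None = None,
    seed: int | None = None,
    fs_hz: float = 100.0,
    leak: float = 0.3,
) -> SimulatedSession:
    """Simulate one listening trial under 0, 1 or 2 distractor speakers.

    High- and low-surprisal word epochs are paired in order of occurrence
    and the high epoch's envelope segment is overwritten with its paired
    low epoch's segment, so the two categories carry bitwise-identical
    acoustic input and surprisal effects are response-side only.
    """
    if n_distractors not in (0, 1, 2):
        raise ValueError("n_distractors must be 0, 1 or 2")
    if duration_s < 60:
        raise ValueError("duration must be >= 60 s")
    rng = np.random.default_rng(seed)
    gt = ground_truth
    n = int(round(duration_s * fs_hz))
    env = _positive_envelope(n, fs_hz, rng)
    if word_schedule is None:
        word_schedule = make_word_schedule(duration_s, rng=rng)
    # enforce identical acoustics for paired high/low epochs
    highs = word_schedule.loc[word_schedule.category == "high", "onset_s"].to_numpy()
    lows = word_schedule.loc[word_schedule.category == "low", "onset_s"].to_numpy()
    for h, lo in zip(highs, lows):
        hs, ls = int(round(h * fs_hz)), int(round(lo * fs_hz))
        span = int(round(2.0 * fs_hz))
        env[hs : hs + span] = env[ls : ls + span]
    dists = np.stack(
        [_positive_envelope(n, fs_hz, rng) for _ in range(n_distractors)]
    ) if n_distractors else np.empty((0, n))

    gain = tracking_gain(gt, n_distractors)
    b = gt.beta
    surp_mod = np.ones(n)
    boost = (
        np.asarray(b.get("b_surprisal", 0.0), dtype=float)
        + np.asarray(b.get("b_surprisal_tendency", 0.0), dtype=float) * gt.g_pred
    )
    if np.any(boost != 0):
        for h in highs:
            hs = int(round(h * fs_hz))
            surp_mod[hs : hs + int(round(2.0 * fs_hz))] = 1.0 + float(np.mean(boost))

    env_c = env - env.mean()
    brain = np.empty((gt.n_channels, n))
    for c in range(gt.n_channels):
        clean = np.convolve(env_c, gt.true_trf[c])[:n]
        brain[c] = gain[c] * surp_mod * clean
        for d in range(n_distractors):
            brain[c] += leak * np.convolve(dists[d] - dists[d].mean(), gt.true_trf[c])[:n]
    brain += rng.normal(0.0, gt.effective_speech_noise_sd, size=brain.shape)
    return SimulatedSession(
        brain=brain,
        envelope=env,
        distractor_envelopes=dists,
        n_distractors=n_distractors,
        word_events=word_schedule,
        sample_rate_hz=fs_hz,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortConfig:
    """Study-scale defaults: 49 subjects, 1,500 tones per entropy condition."""

    n_subjects: int = 49
    grid: SensorGrid = field(default_factory=SensorGrid)
    n_tones: int = 1500
    soa_s: float = DEFAULT_SOA_S
    speech_duration_s: float = 180.0
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    noise_sd: float = 1.0
    # speech noise dominates the per-voxel signal so that single-voxel
    # tracking r sits in a realistic low-to-mid range instead of at ceiling
    speech_noise_sd: float = 8.0
    subject_intercept_sd: float = 0.1
    g_pred_low: float = 0.0
    g_pred_high: float = 1.0
    leak: float = 0.3
    fs_hz: float = 100.0
    ordered_residual: str = "self"

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("invalid config value: n_subjects must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("invalid config value: noise_sd must be > 0")
        if self.g_pred_high < self.g_pred_low or self.g_pred_low < 0:
            raise ValueError("invalid config value: g_pred range must be 0 <= low <= high")
        if self.n_tones < 2:
            raise ValueError("invalid config value: n_tones must be >= 2")


@dataclass
class SubjectData:
    """All simulated sessions for one subject."""

    ground_truth: SubjectGroundTruth
    tone_runs: dict[str, ContinuousRecording]
    speech_trials: dict[int, SimulatedSession]


class Cohort:
    """Lazy cohort: ground truths up-front, sessions simulated on demand.

    Per-subject seeds are spawned from the cohort seed, so ``subject(i)``
    is reproducible independent of simulation order.
    """

    def __init__(self, config: CohortConfig, seed: int):
        config.validate()
        self.config = config
        self.seed = seed
        # explicit spawn keys: SeedSequence.spawn() is stateful, which would
        # make repeated subject(i) calls non-reproducible
        self.ground_truths: list[SubjectGroundTruth] = []
        for i in range(config.n_subjects):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 0)))
            g = rng.uniform(config.g_pred_low, config.g_pred_high)
            self.ground_truths.append(
                make_subject_ground_truth(
                    subject_id=f"sub-{i:03d}",
                    n_channels=config.grid.n_channels,
                    g_pred=g,
                    rng=rng,
                    beta=config.beta,
                    noise_sd=config.noise_sd,
                    speech_noise_sd=config.speech_noise_sd,
                    subject_intercept_sd=config.subject_intercept_sd,
                    fs_hz=config.fs_hz,
                )
            )

    @property
    def n_subjects(self) -> int:
        return self.config.n_subjects

    def subject(self, i: int, include: tuple[str, ...] = ("tone", "speech")) -> SubjectData:
        """Simulate subject ``i``'s sessions; ``include`` limits the kinds."""
        cfg = self.config
        gt = self.ground_truths[i]
        child = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(i, 1)))
        seeds = child.integers(0, 2**31 - 1, size=8)
        runs = {}
        if "tone" in include:
            for j, cond in enumerate(("ordered", "random")):
                mat = build_transition_matrix(cond, cfg.ordered_residual)
                seq = generate_sequence(mat, cfg.n_tones, cfg.soa_s, seed=int(seeds[j]))
                runs[cond] = simulate_tone_run(gt, seq, fs_hz=cfg.fs_hz, seed=int(seeds[2 + j]))
        trials = {}
        if "speech" in include:
            trials = {
                nd: simulate_speech_trial(
                    gt,
                    nd,
                    duration_s=cfg.speech_duration_s,
                    seed=int(seeds[4 + nd]),
                    fs_hz=cfg.fs_hz,
                    leak=cfg.leak,
                )
                for nd in (0, 1, 2)
            }
        return SubjectData(ground_truth=gt, tone_runs=runs, speech_trials=trials)

    def __iter__(self):
        for i in range(self.n_subjects):
            yield self.subject(i)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Build a reproducible synthetic cohort (lazy per-subject simulation)."""
    return Cohort(config if config is not None else CohortConfig(), seed)


# ---------------------------------------------------------------------------
# speech-like audio


def synthesize_speechlike_audio(
    duration_s: float,
    fs_hz: int = 44100,
    seed: int | None = None,
    modulator: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Broadband multi-band noise carrier amplitude-modulated at 2-8 Hz.

    Returns ``(waveform, modulator)`` where the modulator (at the audio
    rate) is the ground-truth envelope for oracle comparison with the
    envelope-extraction stage.
    """
    from .envelope import band_edges

    if duration_s < 1:
        raise ValueError("duration must be >= 1 s")
    edges = band_edges()
    if fs_hz <= 2 * edges[-1]:
        raise ValueError(f"sampling rate {fs_hz} below Nyquist of highest band")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    carrier = np.zeros(n)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
        carrier += sp_signal.sosfilt(sos, rng.standard_normal(n))
    carrier /= np.abs(carrier).max()
    if modulator is None:
        sos = sp_signal.butter(4, [2.0, 8.0], btype="bandpass", fs=fs_hz, output="sos")
        m = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
        modulator = np.clip(1.0 + m / m.std(), 0.0, None)
    else:
        modulator = np.asarray(modulator, dtype=float)
        if len(modulator) != n:
            raise ValueError("modulator length must match duration * fs")
    wave = carrier * modulator
    wave /= np.abs(wave).max()
    return wave, modulator
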