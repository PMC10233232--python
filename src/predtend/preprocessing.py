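"""Continuous-signal conditioning: band-pass filtering, resampling, epoching.

Mirrors the generic acquisition pipeline for passively recorded sensor
data: a zero-phase Kaiser-window FIR band-pass (default 0.1-30 Hz),
downsampling to 100 Hz, and epoching into 1,200-ms segments (-400 ms to
+800 ms around each tone onset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)


@dataclass
class ContinuousRecording:
    """channels x samples array with a sampling rate and an event table."""

    data: np.ndarray
    fs_hz: float
    events: pd.DataFrame | None = None  # columns: onset_s plus labels

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class SensorEpochs:
    """trials x channels x samples, with per-sample latencies and trial labels."""

    data: np.ndarray
    times_s: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[2] != len(self.times_s):
            raise ValueError("time axis length mismatch")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per trial")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "SensorEpochs":
        mask = np.asarray(mask)
        return SensorEpochs(
            data=self.data[mask],
            times_s=self.times_s,
            labels=self.labels.loc[mask].reset_index(drop=True),
        )


def design_bandpass(
    fs_hz: float,
    low_hz: float = 0.1,
    high_hz: float = 30.0,
    transition_hz: float | None = None,
    ripple_db: float = 60.0,
) -> np.ndarray:
    """Kaiser-window FIR band-pass taps (linear phase, odd length)."""
    nyq = fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist {nyq}"
        )
    if transition_hz is None:
        # narrow transition at the low edge matters for a 0.1 Hz cutoff
        transition_hz = min(max(low_hz, 2.0), (nyq - high_hz))
    numtaps, beta = signal.kaiserord(ripple_db, transition_hz / nyq)
    numtaps |= 1  # odd length -> integer group delay, type-I band-pass
    return signal.firwin(
        numtaps, [low_hz, high_hz], window=("kaiser", beta), pass_zero=False, fs=fs_hz
    )


def bandpass_filter(
    recording: ContinuousRecording,
    low_hz: float = 0.1,
    high_hz: float = 30.0,
    transition_hz: float | None = None,
    ripple_db: float = 60.0,
) -> ContinuousRecording:
    """Zero-phase FIR band-pass per channel (filtfilt on linear-phase taps)."""
    taps = design_bandpass(recording.fs_hz, low_hz, high_hz, transition_hz, ripple_db)
    padlen = min(3 * len(taps), recording.n_samples - 1)
    filtered = signal.filtfilt(taps, [1.0], recording.data, axis=1, padlen=padlen)
    return ContinuousRecording(data=filtered, fs_hz=recording.fs_hz, events=recording.events)


def resample(recording: ContinuousRecording, fs_target: float = 100.0) -> ContinuousRecording:
    """Polyphase anti-aliased resampling; event onsets (in seconds) are unchanged."""
    if fs_target <= 0:
        raise ValueError("target sampling rate must be positive")
    if fs_target > recording.fs_hz:
        raise ValueError("upsampling is not supported here")
    from fractions import Fraction

    frac = Fraction(fs_target / recording.fs_hz).limit_denominator(10000)
    out = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    return ContinuousRecording(data=out, fs_hz=fs_target, events=recording.events)


def epoch(
    recording: ContinuousRecording,
    onsets_s: np.ndarray,
    tmin_s: float = -0.4,
    tmax_s: float = 0.8,
    labels: pd.DataFrame | None = None,
) -> SensorEpochs:
    """Cut [onset+tmin, onset+tmax) windows around event onsets.

    Half-open sample convention: the window holds
    round((tmax - tmin) * fs) samples starting at round((onset+tmin) * fs).
    Out-of-bounds windows are dropped with a logged count rather than
    zero-padded (padding would bias downstream decoding).
    """
    fs = recording.fs_hz
    onsets_s = np.asarray(onsets_s, dtype=float)
    n_win = int(round((tmax_s - tmin_s) * fs))
    if n_win < 1:
        raise ValueError("epoch window must contain at least one sample")
    starts = np.round((onsets_s + tmin_s) * fs).astype(int)
    in_bounds = (starts >= 0) & (starts + n_win <= recording.n_samples)
    n_dropped = int(np.sum(~in_bounds))
    if n_dropped:
        logger.warning("dropped %d/%d out-of-bounds epochs", n_dropped, len(onsets_s))
    starts_kept = starts[in_bounds]
    data = np.stack([recording.data[:, s : s + n_win] for s in starts_kept])
    times = tmin_s + np.arange(n_win) / fs
    if labels is None:
        if recording.events is not None and len(recording.events) == len(onsets_s):
            labels = recording.events
        else:
            labels = pd.DataFrame({"onset_s": onsets_s})
    labels = labels.loc[np.flatnonzero(in_bounds)].reset_index(drop=True)
    labels = labels.assign(n_dropped=n_dropped)
    return SensorEpochs(data=data, times_s=times, labels=labels)
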