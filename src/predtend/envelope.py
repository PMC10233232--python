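"""Speech-envelope extraction via a cochlear-spaced 9-band filterbank.

The audio is split into 9 bands between 100 Hz and 10 kHz whose edges are
equidistant on the ERB-rate scale (a standard operationalisation of equal
spacing on the cortical tonotopic map), the magnitude (Hilbert) envelope is
taken per band, bands are averaged, low-passed and resampled to 100 Hz to
align with the neural data.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass
class Waveform:
    samples: np.ndarray
    fs_hz: float = 44100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")


@dataclass
class EnvelopeSignal:
    values: np.ndarray  # nonnegative, at fs_hz
    fs_hz: float
    band_edges_hz: np.ndarray
    band_envelopes: np.ndarray | None = None  # n_bands x samples at the audio rate


def erb_rate(f_hz):
    """ERB-rate (Cam) scale: 21.4 * log10(1 + 0.00437 f)."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f_hz, dtype=float))


def erb_rate_inverse(cams):
    return (10.0 ** (np.asarray(cams, dtype=float) / 21.4) - 1.0) / 0.00437


def band_edges(fmin_hz: float = 100.0, fmax_hz: float = 10000.0, n_bands: int = 9) -> np.ndarray:
    """n_bands+1 edges spanning [fmin, fmax], equidistant in ERB-rate."""
    if not (0 < fmin_hz < fmax_hz) or n_bands < 1:
        raise ValueError("need 0 < fmin < fmax and n_bands >= 1")
    cams = np.linspace(erb_rate(fmin_hz), erb_rate(fmax_hz), n_bands + 1)
    edges = erb_rate_inverse(cams)
    edges[0], edges[-1] = fmin_hz, fmax_hz  # pin endpoints exactly
    return edges


def extract_envelope(
    waveform: Waveform,
    fs_out: float = 100.0,
    fmin_hz: float = 100.0,
    fmax_hz: float = 10000.0,
    n_bands: int = 9,
    combine: str = "mean",
    antialias_hz: float = 45.0,
    keep_bands: bool = False,
) -> EnvelopeSignal:
    """Band-filter, per-band magnitude envelope, combine, low-pass, resample.

    ``combine`` is "mean" (default) or "sum" across bands; the anti-alias
    low-pass (default 45 Hz) is applied before resampling to ``fs_out``.
    """
    fs = waveform.fs_hz
    if fs <= 2 * fmax_hz:
        raise ValueError(f"sampling rate {fs} too low for band up to {fmax_hz} Hz")
    if antialias_hz >= fs_out / 2 * 1.0 + 1e-9 and antialias_hz > fs_out / 2:
        raise ValueError("anti-alias cutoff must not exceed the output Nyquist")
    if combine not in ("mean", "sum"):
        raise ValueError("combine must be 'mean' or 'sum'")
    edges = band_edges(fmin_hz, fmax_hz, n_bands)
    x = waveform.samples
    band_envs = np.empty((n_bands, len(x)))
    for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        band = signal.sosfiltfilt(sos, x)
        band_envs[b] = np.abs(signal.hilbert(band))
    env = band_envs.mean(axis=0) if combine == "mean" else band_envs.sum(axis=0)
    sos_lp = signal.butter(4, antialias_hz, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos_lp, env)
    frac = Fraction(fs_out / fs).limit_denominator(100000)
    env_out = signal.resample_poly(env, frac.numerator, frac.denominator)
    env_out = np.clip(env_out, 0.0, None)  # filtering can undershoot slightly
    return EnvelopeSignal(
        values=env_out,
        fs_hz=fs_out,
        band_edges_hz=edges,
        band_envelopes=band_envs if keep_bands else None,
    )
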