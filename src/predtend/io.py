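"""File round-tripping: HDF5 sensor data, CSV tables, WAV audio."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .paradigm import ToneSequence
from .preprocessing import ContinuousRecording
from .simulate import SimulatedSession, SubjectData, SubjectGroundTruth


def write_wav(path: str | Path, samples: np.ndarray, fs_hz: int) -> None:
    wavfile.write(str(path), int(fs_hz), np.asarray(samples, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    fs, data = wavfile.read(str(path))
    return np.asarray(data, dtype=float), int(fs)


def sequence_to_csv(seq: ToneSequence, path: str | Path) -> None:
    """CSV of the tone stream plus a JSON sidecar with the seed/condition."""
    path = Path(path)
    seq.to_frame().to_csv(path, index=False)
    sidecar = {"condition": seq.condition, "soa_s": seq.soa_s, "seed": seq.seed,
               "tone_freqs_hz": list(seq.tone_freqs_hz)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def save_envelope(path: str | Path, env) -> None:
    """Envelope values to CSV with a JSON sidecar holding the band edges."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": np.arange(len(env.values)) / env.fs_hz, "envelope": env.values}
    ).to_csv(path, index=False)
    sidecar = {"fs_hz": env.fs_hz, "band_edges_hz": list(map(float, env.band_edges_hz))}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_envelope(path: str | Path):
    from .envelope import EnvelopeSignal

    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return EnvelopeSignal(
        values=frame["envelope"].to_numpy(),
        fs_hz=float(sidecar["fs_hz"]),
        band_edges_hz=np.asarray(sidecar["band_edges_hz"]),
    )


def _write_events(group: h5py.Group, name: str, events: pd.DataFrame) -> None:
    group.create_dataset(name, data=events.to_csv(index=False).encode())


def _read_events(group: h5py.Group, name: str) -> pd.DataFrame:
    import io as _io

    return pd.read_csv(_io.BytesIO(group[name][()]))


def save_subject_h5(path: str | Path, subject: SubjectData) -> None:
    """One HDF5 container per subject: tone runs, speech trials, ground truth."""
    gt = subject.ground_truth
    with h5py.File(path, "w") as f:
        tone = f.create_group("tone")
        for cond, rec in subject.tone_runs.items():
            g = tone.create_group(cond)
            g.create_dataset("data", data=rec.data, compression="gzip")
            g.attrs["fs_hz"] = rec.fs_hz
            _write_events(g, "events", rec.events)
        speech = f.create_group("speech")
        for nd, sess in subject.speech_trials.items():
            g = speech.create_group(f"{nd}dist")
            g.create_dataset("brain", data=sess.brain, compression="gzip")
            g.create_dataset("envelope", data=sess.envelope, compression="gzip")
            if sess.distractor_envelopes.size:
                g.create_dataset(
                    "distractor_envelopes", data=sess.distractor_envelopes, compression="gzip"
                )
            g.attrs["n_distractors"] = sess.n_distractors
            g.attrs["sample_rate_hz"] = sess.sample_rate_hz
            _write_events(g, "word_events", sess.word_events)
        truth = f.create_group("truth")
        truth.attrs["subject_id"] = gt.subject_id
        truth.attrs["g_pred"] = gt.g_pred
        truth.attrs["subject_intercept"] = gt.subject_intercept
        truth.attrs["noise_sd"] = gt.noise_sd
        truth.attrs["beta"] = json.dumps({k: float(np.mean(v)) for k, v in gt.beta.items()})
        truth.create_dataset("tone_patterns", data=gt.tone_patterns)
        truth.create_dataset("true_trf", data=gt.true_trf)
        truth.create_dataset("trf_lags_s", data=gt.trf_lags_s)


def load_subject_h5(path: str | Path) -> SubjectData:
    with h5py.File(path, "r") as f:
        truth = f["truth"]
        gt = SubjectGroundTruth(
            subject_id=str(truth.attrs["subject_id"]),
            g_pred=float(truth.attrs["g_pred"]),
            tone_patterns=truth["tone_patterns"][()],
            true_trf=truth["true_trf"][()],
            trf_lags_s=truth["trf_lags_s"][()],
            beta=json.loads(truth.attrs["beta"]),
            subject_intercept=float(truth.attrs["subject_intercept"]),
            noise_sd=float(truth.attrs["noise_sd"]),
        )
        runs = {}
        for cond in f["tone"]:
            g = f["tone"][cond]
            runs[cond] = ContinuousRecording(
                data=g["data"][()], fs_hz=float(g.attrs["fs_hz"]), events=_read_events(g, "events")
            )
        trials = {}
        for key in f["speech"]:
            g = f["speech"][key]
            nd = int(g.attrs["n_distractors"])
            dist = (
                g["distractor_envelopes"][()]
                if "distractor_envelopes" in g
                else np.empty((0, g["envelope"].shape[0]))
            )
            trials[nd] = SimulatedSession(
                brain=g["brain"][()],
                envelope=g["envelope"][()],
                distractor_envelopes=dist,
                n_distractors=nd,
                word_events=_read_events(g, "word_events"),
                sample_rate_hz=float(g.attrs["sample_rate_hz"]),
            )
    return SubjectData(ground_truth=gt, tone_runs=runs, speech_trials=trials)
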