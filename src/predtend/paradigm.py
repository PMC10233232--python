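"""Entropy-modulation tone paradigm: transition structure and sequence generation.

Four pure tones (f1: 440 Hz, f2: 587 Hz, f3: 782 Hz, f4: 1043 Hz) are
presented at 3 Hz.  In the *ordered* context the cyclically next tone
("forward" transition, f1->f2, f2->f3, f3->f4, f4->f1) follows with
probability 0.75 and a self-repetition with probability 0.25; in the
*random* context all 16 transitions are uniform at 0.25.  The first-order
Markov structure defined here is shared by the simulator (which injects
anticipatory preactivation of the expected next tone) and by the decoding
stage (which relabels classifier evidence into transition types).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_TONES = 4
TONE_FREQS_HZ = (440.0, 587.0, 782.0, 1043.0)
DEFAULT_SOA_S = 1.0 / 3.0
TONE_DURATION_S = 0.1

# indexed by the cyclic step (cur - prev) mod 4
TRANSITION_LABELS = ("repetition", "forward", "two_step", "backward")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 matrix; row = preceding tone, column = next tone."""

    probs: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (N_TONES, N_TONES):
            raise ValueError(f"transition matrix must be 4x4, got {probs.shape}")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every row of a transition matrix must sum to 1")
        object.__setattr__(self, "probs", probs)


@dataclass
class ToneSequence:
    """A generated tone stream: identities (1..4) plus onset times."""

    tones: np.ndarray
    onsets_s: np.ndarray
    condition: str
    tone_freqs_hz: tuple = TONE_FREQS_HZ
    soa_s: float = DEFAULT_SOA_S
    seed: int | None = None

    def __post_init__(self) -> None:
        self.tones = np.asarray(self.tones, dtype=int)
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.tones.shape != self.onsets_s.shape:
            raise ValueError("tones and onsets must have equal length")
        if np.any((self.tones < 1) | (self.tones > N_TONES)):
            raise ValueError("tone indices must lie in 1..4")
        if len(self.onsets_s) > 1 and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.tones)

    @property
    def transition_labels(self) -> np.ndarray:
        """Label of the transition *into* each tone; first entry is ''. """
        labels = np.empty(len(self), dtype=object)
        labels[0] = ""
        for i in range(1, len(self)):
            labels[i] = classify_transition(self.tones[i - 1], self.tones[i])
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "tone": self.tones,
                "onset_s": self.onsets_s,
                "condition": self.condition,
                "transition_label": self.transition_labels,
            }
        )


def forward_successor(tone: int) -> int:
    """Cyclic successor: 1->2, 2->3, 3->4, 4->1."""
    if not 1 <= tone <= N_TONES:
        raise ValueError(f"tone index out of range 1..4: {tone}")
    return tone % N_TONES + 1


def classify_transition(prev: int, cur: int) -> str:
    """Classify an ordered tone pair by its cyclic step.

    forward: cur is the cyclic successor of prev (f4 -> f1 wraps);
    repetition: cur == prev; backward: cyclic predecessor; two_step: the
    remaining (opposite) tone.
    """
    for t in (prev, cur):
        if not 1 <= int(t) <= N_TONES:
            raise ValueError(f"tone index out of range 1..4: {t}")
    step = (int(cur) - int(prev)) % N_TONES
    return TRANSITION_LABELS[step]


def build_transition_matrix(
    condition: str, ordered_residual: str = "self"
) -> TransitionMatrix:
    """Build the paradigm's transition matrix for an entropy condition.

    ordered: P(forward successor) = 0.75 and, with the default
    ``ordered_residual="self"``, P(repetition) = 0.25 (other entries 0);
    ``ordered_residual="uniform"`` spreads the residual 0.25 uniformly
    over the three non-forward tones.  random: all entries 0.25.
    """
    if condition == "random":
        probs = np.full((N_TONES, N_TONES), 0.25)
    elif condition == "ordered":
        probs = np.zeros((N_TONES, N_TONES))
        for prev in range(1, N_TONES + 1):
            probs[prev - 1, forward_successor(prev) - 1] = 0.75
            if ordered_residual == "self":
                probs[prev - 1, prev - 1] = 0.25
            elif ordered_residual == "uniform":
                for other in range(1, N_TONES + 1):
                    if other != forward_successor(prev):
                        probs[prev - 1, other - 1] += 0.25 / 3.0
            else:
                raise ValueError(
                    f"unknown ordered_residual {ordered_residual!r}; "
                    "expected 'self' or 'uniform'"
                )
    else:
        raise ValueError(
            f"unknown entropy condition {condition!r}; expected 'ordered' or 'random'"
        )
    return TransitionMatrix(probs=probs, condition=condition)


def generate_sequence(
    matrix: TransitionMatrix,
    n_tones: int,
    soa_s: float = DEFAULT_SOA_S,
    seed: int | None = None,
) -> ToneSequence:
    """Draw a first-order Markov tone sequence from ``matrix``.

    The first tone is uniform over the four tones; tone t+1 is drawn from
    the matrix row of tone t.  Onsets are k * soa_s.  Reproducible given
    (matrix, n_tones, seed).
    """
    if n_tones < 2:
        raise ValueError("n_tones must be >= 2")
    rng = np.random.default_rng(seed)
    tones = np.empty(n_tones, dtype=int)
    tones[0] = rng.integers(1, N_TONES + 1)
    # cumulative rows let each draw be a single uniform comparison
    cum = np.cumsum(matrix.probs, axis=1)
    u = rng.random(n_tones - 1)
    for i in range(1, n_tones):
        tones[i] = int(np.searchsorted(cum[tones[i - 1] - 1], u[i - 1])) + 1
    onsets = np.arange(n_tones) * soa_s
    return ToneSequence(
        tones=tones, onsets_s=onsets, condition=matrix.condition, soa_s=soa_s, seed=seed
    )


def transition_counts(sequence: ToneSequence) -> dict[str, int]:
    """Tally consecutive-pair transition types over a sequence."""
    labels = sequence.transition_labels[1:]
    return {name: int(np.sum(labels == name)) for name in TRANSITION_LABELS}
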