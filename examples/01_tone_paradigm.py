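"""Generate entropy-modulated tone sequences and inspect their statistics.

The paradigm presents four pure tones at 3 Hz under two transition
regimes: an ordered context (75% cyclic "forward" steps, 25%
self-repetitions) and a random context (all 16 transitions at 25%).
"""

from predtend import build_transition_matrix, generate_sequence
from predtend.paradigm import transition_counts

for condition in ("ordered", "random"):
    matrix = build_transition_matrix(condition)
    seq = generate_sequence(matrix, n_tones=1500, seed=1)
    counts = transition_counts(seq)
    n = len(seq) - 1
    print(f"{condition} sequence ({len(seq)} tones):")
    for name, k in counts.items():
        print(f"  {name:>10}: {100 * k / n:5.1f} %")

# The ordered percentages should sit near 75/25 (forward/repetition) and
# the random ones near 25 each — the designed transition probabilities.
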