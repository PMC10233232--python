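"""Estimate a subject's prediction tendency from simulated tone runs.

A time-resolved LDA is trained on ordered forward-transition trials and
tested on self-repetition trials of both entropy conditions; the summed
pre-stimulus excess of forward-vs-repetition evidence (ordered > random)
is the subject's prediction tendency.  Here we simulate three subjects
with increasing anticipatory gain and watch the estimate follow it.
"""

from predtend import CohortConfig, SensorGrid, estimate_tendency, simulate_cohort

config = CohortConfig(n_subjects=3, grid=SensorGrid(4, 4), speech_duration_s=60)
cohort = simulate_cohort(config, seed=7)

print("subject   true gain   estimated tendency   decoding accuracy")
for i in range(cohort.n_subjects):
    subject = cohort.subject(i, include=("tone",))
    result = estimate_tendency(subject.tone_runs)
    gt = subject.ground_truth
    print(
        f"{gt.subject_id}   {gt.g_pred:9.2f}   {result.prediction_tendency:18.2f}"
        f"   {result.decoding_accuracy:17.2f}"
    )

# The estimated tendency should increase with the generative gain; the
# 4-class decoding accuracy (chance = 0.25) serves as a signal-to-noise
# control variable for the regression stage.
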