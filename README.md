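# predtend

Individual auditory **prediction tendency** and its relation to **cortical
speech tracking**, as a tested, fully synthetic-data-driven analysis
pipeline for MEG/EEG-style multichannel time series.

## The scientific problem

Listeners differ in how strongly they anticipate probable sounds. This
package implements a complete analysis chain that quantifies that
tendency and relates it to how well a listener's cortex tracks continuous
speech in multi-speaker scenes:

1. **Entropy-modulation paradigm** — sequences of four pure tones
   (440/587/782/1043 Hz) at 3 Hz, in an *ordered* context (cyclic forward
   transitions f1→f2→f3→f4→f1 with probability 0.75, self-repetitions
   0.25) and a *random* context (all transitions 0.25).
2. **Decoding-based tendency measure** — a time-resolved multiclass LDA is
   trained on ordered forward trials and tested on self-repetition trials
   of both contexts. Classifier evidence is relabelled into transitions
   relative to the preceding tone; prediction tendency is the summed
   pre-stimulus ([-0.3, 0) s) excess of forward-vs-repetition evidence in
   the ordered over the random context. Because both test sets contain
   the same trial type, carry-over of the preceding tone cancels in the
   contrast.
3. **Speech-envelope encoding** — the envelope is extracted through a
   9-band filterbank (100 Hz–10 kHz, equidistant on the ERB-rate scale),
   and a temporal response function (TRF) with lags −100…500 ms is
   estimated by greedy boosting deconvolution with validation-based early
   stopping. Cortical tracking is the Pearson correlation between the
   TRF-predicted and observed response, 4-fold cross-validated on clear
   speech (0-dist) and transferred to the 1- and 2-distractor conditions;
   a word-epoch variant contrasts high- vs low-surprisal words on
   acoustically identical input.
4. **Per-voxel Bayesian multilevel regression** —

   ```
   tracking ~ n_distractors * prediction_tendency + (1 | subject)
   ```

   with a Student-T response, fit per voxel by a scale-mixture Gibbs
   sampler. Coefficients are significant when the 94% highest density
   interval (HDI) excludes zero; significant voxels additionally need two
   significant neighbours, and posterior draws are pooled over the
   surviving clusters. Convergence requires r̂ < 1.05 and ESS > 400.

Because raw recordings of this kind are not publicly deposited, the
package ships a first-class **synthetic cohort generator** whose ground
truth (anticipatory gain per subject, true TRFs, generative regression
coefficients) makes every stage verifiable by parameter recovery.

## Worked example

```bash
python examples/02_prediction_tendency.py
```

```
subject   true gain   estimated tendency   decoding accuracy
sub-000        0.39                 0.85                0.39
sub-001        0.59                 2.49                0.43
sub-002        0.11                 0.03                0.39
```

Three synthetic subjects with increasing anticipatory gain: the decoded
prediction tendency increases with the generative gain, while 4-class
frequency decoding accuracy (the control variable; chance 0.25) stays in
a narrow band. `examples/03_envelope_and_trf.py` continues the chain:

```
envelope vs ground-truth modulator: r = 0.996
0-dist cross-validated tracking: mean r = 0.584
1-dist transfer tracking:        mean r = 0.492
2-dist transfer tracking:        mean r = 0.350
```

Tracking degrades as distractor speakers are added — the generative
distractor effect that `examples/04_multilevel_stats.py` then recovers as
a significant negative cluster with its 94% HDI covering the true value.

The full pipeline is also available from the shell:

```bash
predtend all --config cfg.json --out results/
```

which writes `tendency.csv`, `encoding.csv`, `stats_summary.csv` and
`clusters.json` plus the resolved configuration.

## Layout

```
src/predtend/      paradigm, simulate, preprocessing, decoding, envelope,
                   trf, stats, config, io, pipeline, cli
examples/          one narrative script per capability
tests/             unit + property + acceptance suites
docs/methods.md    model assumptions, parameters, numerical choices
```
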