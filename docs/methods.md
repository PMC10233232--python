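# Methods

This note documents the models, parameters and numerical choices behind
`predtend`, and states precisely what the synthetic cohort does and does
not emulate.

## 1. Paradigm model

Tone sequences are first-order Markov chains over four tones with a
stimulus-onset asynchrony of 1/3 s (3 Hz) and 100-ms tone duration
(configurable). The *ordered* transition matrix places 0.75 on the
cyclic forward successor and, by default, the residual 0.25 on
self-repetition (`ordered_residual="self"`); an alternative reading that
spreads the residual uniformly over the three non-forward tones is
available (`ordered_residual="uniform"`). The *random* matrix is uniform
(0.25 everywhere). The first tone is uniform over the four tones. A run
is a single 1,500-tone sequence per entropy condition; block interleaving
has no analytic consequence for any downstream estimator and is not
simulated.

Transitions are labelled by the cyclic step `(current − previous) mod 4`:
0 = repetition, 1 = forward (f4→f1 wraps), 2 = two-step, 3 = backward.

## 2. Synthetic cohort

The generator is the package's study stand-in; its defaults are the study
conditions (49 subjects, 1,500 tones per entropy condition, three
listening conditions with 0/1/2 distractors) on a desk-scale 6×6 sensor
grid with rook adjacency instead of a 2,982-voxel source grid.

**Tone runs.** Each tone adds a subject-specific channel-space pattern
(the four patterns are orthonormal) times a gamma-shaped evoked kernel
(shape 3, peak 100 ms, ~400 ms support, unit peak). In ordered runs
only, the pattern of the forward successor of the *previous* tone is
added in the 300 ms before each onset with amplitude `g_pred` — the
subject's anticipatory preactivation gain and the generative counterpart
of prediction tendency. Carry-over of the previous tone's evoked
response into the pre-stimulus window arises naturally from the 333-ms
SOA. White Gaussian sensor noise has `noise_sd = 1.0` (pattern peak = 1),
which puts 4-class decoding accuracy near 0.4 — decodable but far from
ceiling, the regime in which tendency recovery is neither trivial nor
impossible. `g_pred` is drawn per subject from Uniform(0, 1) by default.

**Speech trials.** Target and distractor envelopes are positive 2–8 Hz
band-limited modulations (mean ≈ 1, unit SD). Per channel c the response
is

    brain_c = gain_c · (trf_c ⊛ envelope) + leak · Σ_d (trf_c ⊛ distractor_d) + noise,
    gain_c  = intercept + b_ndist·n + b_tendency·g_pred + b_interaction·n·g_pred + u_subject,

with `leak = 0.3` and generative defaults intercept 1.0, b_ndist −0.25,
b_tendency 0.4, b_surprisal 0.3 (betas may be per-channel vectors, which
is how spatially confined effects are simulated). True TRFs are a
biphasic kernel (positive lobe ~80 ms, negative ~180 ms) scaled per
channel by a weight drawn from Uniform(0.75, 1.25); wider spreads were
found to drown between-subject tracking effects in weight-driven SNR
differences, so the default keeps amplitude heterogeneity moderate.
Speech noise (`speech_noise_sd = 8.0`) deliberately dominates the signal
so that single-voxel tracking r sits in a realistic low-to-mid range
(≈ 0.3–0.6 on 60-s trials) rather than at ceiling, where gain effects
would be invisible in r. Within high-surprisal word epochs the response
gain is multiplied by `1 + b_surprisal (+ interaction terms)`; high and
low epochs are paired in order of occurrence and the high epoch's
envelope segment is overwritten by its partner's, so the two categories
carry bitwise-identical acoustics and any surprisal effect is purely
response-side.

All randomness derives from one seed through explicit `SeedSequence`
spawn keys, so any subject's sessions are bit-reproducible regardless of
simulation order or repetition.

**What the generator does not emulate:** realistic head geometry and
field spread, 1/f sensor noise (optional white noise only), eye/cardiac
artifacts, real speech acoustics or linguistic structure, temporal (as
opposed to spectral) prediction. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated generative
model, not their behaviour on real recordings.

## 3. Preprocessing

Zero-phase band-pass filtering uses a linear-phase Kaiser-window FIR
(60 dB stop-band attenuation; transition width 2 Hz at the low edge by default)
applied forward-backward. Resampling is polyphase with implicit
anti-aliasing. Epochs use a half-open sample convention
`[onset+tmin, onset+tmax)` with 0-based indexing; out-of-bounds epochs
are dropped and counted, never zero-padded (padding would bias decoding
toward the boundary trials).

## 4. Decoding and the tendency measure

One LDA per epoch timepoint (`scikit-learn`, `lsqr` solver) with
covariance shrinkage toward the scaled identity; the intensity is
Ledoit-Wolf by default and exposed because unregularised LDA is ill-posed
when channels approach trials per timepoint. Decision values are
softmax-normalised discriminant scores by default (`dval_scale="raw"`
available), making evidence amplitude-comparable across conditions.

The forward-vs-repetition contrast centres the two used dvals on their
mean per trial and timepoint before averaging (`centering=
"per_timepoint"`; an across-time variant is available). Prediction
tendency sums the (ordered − random) contrast over [−0.3, 0) s; updating
tendency sums the repetition-directed contrast over (0, 0.3] s; the
boundary sample at 0 belongs to neither window. Epochs are not
baseline-corrected before decoding. The decoding-accuracy control is
computed on a random 20% holdout of the forward training trials
(deterministically seeded); a periodic holdout would alias the
near-period-4 structure of ordered sequences and can delete an entire
tone class.

## 5. Envelope extraction

"Equidistant on the tonotopic map" is operationalised as equidistance on
the ERB-rate scale, `21.4·log10(1 + 0.00437 f)`; 9 bands between 10
edges pinned to 100 Hz and 10 kHz. Per band: 4th-order Butterworth
band-pass (zero-phase), magnitude of the analytic signal; bands are
combined by mean (sum available), low-passed at 45 Hz and polyphase-
resampled to 100 Hz to align with the neural data. Slight filter
undershoot is clipped at zero.

## 6. Boosting TRFs

Lags cover −100…500 ms (61 coefficients at 100 Hz). Stimulus and
response are z-scored; the coordinate step is 0.005 of the (unit)
response SD, patience is 10 accepted steps without validation
improvement, and the kernel at the validation optimum is returned. The
implementation precomputes per-segment Gram matrices, making each
iteration O(n_lags) and guaranteeing that concatenated folds or word
epochs never mix across their seams — equivalent to guard gaps of at
least the kernel length. Cross-validation uses contiguous folds
(interleaved folds leak through autocorrelation); within each training
fold the final 20% of every segment is the early-stopping set. Scores
are Pearson correlations on concatenated predictions. Transfer scoring
applies the fixed 0-dist kernel; channels with an identically zero
kernel report NaN with a `valid=False` flag rather than a silent 0.

A note on identifiability: with narrowband stimuli the lag Gram matrix
is near-singular, so kernel *shape* has an unidentifiable null-space
component even though predictions (and hence all r scores) are
unaffected. Kernel-recovery oracles therefore use broadband stimuli.

## 7. Multilevel regression

Per voxel: `tracking ~ n_distractors * prediction_tendency +
(1|subject)` (optionally fully crossed with binary word surprisal, plus
additive subject-level control covariates), Student-T response,
`n_distractors` continuous 0–2, `prediction_tendency` zero-centred
across subjects. Priors are weakly informative and data-scaled: fixed
effects N(0, 2.5·sd(y)/sd(x)) with the intercept centred at mean(y);
half-normal(sd(y)) on the group and residual scales; Gamma(2, 0.1) on
(ν − 1).

Sampling uses the scale-mixture representation of the Student-T (a
latent gamma precision per observation), which yields exact conjugate
normal draws for the fixed effects and the per-subject intercepts and
1-D slice updates for the scales. The residual scale and degrees of
freedom are updated jointly from the λ-marginalised likelihood
(partially collapsed Gibbs) including a random-direction slice move
along their ridge; without this, σ mixes an order of magnitude slower.
Defaults are 4 chains × 1,000 post-warmup draws (500 warmup), giving
coefficient r̂ ≈ 1.00 and ESS in the thousands in ~1–2 s per voxel.
The convergence flag gates on the reported coefficients (r̂ < 1.05 and
ESS > 400); scale-parameter diagnostics are computed and reported but do
not gate, as the σ–ν ridge occasionally yields nuisance ESS below the
threshold without affecting coefficient inference.

Significance is "94% HDI excludes zero". The spatial filter keeps a
significant voxel only if at least two of its neighbours are significant
*in the pre-filter mask* (one simultaneous pass, not an erosion to
fixpoint — consequently post-filter clusters of fewer than three voxels
are possible when a voxel's qualifying neighbours are themselves
removed). Cluster posteriors pool raw draws over each connected
component of the filtered mask. Adjacency is always an explicit input
(rook neighbourhood on the simulated grid); no adjacency is ever
inferred silently. No multiplicity correction is applied beyond the HDI
criterion and the neighbour rule.

## 8. Problem sizes used in the test suite

The suites run the study-structure analyses at desk scale: 20-subject
cohorts for tendency recovery and null calibration, single-subject
10-seed runs for condition monotonicity, 50 null voxels and 40
study-sized (49-subject) replicates for calibration and coverage of the
regression stage, and a 16-subject, 4×4-grid, 10-seed experiment with a
3×3 blob of positive tendency effect (b_tendency = 1 inside, 0 outside)
for end-to-end cluster recovery. Speech trials in tests are 60 s; the
generator default is 180 s.

## 9. Known limitations

- The Gibbs sampler is specific to the random-intercept Student-T model;
  random slopes or non-nested grouping would need new conditionals.
- The tendency measure's absolute scale depends on the dval scale
  (softmax) and the number of pre-stimulus samples; only comparisons
  across subjects analysed identically are meaningful.
- The word-surprisal analysis assumes non-overlapping 2-s epochs and
  pairs high/low epochs by order of occurrence.
- Updating tendency is computed but, as in the decoding literature this
  design follows, a decoder trained only on correctly predicted trials
  may be insensitive to post-stimulus model updating; the quantity is
  reported without further downstream use.
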