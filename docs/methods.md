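# Methods

This note documents the models and procedures implemented in `dcamnet`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Signal model and preprocessing

Continuous EEG (microvolts, channels × time) is bandpass-filtered with a
fourth-order Butterworth design applied forward and backward. The
forward–backward pass gives zero phase distortion and an effective magnitude
order of 8; we state this explicitly because "fourth-order zero-phase" admits
both this realization and a squared-magnitude design. Edge transients are
bounded by reflection ("even") padding of length `3 × order` samples.
Initial filter states are set so a constant input produces its exact
steady-state response, which makes the DC response identically zero rather
than a decaying transient. No artifact rejection (ICA, regression) is
applied; ocular and muscular components stay in the data by design, so the
frontal-channel ablation remains meaningful.

Epochs are half-open windows `[start, end)` with 0-based sample indices.
Event-locked mode takes the window immediately *preceding* each event
(reaction-time labeling uses the EEG leading up to a lane deviation); an
anchor without a full pre-anchor window is skipped with a warning.

The filter bank expands each epoch into nine sub-bands — δ (0.5–4 Hz),
θ (4–8), α1 (8–10), α2 (10–13), β1 (13–20), β2 (20–30), γ1 (30–36),
γ2 (36–42) and broadband (0.5–45) — using the same filter family and order
as the preprocessing, for uniformity (the bank's realization is otherwise a
free choice). Band axis order is fixed: index 0 = δ … index 8 = broadband.

## Label derivation

**Reaction-time scheme.** Per deviation event `i`:
`LRT(i) = Act(i) − Dep(i)`; `GRT(i)` is the mean LRT over prior events whose
onsets fall within 90 s, undefined when fewer than two qualify; `ART` is the
95th percentile of all LRT values (linear-interpolation percentile; the
convention is configurable since only "95th percentile" is specified).
An event is FATIGUED when both LRT and GRT exceed `2.5·ART`, ALERT when both
are below `1.5·ART`, DISCARDED otherwise. Three deliberate choices:
boundary values equal to `1.5·ART` or `2.5·ART` are discarded (the rule uses
strict inequalities); events with undefined GRT are discarded (the rule
requires both conditions); and ART defaults to the dataset-level pool of
LRTs, configurable per session, because the pooling level is not stated.
Note the pooled-P95 definition ties the "alert" threshold to the fatigued
trials present; it is implemented as stated, not second-guessed.

**PERCLOS scheme.** Per 4 s epoch, PERCLOS is the closure duration divided
by the observable interval (blink + fixation + saccade + closure), which may
be shorter than the epoch; epochs with an empty interval are dropped as
unlabeled. FATIGUED iff PERCLOS strictly exceeds 0.5. The duration type
does not carry the epoch length, so the "durations sum to the epoch length"
constraint is enforced by the generator, not the type — this keeps the
scale-invariance property of the ratio exact.

Subjects are retained when both classes have at least 50 labeled segments.

## Network

Input is the `(Nb, C, T)` band tensor of one epoch. Defaults: `K=4` kernels
of length `L=64` samples, `N=16` output maps, SE reduction `r=4`,
temperature `τ_d=1`, `m=16` spatial filters, window `w=25` samples, `h=4`
group channels, dropout 0.5 before the classifier.

**Dynamic convolution.** Each of the `K` kernels is `(N, Nb, 1, L)` — the
unit axis confines them to the time dimension. The SE branch pools each
band slice to its global mean `g ∈ R^Nb`, maps it through a bottleneck
(`max(1, ⌊Nb/r⌋)`; 9/4 floors to 2, so the r sweep {2,4,8} gives bottlenecks
{4,2,1}) with ReLU, and a second layer to `K` logits; a temperature softmax
yields the simplex weights `π`. The effective kernel and bias are the
π-weighted convex combinations, so every entry lies between the per-entry
min and max of the basis kernels. Smaller τ_d concentrates π (entropy is
monotone in τ_d). With `K=1` the branch is omitted and the layer is an
ordinary static convolution — the equivalence is exact and tested.

One structural property worth stating: the SE descriptor is the plain mean
of each band slice, and bandpassed signals are zero-mean, so `g` is small
and π stays close to uniform on the synthetic cohorts (the class-mean π
vectors differ only in the third decimal). Band *power* differences reach
the kernels through the convolution itself rather than through the branch;
on real recordings, residual offsets and asymmetric waveforms give the
branch more to work with.

Time-axis padding is 'same' (zero padding, stride 1) so `T1 = T`, keeping
window counts clean (800/25 = 32); a 'valid' mode (`T1 = T − L + 1`) is
available behind a flag. Convolutions run in the frequency domain
(`rfft`/`irfft` with per-sample effective kernels); forward values and all
gradients are verified against brute-force loops and central differences.

**Spatial convolution.** `m` bias-free filters of size `C×1` contract the
(map, electrode) axes at each time point, then batch normalization and ELU.
The spatial and classifier layers carry no bias terms, matching the
closed-form layer parameter counts (`m·N·C` and `Nc·m`).

**Temporal attention.** Each of the `m` series is cut into
`n = ⌊T1/w⌋` non-overlapping windows; the per-window *population* variance
(divisor `w`) is the local energy descriptor. A shared matrix `U ∈ R^{h×n}`
is row-softmaxed over the window axis and channel `c` uses row `c mod h`, so
each output is a convex combination of that channel's window variances. The
raw-weight (no softmax) form is available behind a flag, since the weighted
sum is written with raw entries while the accompanying text normalizes them;
the softmax reading is the default because it makes the outputs attention
weights in the usual sense.

**Parameter accounting** reports two totals: the layer-table convention
(dynamic conv `K·N·(Nb·L+1)`, spatial `m·N·C`, temporal `h·⌊T1/w⌋`, FC
`Nc·m`, with the SE branch `⌊Nb/r⌋·Nb + K·⌊Nb/r⌋` listed separately) and a
full count adding batch-norm affine parameters, which equals the number of
learnable scalars in the assembled network (verified per variant).

**Initialization** is fan-in-scaled uniform (`U(±1/√fan_in)`) for all
weights, zeros for biases, driven by the experiment seed. Batch
normalization keeps running statistics (momentum 0.1) for inference.

## Training

Adam (β₁=0.9, β₂=0.999) with L2 weight decay 1e-4 folded into the gradient,
initial learning rate 1e-3 halved every 50 epochs, at most 300 epochs at
batch size 64, early stopping on validation loss with patience 30, and the
best-validation weights restored. The validation split (10% of the training
portion, stratified) never touches the test set. All randomness —
validation carve-out, batch order, dropout masks, weight init — derives from
one seed; two runs with the same seed are bit-identical.

## Evaluation protocols

*Subject-mixed*: segment-level stratified split (0.7 or 0.8 train); the same
subject may appear on both sides, so results are upper bounds.
*LOSO*: one fold per subject, train on the rest (with a stratified
validation carve-out), test on the held-out subject; every sample is tested
exactly once. Predicted class is the probability argmax with exact ties
resolved to ALERT. Metrics are percentages from the fold confusion matrix;
zero-denominator metrics are flagged undefined, never silently zero.
Fold aggregation reports the unweighted mean, the sample-size-weighted
aggregate-matrix accuracy, and a normal-approximation 95% CI
(`mean ± 1.96·sd/√n`); these can differ, so all are exposed. Paired fold
comparisons use the two-sided paired t-test, the Wilcoxon signed-rank test
(zero differences dropped; exact null for n ≤ 25 folds, normal approximation
with continuity correction above; W reported as the positive-rank sum), and
paired Cohen's d (`mean(diff)/sd(diff, ddof=1)`, flagged when the sd is 0).

Balanced re-sampling draws equal per-subject quotas
(`⌊per_class/n_subjects⌋`, remainder by seeded draw) and repeats the mixed
protocol over a fixed seed list (100…500 by default).

## Synthetic cohorts

Each epoch is `1/f^γ` background noise (γ=1, synthesized in the frequency
domain, unit variance per channel) plus three amplitude-modulated narrowband
oscillations — θ (4–8 Hz), α (3 Hz wide around a per-subject peak near
10 Hz), β (13–30 Hz) — mixed into channels through fixed random gains
(0.5–1.5). Oscillations are band-limited Gaussian processes with a slow
sinusoidal envelope (depth 0.5, 0.1–0.5 Hz), not pure sinusoids, to avoid
degenerate filter-bank behavior. Fatigued epochs shift oscillation power by
+3 dB (θ), +2 dB (α) and −2 dB (β) by default — the directions reported for
drowsy EEG; each subject carries fixed band offsets (σ=2 dB, clipped ±6) and
an individual alpha peak, which is what makes held-out subjects genuinely
harder than held-out segments. Defaults: 6 subjects × 40 epochs/class,
8 channels, 4 s at 200 Hz.

Because the measured θ-band power also contains the 1/f background, the
recovered class difference is slightly below the configured dB effect
(≈2.8 dB for a 3 dB setting at the default in-band SNR); the generator tests
assert recovery within 1 dB.

The deviation-session generator draws alert reaction times around 0.7 s and
inflated fatigued ones around 5 s, with onsets 5–15 s apart. Since ART is
the 95th percentile of *all* LRTs, a stream with more than ~5% strongly
inflated events pushes ART into the inflated range and suppresses FATIGUED
labels entirely; ground-truth recovery therefore uses sparse contiguous
fatigued blocks (the look-back window must also fill with inflated responses
before GRT crosses the threshold). The eye-closure generator produces
durations whose PERCLOS equals the requested trajectory exactly when noise
is zero.

What the synthetic data does *not* model: volume conduction and realistic
montage geometry, non-stationary drift within a session, ocular/muscular
artifacts, label noise, and the long-tailed RT distributions of real
driving. Passing the end-to-end checks therefore demonstrates that the
pipeline recovers the class-dependent band-power structure it assumes — not
field performance on real recordings.

## Desk-scale studies

The bundled end-to-end studies (`dcamnet.experiments`) use 4 subjects × 24
epochs per class, 8 channels, 2 s epochs at 200 Hz, and a half-width network
(N=8, m=8, L=33) trained for at most 25 epochs (patience 8, batch 32) —
sizes chosen so a full study runs in minutes on one CPU. The subject-mixed
benchmark uses a strongly separated cohort (+6/+4/−4 dB); the LOSO
dynamic-vs-static comparison keeps the default (moderate) effects, where
per-sample kernel adaptation has room to matter.

## The single-band masking probe

Masking retains one filter-bank slice and zeroes the other eight, then runs
the trained network without retraining. With frozen batch-norm running
statistics this probe is uninformative at our scale: the masked tensors
carry roughly one ninth of the training input's energy, the frozen statistics
shift the activations into the ELU saturation/constant region, and every
band condition collapses to a near-constant prediction. The probe therefore
re-normalizes batch normalization with the probe batch's own statistics
(running statistics untouched, dropout off, the whole probe set as one
batch), which restores the intended readout: the broadband slice recovers
the full-model accuracy and per-band accuracies track per-band class
information. A `renormalize=False` flag keeps the frozen-statistic variant
for comparison.

## Numerical choices and degenerate inputs

- Frequency-domain convolution uses `next_fast_len(T+L−1)` FFT lengths; no
  circular aliasing by construction (verified against direct loops).
- Softmax subtracts the row max; cross-entropy clips probabilities at 1e-12.
- Window variances discard trailing samples beyond `n·w`; `w > T1` is a
  configuration error.
- An epoch store with constant labels still trains (the loss drives the
  logits one-sided); stratified carve-outs degrade gracefully to no
  validation split when the split would be smaller than the class count.
- Checkpoints are single-file archives (config JSON + weight arrays) with a
  bit-exact save → load → forward round-trip.

## Known limitations

- The parameter counter reports formula-derived values under two explicit
  conventions (layer-table rows, and the full count including SE and
  batch-norm affine parameters); headline "total parameter" figures quoted
  for architectures of this family often follow yet other conventions and
  should not be compared across tools without checking the convention.
- Training is CPU-bound numpy; the default 300-epoch protocol on full-size
  tensors (17 channels × 800 samples × 9 bands) is hours, not minutes — use
  the desk-scale presets for exploration.
- The EDF reader requires the optional `mne` dependency; HDF5/CSV paths are
  dependency-free.
- LOSO accuracy on synthetic cohorts has high fold-to-fold variance at 4
  subjects; the dynamic-vs-static comparison is therefore reported as a mean
  over seeds × folds, and only its direction is asserted.
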