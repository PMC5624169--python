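# Methods

This note documents the models, numerical choices and limitations behind
`pdvoice`, in the order the pipeline runs.

## Dysphonia feature extraction

**Pitch and voicing.** Frames of 40 ms are taken every 10 ms (defaults in
`ExtractorConfig`; the frame must hold at least two periods at the pitch
floor). Each frame is mean-subtracted, Hann-windowed and autocorrelated via
FFT; the raw autocorrelation is divided by the window's own autocorrelation
so that a perfectly periodic frame scores near 1 regardless of lag. The
pitch search range is 75–600 Hz. Candidate selection adds a small
octave-cost bonus of 0.03·log2 per octave above the floor, which resolves
the period-doubling ambiguity (without it, a 150 Hz vowel occasionally reads
as 75 Hz, because window normalisation amplifies the double-period lag).
The peak is refined by parabolic interpolation; a frame is voiced iff the
refined peak reaches the voicing threshold 0.45 and the frame is not silent
relative to the recording's global peak (relative silence threshold 0.01).

**Glottal pulses.** Inside each maximal voiced stretch the detector starts
at the strongest waveform extremum and marches outward cycle by cycle,
searching for the largest |x| in a window 0.75–1.35 local periods from the
previous pulse (local period = run-median of the frame F0 values — robust to
isolated track errors and adequate for sustained phonation, which is the
intended input). Marching stops when the found peak falls below 0.2 of the
run's maximum amplitude; this rejects the decaying vocal-tract ringing after
the final glottal excitation, which otherwise registers as a spurious extra
pulse. Pulse times and per-cycle amplitudes are refined to sub-sample
precision with a three-point parabola on the signed waveform; without this
refinement, sample quantisation alone would contribute ~0.3 % apparent
jitter at 22.05 kHz and swamp small perturbations.

**Perturbation measures.** Periods are successive pulse-time differences; a
period is *valid* when it lies in [1/ceiling, 1.25/floor] seconds, so a
silent gap between voiced stretches never leaks into jitter. Jitter and
shimmer follow the standard Praat conventions — local (mean absolute
consecutive difference over the mean), local-absolute (seconds), local-dB,
and the 3/5/11-point perturbation quotients, with ddp = 3·rap and
dda = 3·apq3 holding identically. All ratio features are reported as
fractions, not percent. N-point quotients require N consecutive valid
periods; windows never span a voice break. Per voiced frame with periodicity
strength r (clipped to [1e-6, 1−1e-6]), HNR = 10·log10(r/(1−r)) dB and
NHR = (1−r)/r, averaged over voiced frames. Pitch statistics use voiced
frames only, with the n−1 standard deviation. A voice break is an
inter-pulse gap exceeding 1.25 maximum periods (1.25/75 s at default
settings); degree of voice breaks is summed break time over the analysed
duration. Conventions for degenerate inputs: an all-silent recording has
fraction-unvoiced 1 and zero voice breaks; any feature whose precondition
fails (too few cycles, no voiced frames) is NaN — the package-wide missing
sentinel — and downstream consumers impute with the training-set median.

**Feature battery.** The canonical order is frequency (5), harmonicity (3),
pulse (4), amplitude (6), pitch (5), voicing (3) = 26 features. The
22-feature profile drops the two derived redundancies (ddp, dda) and the two
duration-dependent raw counts (number of pulses, number of periods) by
default; the membership is configurable because published 22-feature voice
datasets differ in composition and a fixed subset cannot represent them all.

## Stacked autoencoder

Encoder x1 = sigmoid(W1ᵀx0 + b1), decoder x2 = sigmoid(W2ᵀx1 + b2); the
training objective is mean squared reconstruction error plus L2 weight decay
0.5·ε(‖W1‖² + ‖W2‖²). MSE was chosen as the reconstruction term because the
inputs are real-valued features scaled to [0, 1]. Inputs are min-max scaled
per feature on the training set (required by the sigmoid-bounded decoder;
constant features scale to 0); the scaler is part of the saved model.

Training is plain mini-batch SGD with batch size 20. Weights initialise
uniformly in ±4·sqrt(6/(d0+d1)) (the sigmoid-appropriate Glorot range),
biases at zero, from a single seeded generator that also drives batch
shuffling — the trained model is a pure function of (data, config). Stages
are pretrained greedily (each on the previous stage's codes), then the whole
stack is fine-tuned. The default fine-tuning objective is unsupervised:
the stack is unrolled into a deep autoencoder (enc₁…enc_k, dec_k…dec₁) and
trained end to end on reconstruction. A supervised variant (encoder stack +
softmax head, cross-entropy) is available via `finetune="supervised"`;
neither is claimed canonical, the unsupervised one ships as default because
it needs no labels.

Hyper-parameter defaults and why: ε = 1e-3 (mild decay, keeps the gradient
check well-conditioned); learning rate 1.0; 400 pretraining and 400
fine-tuning epochs. The learning rate deserves a note: sigmoid layers with
MSE produce small gradients (the sigmoid derivative is ≤ 0.25 at best), and
at rate 0.1 the unrolled stack plateaus around reconstruction loss 0.26 on
[0, 1]-scaled cohort data — barely better than predicting the feature means,
leaving the bottleneck code uninformative. At rate 1.0 the same
architecture reaches ≈ 0.04 and the reduced representation supports
nearest-neighbour accuracy close to the unreduced pipeline. Pretraining
loss is recorded per epoch and is empirically non-increasing at these
settings (the test suite allows ≤ 1 % transient increase per epoch);
non-finite loss aborts with a diagnostic rather than returning garbage.
Backpropagation is verified against central finite differences to 1e-6
relative error.

## Vote-KNN classifier

The decision rule is a signed vote over the K nearest training rows:
score(s, cᵢ) = Σⱼ sim(s, Sⱼ)·δ(Sⱼ, cᵢ), δ = +1 if Sⱼ ∈ cᵢ else −1. The
similarity weight is the constant 1: with K = 1 (the default operating
point) any positive weight yields the same decision, so the unweighted vote
is the least-assumption reading. Distance is Euclidean by default
(Manhattan available). Tie rules are deterministic and documented: exact
distance ties rank by lower training-row index (stable argsort); tied class
scores predict the positive (PD) class — for a screening tool the
conservative error is the false positive. Training stores the data
verbatim; a brute-force distance scan is exact and fast at the intended
scale (≤ ~1000 rows), so no tree acceleration is used.

## Metrics

Confusion counts treat PD as positive. Accuracy, sensitivity, specificity
and F-score are the standard ratios; Matthews correlation uses the
square-rooted denominator √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), the form bounded
in [−1, 1]. An uncorrected variant dividing by the raw product is kept
behind `corrected=False` for auditing against sources that print the
formula without the root; it is not bounded and not used anywhere in the
pipeline. Degenerate denominators return 0 with a RuntimeWarning (and MCC
of an empty marginal is defined as 0) so that batch evaluations never crash
on a one-class test split.

## Evaluation protocols

`repeated_split` re-randomises a stratified 50-50 train/test partition on
each of 10 repeats (both the stratification and the re-randomisation are
package decisions; within each class the training side receives the ceiling
of half the class count, so 195 rows split 98/97). `fixed_split` evaluates
a given train/test pair; with repeats > 1 only the SAE seed varies, since
the partition is fixed. Per-repeat seeds derive from the master seed via
`SeedSequence([master, run_index])` and are recorded in the report, so any
single run can be reproduced in isolation. Each repeat fits median
imputation and min-max scaling on the training half only — the evaluation
never leaks test statistics into preprocessing. Grid search evaluates all
nine hidden-size pairs {10, 9, 8} x {8, 7, 6} and ranks by mean test
accuracy (the full table is always retained; ranking is stable under ties).
Reports carry per-run values plus max/mean/min per metric, written as CSV
(one row per configuration) and JSON (full audit trail).

## Synthetic ground truth

**Voice.** The vowel synthesiser draws per-cycle periods
Tᵢ = (1/f0)(1 + σ_jitter·zᵢ) and amplitudes Aᵢ = 1 + σ_shimmer·wᵢ (z, w
standard normal, truncated at ±3 to keep periods positive; amplitudes floored
at 0.05), renders a Rosenberg glottal-flow-derivative pulse at each onset
(opening 0.40·T₀, closing 0.16·T₀), and filters through two cascaded
resonators at 700/1220 Hz (bandwidths 130/70 Hz) — the simplest spectrally
plausible /a/ carrier. White noise is added at a requested SNR; break
intervals are zeroed after synthesis and the corresponding truth pulses
removed. Defaults: f0 150 Hz, 2 s, 22.05 kHz, clean. The programmed pulse
times and amplitudes are returned, so extractor output is checked against
the perturbation actually synthesised, not against the nominal σ (at 2 s
there are only ~290 cycles, and the realised jitter of a finite draw differs
from its asymptotic value).

**Cohorts.** Feature tables are multivariate normal around plausible
sustained-vowel baselines, with correlation 0.6 between features of the same
group (perturbation measures within a family are strongly correlated in real
data) and a per-subject random offset of 0.25 standard deviations shared
across that subject's recordings (class assignment is per subject, so
subject-leakage experiments are possible). The PD class shifts along a
signed dysphonia pattern — jitter, shimmer, NHR, unvoiced fraction and voice
breaks up; autocorrelation, HNR and pitch variability down — by
`effect_size` pooled standard deviations, default 2.0 (a clearly separable
cohort; 0 gives chance-level data, and difficulty decreases monotonically in
between). Layout defaults mirror the emulated corpora: 147 + 48 single
recordings x 22 features, or 20 + 20 subjects x 26 recordings = 1040
training rows and 28 test subjects x 6 recordings = 168 test rows x 26
features. The test subjects default to a 14/14 class split so that
specificity and MCC stay well-defined under the fixed-split protocol.

**What passing tests do and do not show.** The generators prove the
pipeline's internal consistency: programmed perturbations are recovered,
separable cohorts are separated, chance-level cohorts score at chance. They
do not emulate articulation, recording-channel variation, non-Gaussian
feature tails, or severity heterogeneity of real PD speech, so accuracy on
these cohorts says nothing about clinical accuracy on real recordings.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at the protocol sizes above
(195-row and 1040/168-row cohorts, 2 s vowels, 10 evaluation repeats, the
full 3x3 grid at 2 repeats) — the same shapes the package's default
workflows target.

## Known limitations

- The pulse detector assumes sustained phonation (near-constant F0 within a
  voiced run); running speech with large F0 excursions will mis-march.
- Pitch statistics at high programmed jitter (σ ≥ 0.02) can include
  occasional octave-error frames; perturbation measures are insulated from
  these by the median-period marching, but `sd_pitch` is not.
- WAV PCM/float is the only audio input; compressed formats must be
  converted upstream.
- The SAE optimiser is plain SGD by design (reproducibility and simplicity);
  it needs the documented learning rate to converge and offers no early
  stopping, momentum or adaptive schedules.
- 16-bit WAV round-trips quantise amplitudes at ~3e-5; shimmer floors near
  1e-4 on re-read audio for this reason.
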