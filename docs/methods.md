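# Methods

## Problem and model

Ambulatory ECG is contaminated by three canonical noise processes: baseline
wander (BW, sub-0.5 Hz drift), muscle artifact (MA, broadband EMG) and
electrode motion (EM, transient steps and spikes that can mimic ectopic
beats). The package denoises fixed-length ECG fragments with a conditional
generative adversarial network. The generator G maps a noisy fragment
x̃ = x + n (1024 samples) to a denoised estimate x̂ = G(x̃); the
discriminator D receives either x̂ or the clean fragment x and outputs, via
a two-class softmax, the probability that its input is real. The generator
is trained on a composite objective

    L_G = adv(D(G(x̃))) + λ₁ · L_dist + λ₂ · L_max,
    L_dist = Σᵢ (x̂ᵢ − xᵢ)²,    L_max = maxᵢ |x̂ᵢ − xᵢ|,

with λ₁ = 0.7 and λ₂ = 0.2. The squared-distance term anchors the global
reconstruction, the max-deviation term penalizes the worst local error
(protecting the R peak, which denoisers tend to clip), and the adversarial
term pushes the output distribution toward that of clean ECG.

### Generator (LSTM-DCGAN)

A dense input stage maps the 1024-sample fragment to a 32-step × 256-channel
seed sequence (batch-norm, LeakyReLU α = 0.2); five CNN-LSTM blocks then
upsample 32 → 64 → 128 → 256 → 512 → 1024. Each block is a stride-2
transposed convolution (kernel 16) with batch-norm and a leaky activation,
followed by an LSTM over the time axis with one unit per channel, dropout,
and tanh; block channel widths are 128-64-40-20-40. A 1×1 transposed
convolution collapses to one channel; the output head is linear, since
targets live on the [0, 1] normalized scale but residual-free regression
needs no squashing. The registry also provides the ablation and baseline
families: `dcgan` (the same pipeline without the recurrent layers),
`lstm_gan` (recurrent layers only), `dnn_gan` (dense 310-250-250-310, tanh
hidden, sigmoid output head) and `fcn_dae` (convolutional encoder
40-20-20-20-40-1, transposed-convolution decoder 1-40-20-20-20-40-1, kernel
16, stride 2 throughout).

Reading of the input stage: "32×256" is interpreted as a dense map to a
32-step sequence of 256 channels, because five stride-2 upsamplings then
recover exactly 1024 samples. Sequences are (time, channels); each recurrent
layer consumes and returns the full sequence so the next transposed
convolution can upsample it. In each block the listed order is kept:
deconv → batch-norm → activation → LSTM → dropout → tanh.

### Discriminator

LSTM (128 units) → dropout 0.5 → convolution (64 filters, kernel 16,
stride 2) → max-pool (size 3, stride 2) → flatten → dense → two-class
softmax. `prob_real` is the softmax probability of the "real" class. The
discriminator loss is the two-class cross-entropy
−[log p(real | x) + log p(generated | x̂)], the objective that "assign the
correct label to both" describes; a literal reading of a value function in
terms of log(1/(1+D)) does not reduce to a standard objective and is not
provided.

### Adversarial surrogate

By default the generator minimizes −log D(G(x̃)) (the non-saturating
surrogate) instead of log(1 − D(G(x̃))); early in training, when the critic
wins easily, the literal form has vanishing gradients. The literal form is
available via `TrainConfig(adversarial_mode="literal")`. Probabilities are
clamped to [1e-7, 1 − 1e-7] before logarithms; clamping is logged, not
raised. Because the adversarial gradient is taken through the softmax head,
its magnitude per sample is bounded even when the critic saturates.

## Numerical core

No deep-learning framework is used: `ecgan.nn` implements dense,
1-D convolution and transposed convolution (kernel/stride of equal parity,
symmetric zero padding), batch normalization (momentum 0.9, ε = 1e-5),
LSTM (gate order input-forget-output-cell, forget bias 1), max-pooling,
dropout (inverted), LeakyReLU/PReLU/ReLU/tanh/sigmoid/softmax, and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). All backward passes are hand-derived and
verified against central finite differences in the test suite. The LSTM
recurrences are JIT-compiled with numba when available, with an identical
pure-numpy path otherwise. Weights are initialized from a seeded normal
scaled by 1/√fan-in; every builder takes an explicit seed, and all
randomness (init, batch order, dropout) derives from the training seed, so
runs are bit-reproducible on the same BLAS.

## Data pipeline

Long signals are segmented into non-overlapping 1024-sample fragments
(trailing remainder dropped). Each clean fragment is min-max normalized to
[0, 1]; noise is then scaled and added to the *normalized* clean fragment so
that the measured input SNR equals the requested level (−1, 3 or 7 dB):

    scale = sqrt( Σx² / (10^(SNR/10) · Σn²) ).

The noisy fragment is deliberately not re-normalized: clean, noisy and
denoised signals share one amplitude scale, so SNR, RMSE and PRD remain
comparable. (Re-normalizing the noisy fragment independently would silently
change the input SNR.) Mixed noise kinds are summed with equal weight before
the single global scaling — only the total SNR of the mixture is specified.
The train/test split labels round(fraction·n) fragments as test via a seeded
shuffle; the default fraction is 0.05.

PRD divides by the energy of the denoised signal (the form implemented
matches the evaluation formula as printed); `prd(..., denominator="clean")`
selects the conventional normalization by the clean signal's energy. "lg"
in the SNR formulas is read as log₁₀. Aggregates are unweighted means over
fragments; rows with infinite SNR (perfect reconstruction) are kept in the
per-fragment table but excluded from dB means, with a count.

## Synthetic data generator

The simulator exists so that the whole pipeline runs and is tested without
downloading clinical data. One beat is a sum of five Gaussian bumps
(P, Q, R, S, T) with configurable amplitudes, widths and offsets relative to
the R peak; defaults (amplitudes 0.12/−0.1/1.0/−0.15/0.3, widths
25/10/12/12/45 ms, offsets −180/−35/0/35/280 ms) give an R wave at least 3×
any other deflection, so R-preservation assertions are meaningful. RR
intervals are jittered uniformly by ±5% around 60/heart-rate. Noise models:
BW is a sum of 4 sinusoids below 0.5 Hz with random phases and roughly 1/√f
amplitudes; MA is 4th-order Butterworth band-passed white noise (15–120 Hz)
gated by a smoothed on/off burst envelope (duty cycle 0.5, floor 0.1); EM is
a Poisson stream (0.5 events/s) of smoothed decaying steps and sharp
biphasic spikes. All three are zero-mean, and every generator is a pure
function of (parameters, seed).

What the simulator does *not* capture: arrhythmic and ectopic beats, QRS
micro-structure, respiration-correlated amplitude modulation, the empirical
spectra of real electrode noise, or inter-lead differences. Passing tests
therefore demonstrate that the algorithmic machinery (calibration, training
dynamics, metric accounting) works, not that clinical denoising performance
matches any particular figure on real recordings.

## Training loop

Per minibatch: one discriminator step (clean and generated fragments scored
in one concatenated pass, cross-entropy gradient, Adam) followed by one
generator step (adversarial gradient propagated through the frozen critic
plus the analytic gradients of λ₁L_dist and λ₂L_max). The discriminator:
generator update ratio is configurable (`steps_per_generator_update`,
default 1). Full-scale defaults follow the training protocol: Adam,
learning rate 1e-4, batch 64. The epoch count is a required field with no
silent default. No early stopping by default. A non-finite loss raises a
divergence error naming the epoch. Per-epoch bookkeeping records both
losses, the RMSE on a seeded subsample of at most `eval_subsample` training
fragments (a full-train-set pass per epoch would double the run time), and
the mean SNR improvement on the test split.

## Desk-scale presets

Adversarial training at full scale is a GPU-scale job, so the package ships
reduced presets that run in CPU minutes while exercising the identical code
path: generator blocks 32-16-8-8-16 with a 32-channel seed stage and
dropout 0.2, critic with LSTM 32 / 16 conv filters, Adam 1e-3 for the
generator and 1e-4 for the critic, batch 32, patience 6 on the test SNR
improvement with best-weight restoration. The choices reflect desk-scale
dynamics: a few hundred gradient steps need a larger generator step size
than the full-scale 1e-4; dropout 0.5 on 8-16-channel layers removes too
much capacity; the slower critic keeps the adversarial signal useful
instead of saturating; and at this scale the critic eventually overpowers
the small generator, so training keeps the weights from the best-scoring
epoch rather than the last one. With 200 mixed-noise fragments at −1 dB
input SNR and at most 30 epochs this preset gains more than 5 dB of SNR on
held-out fragments across seeds (the acceptance suite runs exactly this
experiment at three seeds).

Problem sizes used by the test suite: gradient checks on layers with 2–9
time steps; protocol checks on 1024-sample fragments; training tests on
24–200 fragments of length 64–1024; the subject-holdout and boosting
properties use 256-sample fragments (long enough to hold whole beats) and a
matching reduced generator, with a deliberately shifted subject whose R wave
is inverted.

## Degenerate inputs and tie-breaks

Constant fragments cannot be min-max normalized (degenerate-fragment error);
all-zero signals carry no energy for SNR/PRD scaling (degenerate-input
error); corrupted == reference yields a +∞ SNR sentinel rather than an
exception. The max-deviation subgradient uses the first argmax on ties.
Min-max normalization uses stable order (argsort is preserved exactly).
WFDB support covers header parsing plus signal formats 16 and 212 — the
formats of the ambulatory databases this pipeline targets — reading one
channel by its description string.

## Known limitations

* Training beyond desk scale is CPU-bound in the LSTM recurrences; there is
  no GPU path.
* The discriminator architecture has no batch normalization and can still
  overpower the small generator on long runs; the per-architecture learning
  rates mitigate but do not remove this.
* The simulator's noise statistics are plausible fixtures, not fits to the
  reference noise recordings.
* Checkpoints store raw float64 arrays (npz) with a JSON config sidecar;
  they are not interchangeable with any deep-learning framework's format.
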