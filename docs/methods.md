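# Methods

## The decoding problem and the augmentation framework

A motor-imagery session provides a few hundred labeled trials x ∈ R^(C×T)
(C electrodes, T samples at 250 Hz; T = 1125 for a 4.5 s epoch cut 0.5 s
after the cue). The framework trains three coupled components:

1. a **conditional generator** G(z, l) mapping Gaussian noise plus a class
   label to a synthetic trial,
2. a **discriminator** D(x, l) scoring whether a labeled trial is real, and
3. a **classifier** sharing the discriminator's architecture, whose dense
   head outputs class probabilities.

Training proceeds in two phases. Phase one alternates least-squares GAN
updates: D minimizes (Σ(D(real)−1)² + ΣD(fake)²)/2n; G minimizes
L_M + λ·L_F with λ = 0.5, where L_M pushes D's score on fakes toward 1 and
L_F matches per-sample flatten-layer features of real and generated batches
(paired by batch index — the per-sample indexing of the objective implies
pairwise matching rather than matching batch means). Phase two augments the
training set with generated trials — half the original count, equal per
class, labels taken from the conditioning input — and trains the classifier
on sliding-window crops, minimizing the negative log-likelihood of the true
class on the crop-averaged probability vector. Evaluation uses the same
crop-averaging rule.

Assumptions: trials are identically distributed within a class and session;
amplitudes are tanh-range normalized so the generator's Tanh output and real
data share support; every class is present in the training split.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| bandpass corners | 4–38 Hz | Hz | brackets mu (8–13 Hz) and beta (18–26 Hz) rhythms; rejects drift and 50 Hz line noise |
| FIR order | 200 | taps−1 | Blackman-window design; applied forward-backward, so zero phase and squared magnitude response |
| epoch window | 0.5 s + 4.5 s | s after cue | 1125 samples at 250 Hz |
| latent dimension | 100 (+1 label code) | — | generator input is 101-d |
| F₁, D, F₂ | 8, 2, 16 | filters | EEGNet-family defaults for the backbone |
| SE reduction | 8 | — | bottleneck width max(D·F₁/8, 1) = 2 |
| dropout | 0.25 | prob. | backbone default |
| crop window / step | 500 / 125 | samples | 6 crops per 1125-sample trial |
| λ (feature matching) | 0.5 | — | stated default of the objective |
| augmentation ratio | 0.5 | fraction | half the original trials, class-balanced |
| GAN optimizer | Adam, lr 2·10⁻⁴, β = (0.5, 0.999) | — | standard small-GAN settings |
| classifier optimizer | Adam, lr 10⁻³, β = (0.9, 0.999) | — | standard CNN settings |
| batch size | 64 (trials ÷ crops for the classifier) | — | fits comfortably in memory |

Training lengths (`gan_epochs`, `clf_epochs`) are configuration, not model
constants: the GAN has no principled stopping rule here (a fixed epoch
budget is used; the similarity score can select among checkpoints), and the
classifier's loss plateaus within roughly ten epochs on the surrogate data.

## Label conditioning

The discriminator input is (1, C, T+1): one extra time column, constant
across electrodes, carries the label encoded as an evenly spaced value in
[−1, 1] (n_c = 4: −1, −1/3, 1/3, 1). A scalar code rather than a one-hot
block keeps the input layout identical for the 4-class and 2-class
geometries, and the encoding is exactly invertible. The generator receives
the same scalar code as its 101st input.

## The surrogate sessions

`eeggan.synthetic` emulates the statistical skeleton of a motor-imagery
session: per class, a narrow-band oscillation (8–26 Hz range) with a fixed
smooth channel topography — lateralized bumps for hand classes, midline and
frontal bumps for foot/tongue — added to 1/f Gaussian background noise at a
configurable oscillation-to-noise power ratio (snr). Labels are exactly
balanced (72 trials per class by default), trials are independent, and the
whole session is a deterministic function of one seed.

What it deliberately does not model: electrode covariance structure beyond
the class topographies, non-stationarity within and across trials, eye/muscle
artifacts, inter-subject variability, and event-related *desynchronization*
proper (class membership adds band power rather than suppressing it).
Passing end-to-end tests therefore demonstrates that the implementation
learns and transfers class structure of realistic dimensionality — not that
it attains any particular accuracy on recorded EEG.

The default snr (0.9 for the presets) makes the session clearly learnable: a
deliberately weak band-power nearest-centroid probe (`separability_check`)
sits at its ceiling there, while snr = 0 is at chance. `calibrate_snr`
bisects (in log-snr, since the effect is multiplicative) to any intermediate
probe accuracy; the hard preset used by the ablation tests
(36 trials/class, snr = 0.1) was chosen so the converged full model scores
clearly above chance and below ceiling, leaving room for component effects
to show in either direction.

## Numerical and design choices

- **Execution engine.** Models run on a compact numpy reverse-mode autodiff
  engine written for this package (`eeggan.nn`). Convolutions are evaluated
  in the frequency domain (rfft product, per-frequency BLAS matmuls): every
  kernel here is 16–64 taps, long enough that FFT evaluation beats sliding
  windows on one CPU. float64 is the default dtype (finite-difference
  gradient checks pass at tight tolerance); the training loops switch to
  float32, whose memory traffic is the binding resource at these sizes.
- **Zero-phase filtering.** The FIR bandpass is applied forward-backward so
  cue-locked epoch timing is preserved; the band corners are configurable
  and logged (4–38 Hz default).
- **Normalization.** Tanh-range (per-channel min/max of the *training* split
  mapped to [−1, 1]) is the default because the generator ends in Tanh;
  per-channel z-scoring is available. Statistics are always fitted on the
  training split and reused for held-out data. Zero-variance channels floor
  the scale at 10⁻¹² with a warning.
- **Cropping semantics.** Start indices 0, step, 2·step, …; a trailing
  partial window is dropped, so k = ⌊(T − window)/step⌋ + 1 and all crops
  are uniform. Crops are strided views, not copies; consumers treat them as
  read-only.
- **"FL" in the classifier objective** is read as cross-entropy on the
  crop-averaged probabilities (with k = 1 it reduces exactly to plain
  cross-entropy); a focal-loss variant −(1−p)^γ log p is exposed behind
  `TrainConfig.focal` since the abbreviation is ambiguous.
- **KS score direction.** The similarity score is 1 − D (D the two-sample
  Kolmogorov–Smirnov statistic), so 1 means indistinguishable amplitude
  CDFs; the raw D is co-reported so either reading can be recovered.
  KS and KL are computed per (class, channel) on amplitude samples pooled
  across trials, then averaged; KL uses 100 equal-width bins over the pooled
  range with 10⁻¹⁰ smoothing of empty bins.
- **Classifier body: fresh, not shared.** The head-swap operation supports
  both reusing the trained discriminator body (share-by-reference) and
  re-initializing it. The pipeline default is a fresh body: in controlled
  5-seed experiments on the surrogate, fine-tuning the GAN-trained body
  consistently underperformed a freshly initialized one (the GAN
  discriminator's features are tuned to real-vs-fake with a label column,
  not to class discrimination on unlabeled crops) and interacted badly with
  the SE block. Sharing remains available via `TrainConfig.share_gan_body`.
- **Divergence guard.** Non-finite GAN or classifier losses abort training
  with the step history preserved.
- **Degenerate inputs.** Empty score batches, mismatched feature shapes,
  unequal real/fake batch lengths, out-of-range labels and over-long crop
  windows raise; non-normalized crop probability rows are renormalized with
  a warning; Cohen's kappa is defined as 0 (with a warning) when expected
  agreement is 1.

## Problem sizes used by the test suite and acceptance script

End-to-end checks run one 288-trial session (22 channels, 4 classes) per
seed with 3 GAN epochs and 2 classifier epochs — enough for the classifier
to saturate on the calibrated preset and for the generator to beat a
white-noise baseline on both similarity scores — and a 144-trial 2-class
session for the second geometry. The ablation comparison uses
36 trials/class at snr 0.1 with 10 classifier epochs (the loss-plateau
point) over 5 seeds. These sizes are the package's desk-scale operating
points; larger budgets only improve the margins.

## Known limitations

- The GAN is trained for fixed small epoch budgets in the examples and
  tests; no convergence or mode-coverage diagnostics beyond the KS/KL scores
  are implemented.
- The engine is single-threaded numpy; it is sized for the package's own
  problem scales, not for large-scale experimentation.
- The GDF adapter maps annotation codes to labels by order of appearance;
  session layouts with non-standard event codes need an explicit remap.
- Wilcoxon p-values use scipy's exact/approximate policy; ties are handled
  by the `wilcox` zero-method, which drops zero differences.
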