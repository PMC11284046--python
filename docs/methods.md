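# Methods

`caemgbdt` classifies cancer subtypes from multi-omics profiles (gene
expression, miRNA expression, DNA methylation) in three stages: per-sample
standardization, joint per-omics convolutional autoencoding with a shared
channel/spatial attention block, and gradient-boosted tree classification
of the assembled features. This note records the model, its assumptions,
the defaults and why, and what the synthetic benchmark does and does not
establish.

## Preprocessing

Each omics layer is a features × samples matrix; layers are aligned by
sample ID (not column position), concatenated on the feature axis, and
transposed to samples × features. Standardization is **per sample**: row
*i* is mapped to `(x_ij − u_i) / σ_i` with `u_i` the row mean and `σ_i` the
*population* standard deviation (denominator *n*). This is deliberate and
unusual — conventional pipelines scale per feature — but it makes the
transform stateless, hence free of train/test leakage by construction. A
conventional per-feature scaler is available behind
`SampleStandardizer(per_feature=True)` but is not the default. Rows with
zero variance map to all zeros rather than raising: a flat profile carries
no signal but is plausible in sparse layers. Missing values are a load-time
error; no imputation is offered.

## Autoencoder geometry

Each omics block gets its own encoder/decoder pair described by an
`ArchitectureSpec`:

* **encoder** — dense layer(s) compressing the block width, a reshape to a
  single-channel sequence, then `Conv1D(kernel 3, stride 2, same padding,
  GELU) + MaxPool` stages;
* **decoder** — the mirror: `UpSample(×pool) + ConvTranspose1D(kernel 3,
  stride 2, GELU)` stages ending in a single channel, then dense layer(s)
  restoring the exact input width. The final dense layer is **linear**,
  since standardized data is unbounded in both signs.

Two presets are shipped: a wide stack (Dense 512 → Conv 16 filters/Pool 2 →
Conv 4/Pool 4) for high-dimensional blocks and a narrow one (Dense 128 →
Conv 4/Pool 4) for small blocks; both yield a 16-position × 4-channel
latent. `auto_spec` shrinks the narrow geometry (dense width = largest
power of two ≤ min(width, 128), floor 8) so arbitrary and tiny synthetic
blocks work; the channel count stays 4 so all blocks can share one
attention module. All intermediate lengths follow the closed-form rules
(`ceil(L/s)` for same-padded convolution, `s·(L−1) + k − 2p` for transposed
convolution, integer division for pooling) and `shape_trace` computes them
symbolically; the test suite checks the realized network against the trace
layer by layer.

Transposed convolutions use padding 0, so decoder lengths slightly
overshoot the encoder's (e.g. 64 → 129 instead of 128); the final dense
layer absorbs the mismatch. This keeps every stage's size a closed-form
expression instead of per-layer output-trimming heuristics.

## Attention

The shared block refines the concatenated latent (positions stacked across
omics blocks, 4 channels):

* **channel attention** — average- and max-pool over positions; both pooled
  vectors pass through *one shared* two-layer MLP (hidden width
  `max(channels/ratio, 1)`, ReLU hidden, linear output, biases included);
  the two outputs are summed and squashed by a sigmoid into per-channel
  weights.
* **spatial attention** — per-position mean and max over channels, stacked
  as a 2-channel sequence, convolved (same padding, default kernel 7,
  single output channel) and squashed into per-position weights.

`F″ = S(C(F)⊗F) ⊗ (C(F)⊗F)`. Both maps lie strictly in (0, 1): attention
only attenuates. The reduction `ratio` defaults to 8 (a convention; with 4
channels the hidden width floors at 1). Channel-before-spatial order is
fixed; the reverse exists only behind `attention_order="spatial_first"`
for ablation. The attention parameters sit on the encoder→decoder gradient
path and train jointly with the autoencoders.

## Training objective and optimizer

All blocks train jointly under

    J = (1/2N) Σ_i ‖x_i − x̂_i‖² + λ Σ_W ‖W‖²

— half the mean squared reconstruction error plus an L2 penalty over
trainable *weight matrices* (biases excluded). Optimization is mini-batch
Adam, step size 1e-3, batch 16, λ = 1e-4, 100 epochs by default. The
optimizer, step size, and batch size are this package's choices (the
method's description fixes only "gradient descent" and 100 epochs); all are
exposed in configuration. The per-epoch log records the mean of batch
losses. Dense layers use GELU like the convolutional ones (switchable to
linear via `dense_activation`). Everything is implemented in NumPy with
hand-written backward passes; correctness is enforced by central-difference
gradient checks in the test suite rather than by an autodiff framework.
The Adam update and the weight-penalty gradient are fused single-pass
numba kernels (with pure-NumPy fallbacks): at tens of millions of
parameters these memory-bound elementwise updates, not the matrix
products, dominate wall time.

Arithmetic runs in float32 by default (`dtype="float64"` available); with
BLAS pinned to one thread — done automatically at package import unless the
environment says otherwise — identical seeds give bitwise-identical
training logs, features, and metrics.

## Classifier features

The classifier input per sample is the flattened refined latent X″
(positions fastest within each channel) concatenated with the decoder
reconstruction X⁗ — deliberately *wider* than the raw input, following the
method's stated assembly. `latent_only=True` drops the reconstruction for
users who want a compact representation; the ablation harness exposes the
same switch.

## Boosted trees

The final stage is scikit-learn's `GradientBoostingClassifier` under this
package's validated configuration: learning rate 0.1, ≤ 300 stages
(enforced as a hard cap), depth-3 trees, ≥ 5 samples per leaf and split,
stage subsampling 0.8, log-loss ("deviance") objective. Multi-class
problems fit one tree per class per stage (one-vs-all), so M stages and K
classes give M·K trees; per-class scores are softmax-normalized. Optional
early stopping holds out 15 % of the training samples and stops after 10
non-improving stages (the fractions are this package's choice). Staged
training log-loss is recomputed on the full training set after fitting and
is checked to be non-increasing.

Metrics are accuracy plus macro-averaged one-vs-rest precision, recall, and
F1 (per-class F1 = harmonic mean of that class's precision and recall,
then unweighted class mean), reported as percentages to one decimal.
Macro averaging is chosen because single reported values for imbalanced
multi-class problems are most consistent with it.

## Synthetic benchmark

The generator emulates the *shape* of the real inputs — several blocks of
stated widths (e.g. 17,814 + 354 + 23,094 features × 104 samples for the
breast-cancer-shaped fixture, 12,042 + 534 + 1,305 × 213 for the
glioblastoma-shaped one), K subtypes, balanced by default. Structure per
block: per-feature Gaussian baselines; for an `informative_frac` subset
(default 10 %, 2 % at full scale), an additive shift of magnitude
`effect_size · noise_sd` applied to a random proper nonempty subset of
classes (a shift shared by *all* classes would carry no between-class
signal); i.i.d. Gaussian noise (σ = 1). Subtype counts per class use
largest-remainder apportionment, so balanced configs are exactly balanced.
K = 4 for the full-scale fixtures (the typical subtype count for these
cancers; the source datasets' label compositions are not published with
the method).

Not simulated: real covariance structure, bounded methylation beta values,
batch effects, platform artifacts, class imbalance (available as a knob,
not a default). A green end-to-end test therefore establishes that the
pipeline recovers *planted mean-shift* structure at the stated
dimensionalities — not that it reproduces accuracies reported on real
tumors.

## Protocol choices

* Splits are stratified by subtype (tiny classes make unstratified folds
  degenerate); five-fold cross-validation or a single 3:1 train/test split.
* Feature extraction is retrained inside every fold on training samples
  only.
* The five-fold headline metric is the across-fold mean (± SD).
* `run_train` writes `metrics.json`, per-epoch loss curves, checkpoints,
  and a manifest (config, config hash, versions) that reproduces the run
  bit-identically; timestamps are kept out of `metrics.json` on purpose.

## Numerical details and edge cases

* GELU uses the tanh approximation; note it is *not* monotone — it has a
  shallow minimum (≈ −0.17) near x ≈ −0.75.
* Max-pooling truncates a trailing remainder window; ties take the first
  index. Degenerate geometries (empty convolution or pool output) raise
  shape errors naming the layer.
* Probabilities are clipped at 1e-15 before logs in the loss.
* A non-finite training loss raises immediately with the epoch index.
* `n_estimators > 300` is rejected, not silently clamped.

## Known limitations

* CPU-only and single-threaded by default; the full-scale run (41k
  features) takes minutes, not seconds.
* No hyperparameter search, no variational/stacked-autoencoder variants,
  no unsupervised clustering mode.
* The decoder's skip-free sequential path is the implemented reading;
  a latent-to-decoder skip connection is not provided.
* No missing-data handling beyond refusal, and no batch correction.
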