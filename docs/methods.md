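# Methods

This note documents the models and procedures `strokecad` implements, the
defaults it chose where the underlying method descriptions leave choices
open, and what its synthetic experiments do and do not demonstrate.

## Preprocessing: global thresholding

The binarization rule is f(x,y) = 1 iff g(x,y) ≥ I (boundary inclusive),
a single global threshold per image. Although pipelines of this kind are
often described as "adaptive" thresholding, the rule itself is global; we
give "adaptive" an operational meaning by making the selection of I
pluggable: `fixed` (user value, must lie in the image's intensity range),
`mean` (global mean intensity) and `otsu` (between-class variance
maximizer, via scikit-image), with `otsu` the default. A constant image
degenerates Otsu's criterion; we return the constant itself and the
resulting mask is all ones (every pixel ≥ I).

A strictly binary output would destroy the intensity texture downstream
features rely on, so the default pipeline applies the mask
multiplicatively (`masked_enhance`: background → 0, foreground intensities
preserved); `literal_binary` emits the mask itself for fidelity to the
binarization rule. No denoising, bias-field correction or registration is
performed. Images read from 8-bit files are normalized to [0, 1] on
ingest; one intensity convention everywhere.

Invariants tested: pixelwise monotonicity in I, idempotence on binary
inputs, and agreement with a per-pixel loop on random images.

## Feature extraction

`builtin_texture` is a deterministic 40-dimensional descriptor:

- 16-bin intensity histogram over [0, 1], normalized by pixel count;
- 8-bin gradient-orientation histogram over [−π, π], weighted by gradient
  magnitude and normalized by total gradient energy (an all-flat image
  yields a zero histogram rather than 0/0);
- 4×4 grid of block means.

Pretrained CNN backbones are runtime plugins behind the same
`extract(image, spec) -> vector` contract; requesting an unregistered one
raises a capability error naming the plugin. Which layer of a pretrained
network supplies features is left to the plugin; the core package does not
guess. Grayscale replication to three channels is likewise a plugin
concern.

Fusion concatenates per-extractor vectors in configuration order,
optionally standardized with per-feature mean/sd fitted on training data
only; standard deviations below 1e−12 are clamped to 1 so constant columns
map to 0.

One caveat discovered while testing: the intensity histogram is *not*
invariant to zero-padding (padding adds mass to bin 0). The invariant that
does hold, and is tested, is that zero-padding an image whose boundary is
already zero leaves the gradient-orientation histogram unchanged, while
block means change.

## Improved dragonfly optimizer (IDFO)

Swarm of n positions X with step vectors ΔX. Per individual i, with
neighbors = swarm members within a (Euclidean) neighborhood radius:

- separation S = −Σ_j (X − X_j), alignment A = mean_j ΔX_j,
  cohesion C = mean_j X_j − X (all zero when isolated);
- food attraction F = X⁺ − X toward the best-so-far position;
- enemy distraction E = X⁻ + X, implemented exactly as published (the
  same form appears in the original dragonfly source); a config flag
  `enemy_formula="outward"` switches to X⁻ − X for experimentation.

Update: ΔX(t+1) = s·S + a·A + c·C + f·F + e·E + w·ΔX(t), X ← X + ΔX, with
steps clipped elementwise to one tenth of the box range and positions
clamped to bounds. Isolated individuals take a Mantegna Lévy flight
(β = 1.5) around their position with their step reset.

The update rule is published without a coefficient schedule; we adopt the
schedule of the original dragonfly algorithm: w linear 0.9 → 0.4;
s, a, c ~ U[0, 2r_t] with r_t = max(0, 0.1 − t·0.1/(T/2)); f ~ U[0, 2];
e = r_t; neighborhood radius (range/4) growing by 2·range·t/T. All of it
is config-exposed. The "improved" ingredients are the uniform
per-dimension random initialization x(0) = S_min + (S_max − S_min)·U(0,1)
and an optional, disabled-by-default global-pollination move toward the
food source (a Lévy-weighted step, the only defensible reading of the
flower-algorithm hybridization the method sketch gestures at). Food
tracks the best position seen so far; the enemy is the worst individual
of the current iteration.

## Satin bowerbird optimizer (SBO)

Selection probabilities from fitness: cost_i = 1/(1 + f_i) for f_i ≥ 0,
1 + |f_i| otherwise (always > 0, so probabilities are well defined);
Prob_i = cost_i / Σ cost. Attraction, per individual and per dimension k,
with target j drawn by roulette wheel:

x_ik ← x_ik + β_k((x_jk + x_elite,k)/2 − x_ik), β_k = α/(1 + Prob_j).

The published step-size rule does not fix whose probability enters β; we
use the selected target's (better targets → smaller, more careful steps),
matching the method's original source, with `beta_uses_self` as the
alternative. Mutation perturbs each element with probability
`mutation_prob` by σ·N(0,1), σ = Z·(VarMax − VarMin). Each generation the
old and modified populations are pooled, sorted by fitness (stable sort)
and truncated to n, so the elite is never lost. Defaults α = 0.94,
Z = 0.02, mutation_prob = 0.05 follow the SBO literature.

Both optimizers draw all randomness from one seeded generator per run and
are reproducible byte for byte; both enforce a finite-objective contract
(a non-finite value aborts the run naming the offending vector); both
record a running-minimum trace, non-increasing by construction.

On the 5-D sphere over [−5, 5] with n = 30 and 500 iterations, IDFO
reaches ~1e−4–1e−8 and SBO ~1e−6–1e−7 depending on seed (the acceptance
bar is 1e−2); each run takes under a second.

## Stacked autoencoder classifier

Architecture default input → 64 → 32 → K (layer sizes are not fixed by
the method description; these are conventional desk-scale choices),
sigmoid activations, softmax head. Training:

1. **Greedy layerwise pretraining** — each encoder layer plus a throwaway
   linear decoder is trained by full-batch gradient descent on the mean
   squared reconstruction error of the previous layer's codes; labels
   unused. Zero epochs leaves the seeded Glorot initialization intact.
2. **Fine-tuning** — a K-way softmax head is appended and the whole stack
   is trained end to end on cross-entropy by full-batch gradient descent;
   the loss trace is retained (and tested to be non-increasing at small
   learning rates).
3. **SBO weight refinement** — the entire flat weight/bias vector is
   searched inside a trust region (current parameters ± 0.5 by default)
   with classification error rate on a stratified held-out tuning split
   (20%) as fitness. The input parameters are injected into the initial
   population, so elitism guarantees the result is never worse on that
   split. Direct weight search scales poorly, so the flat dimension is
   capped at 5000 (a capability error past that advises a smaller net or
   hyperparameter mode). Whether published results of this design refine
   weights, hyperparameters or both is unstated; both modes exist.

`idfo_tune_hyperparams` searches named continuous ranges
(learning rate, hidden sizes, epoch counts) with IDFO; integer-valued
entries decode by rounding (3.6 → 4), single-point dimensions are held
fixed, and an all-fixed space short-circuits to that point.

Prediction is the argmax of the softmax scores with ties broken toward
the smaller class index (numpy's argmax convention — determinism for
tests). Flatten/unflatten of the parameter vector is exact and tested;
models serialize to a versioned JSON schema, optionally carrying the
input standardization fitted on training data (not part of the trainable
vector).

"Epochs 500–2000" in the evaluation tables are read as total training
epochs of the classifier stage; no other reading is supportable.

## Evaluation

From a K×K confusion matrix (rows true, columns predicted), each class is
scored one-vs-rest: TP = cm[c][c], FN = row − TP, FP = col − TP,
TN = total − TP − FN − FP, then sensitivity, specificity, per-class
accuracy, precision, F-score and MCC on a ×100 scale. 0/0 cells return 0
with a warning — the convention keeps reports total; the brute-force
oracle tests apply the same rule. Macro rows are unweighted means. The
per-class "accuracy" column is one-vs-rest binary accuracy, which is what
such tables must contain (their values exceed the overall multiclass
accuracy); the trace/total multiclass accuracy is reported separately as
`overall_accuracy`. Rounding to 2 decimals happens only at serialization.

`diagonal_confusion` rebuilds a matrix from per-class correct counts and
class sizes when only diagonals are reported; row-sum metrics
(sensitivity, overall accuracy) are exact under any placement of the
unattributed errors, column-dependent ones are not, and tests only assert
the former against published-style values.

## Synthetic data: what it emulates and what it does not

`generate_images` mimics the *shape* of the target collection — six
classes sized 25/25/24/54/26/24 (178 grayscale slices, nominally
256×256; tests use smaller sizes for speed) — via class signatures in
mean intensity, Gaussian-blob count and sinusoidal texture frequency,
plus additive Gaussian pixel noise, clipped to [0, 1]. Defaults
(noise_sd 0.05, class_contrast 1.0) make classes separable by texture
features: deliberately an easy regime, because the fixtures exist to
verify the pipeline's machinery, not to simulate MRI physics. Passing
tests demonstrate that the chain preserves and exploits class structure
present in its input; they say nothing about performance on real MR
data, where class differences are subtler and confounded.

`generate_feature_table` draws class-conditional unit-variance Gaussians.
With n_features ≥ n_classes the means sit on scaled one-hot axes, every
pair exactly `separation` apart; with fewer features they are spaced
`separation` apart along the first axis. At separation 6 the two-class
Bayes error is Φ(−3) ≈ 0.13%, the closed-form yardstick behind the
parameter-recovery acceptance run (100 samples, small SAE, SBO
refinement, ≥ 95% held-out accuracy required).

## Numerical and design choices

- One seeded `numpy` generator per run; the pipeline fans a single global
  seed into per-stage substreams via SeedSequence keyed on a CRC of the
  stage name (stable across platforms, always < 2³¹).
- Stratified 80/20 train/test split with seeded shuffling (at least one
  sample per class in the test split).
- Sigmoid inputs are clipped to ±60 before exponentiation; softmax is
  computed shift-invariantly.
- Bounds require var_min < var_max elementwise; positions are clamped
  after every public optimizer operation.
- Pipeline artifacts embed the SHA-256 hash (first 16 hex digits) of the
  result-relevant config (workdir and verbosity excluded); the extracted
  feature table is cached under that hash and reused on rerun.
- Problem sizes in the test and acceptance runs (64×64 or smaller images,
  ≤ 178 images, networks of a few thousand parameters, 500-iteration
  optimizer budgets) are desk-scale choices that keep every check fast
  while exercising the same code paths as larger runs.

## Known limitations

- The headline accuracies reported for pipelines of this design on the
  real 178-slice collection are not reproducible here: the collection has
  no public deposit and the CNN backbones are not shipped. The package
  verifies the machinery (arithmetic, optimizers, training dynamics) on
  synthetic data instead.
- Direct SBO weight search is capped at 5000 parameters; beyond that only
  hyperparameter mode is available.
- The off-diagonal structure of published per-epoch confusion figures is
  not recoverable from their text, so column-dependent table cells
  (specificity, precision, MCC) are verified against a brute-force oracle
  on synthetic matrices rather than against published rows — with one
  exception: a published per-class row whose counts are fully pinned by
  its sensitivity and precision is reproduced exactly in the tests.
- The fine-tuning optimizer is plain full-batch gradient descent; it is
  adequate at fixture scale but no substitute for minibatch/adaptive
  methods on large data.
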