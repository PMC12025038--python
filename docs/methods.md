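# Methods

## Problem and model

The package addresses joint per-pixel lesion segmentation and per-image
classification of single-channel kidney CT crops into {normal, cyst,
stone, tumor}. Two architectures are provided.

**Single-stream CNN.** Four 3×3, stride-1, 'same'-padded convolution +
ReLU layers; with no pooling the spatial plane is preserved end to end,
so the segmentation head is a single 3×3 convolution to 2 logit planes
and the classification head a dense layer over the flattened features.
The channel sequence (16, 32, 64, 128) is this package's choice; the
architecture description fixes only depth, kernel, stride and padding.

**Multi-stream CNN.** Two parallel pathways over the same input, one
with plain and one with dilation-2 convolutions (a local-detail and a
wider-context stream), each following stage shapes 46×46×c₁ → 23×23×c₂
→ 11×11×c₃ → 5×5×c₄ via 2×2 max-pooling. The default stage widths are
c = (256, 138, 128, 64). The 138-channel stage is unconventional (not
a power of two) but is kept verbatim as the default and is overridable
in config.
The odd spatial sizes force the pooling convention: floor division
(46→23→11→5); ceiling division would give 46→23→12→6 and cannot
realize the documented shapes. Raw inputs are 1-channel; the first
convolution lifts to c₁, so the stated input-stage width describes
feature maps rather than raw pixels. Stream outputs are fused by channel
concatenation; the segmentation head upsamples the fused 5×5 features
back to 46×46 by nearest neighbor followed by one 3×3 convolution —
the simplest possible decoder, chosen deliberately; the
classification head is a dense layer on the flattened fusion.

Dropout (rate 0.25) after each pool and an L2 weight penalty implement
the stated regularization. All layers carry hand-written reverse-mode
gradients in numpy; a central-finite-difference checker (relative
tolerance 10⁻⁴) in the test suite guards every layer type.

## Losses and metrics

Segmentation and classification use the same cross-entropy form,
−(1/N) Σᵢ Σ_c y_ic log p_ic with natural logarithm (the
field's convention) and probabilities clamped to
[10⁻¹², 1]. For segmentation the samples are pixels. The total
objective adds an auxiliary term, by default the L2 penalty
(coefficient 10⁻⁴, 0 allowed).

Metrics are confusion-count based; multi-class reports use correct/total
accuracy and one-vs-rest, macro-averaged precision and recall, with the
report's F1 the harmonic mean of its own macro precision and recall.
Degenerate zero-denominator cases yield a sentinel 0 plus a flag rather
than an exception. The error measure MSE = 1 − A² is an
accuracy-derived scalar, not a pixel-space mean squared error; at
A = 0.92 it equals 0.1536, an order of magnitude above typical
pixel-space values, and should not be compared against them.

## Firefly Sigma Seeker

The dispersion statistic is the population standard deviation of the
last `window` (default 10) validation losses. The adaptive threshold
is θ = σ_mult · σ_loss.

Stopping fires when either (a) the epoch-over-epoch loss decrease stays
below the θ implied by the loss window ending at that epoch for
`patience` (10) consecutive epochs, or (b) the best validation loss has
not improved by `min_delta` (0.01) for `patience` epochs. Neither rule
can fire before `patience` transitions exist. Raising σ_mult can only
add stops under rule (a) (monotonicity, property-tested).

The swarm optimizer searches (σ_mult, α) by default, bounds [0.1, 5] ×
[0, 2]. Each firefly moves toward every brighter peer — the canonical
all-brighter rule; brightness is validation total loss, ties broken by
index — displaced by β · A_eff · (x_j − x_i), with A_eff the peer's
attractiveness decayed as A · exp(−γ_abs · d). Two deliberate
concretizations: the attraction term is directional (a scalar added to
a position vector would be dimensionally ill-formed), and the two
distinct roles the symbol γ plays (attractiveness decay vs randomness
scale) are split into `gamma_abs` and `gamma_rand`. Distances are
measured in units of the box diagonal, making the decay rate
scale-invariant across search spaces; each firefly's stored
attractiveness decays with the distance it just moved, so a settled
swarm keeps attracting. The random kick is uniform, gamma_rand ·
range · U[−0.5, 0.5] per dimension, geometrically annealed
(`rand_decay` 0.95) so the swarm settles in a basin. Defaults
(population 15, 50 iterations, β = 1, γ_abs = 1, γ_rand = 0.3) place
the swarm within 2 % of the box diameter of the optimum on separable
convex problems in 1–3 dimensions for at least 9 of 10 seeds; elitist
bookkeeping makes the best-so-far trace monotone.

The threshold refinement θ ← clamp(θ − η_θ · g, 0, θ_max) needs a
gradient that hard pruning does not possess; g is a central finite
difference of the validation loss under masks built at θ ± 0.1θ,
evaluated on a capped validation subset (64 samples). This is an
explicit approximation, used only to steer θ.

## MagWeight Rank

Per layer: mean|W| over currently active weights, threshold α · mean|W|,
keep iff |w| ≥ threshold and previously kept. Masks only grow sparser;
equality at the boundary keeps the weight (the conservative reading of
"exceeding kept, falling below pruned"). Biases are never pruned.
Computing the mean over active weights only makes repeated pruning
events well defined. If a threshold would empty a layer, its single
largest-magnitude weight survives and the report flags the event.
Pruning runs every 5 epochs after a 5-epoch warm-up; masked positions receive no SGD updates and zero velocity,
so weights never resurrect. Default α = 0.5 when the swarm search does
not supply one. The ranking (descending |w|, ties by ascending flat
index) is exposed as a diagnostic only. For iid N(0, 1) weights at
α = 1 the pruned fraction has the closed form 2Φ(√(2/π)) − 1 ≈ 0.575,
used as an independent oracle in the tests.

## Training protocol

Batch 32, up to 50 epochs, lr 10⁻³ × 0.9^⌊epoch/10⌋, SGD momentum 0.9
(plain gradient descent is the momentum-0 special case, kept behind a
flag). Splits are stratified 70/15/15 by label, the conventional
ratios. The firefly search, when used, runs as an outer loop over
short inner trainings, which keeps each firefly evaluation a
well-defined experiment rather than interleaving the two loops. Per-epoch accuracy comes from a
deterministic evaluation pass (dropout off), not from a counter inside
the batch loop.

## Synthetic phantoms

Each phantom is a smooth noisy background plus a brighter, slightly
rotated elliptical kidney (axes 16 × 11 px in a 46 × 46 plane), with a
class-specific lesion inside the kidney: cysts are round and darker
(fluid), radius 4–6.5 px, intensity −0.35; stones small and bright
(calcification), 1.5–3 px, +0.55; tumors larger, mildly hyperintense
(+0.30) and irregular — a union of 2–4 jittered discs, the simplest
multi-lobed shape. The morphology is a stand-in chosen for class
separability, not a claim of radiological realism.
Images are min–max normalized to [0, 1]. Masks get nearest-neighbor
interpolation under augmentation (rotation, scaling, flipping,
translation in (row, col) convention) so they stay binary; images get
bilinear. Class apportionment uses the largest-remainder rule with ties
broken in canonical class order.

The phantoms emulate the intensity/shape cues that distinguish the four
classes and the normalization/augmentation pipeline of real CT crops.
They do not emulate anatomy, partial-volume effects, scanner noise
spectra, or inter-patient variability — passing tests demonstrate that
the optimization and training machinery works, not radiological
performance on real data.

## Scaled-down study and problem sizes

The end-to-end study trains the multi-stream model on 400 phantoms
(uniform class mix) for up to 20 epochs with FSS and MWR enabled. At
the default widths this model has ~1.8 M weights in its second conv
stage alone; the `desk` profile instead uses stream widths
(12, 10, 12, 8) (~8 k parameters) and learning rate 0.03 — a rate
suited to the small parameter count, chosen once for this profile —
so the study completes in about a minute on a single core. Under seed 1
the run stops early at epoch 14 by the adaptive rule with validation
accuracy 0.967, total loss 0.164 (epoch 1: 1.476) and sparsity 0.31;
the run is bit-reproducible for a fixed seed.

## Known limitations

* Accuracy-derived MSE is not a pixel-space mean squared error.
* The surrogate threshold gradient is a heuristic; θ refinement is a
  small correction, not a principled descent.
* Phantom realism is deliberately minimal (see above).
* The numpy implementation is single-threaded and CPU-bound; the
  full-width configuration trains slowly and serves as an architectural
  reference.
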