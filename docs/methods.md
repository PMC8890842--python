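# Methods

## Problem and model

The package classifies endoscopic video frames into three anatomical
landmark classes — Z-line (squamocolumnar junction), pylorus, and cecum —
with a small convolutional network, and implements a semisupervised
*self-training* scheme that reaches comparable accuracy from a small
labeled fraction of the training data.

The classifier is a fixed sequential CNN on 32×32×3 inputs in [0, 1]:

| layer | output shape | parameters |
|---|---|---|
| input | 32×32×3 | 0 |
| conv 3×3, 32 filters, same, ReLU | 32×32×32 | 896 |
| maxpool 2×2 | 16×16×32 | 0 |
| batchnorm | 16×16×32 | 128 |
| dropout 0.25 | 16×16×32 | 0 |
| conv 3×3, 64 filters, same, linear | 16×16×64 | 18 496 |
| LeakyReLU (slope 0.3) | 16×16×64 | 0 |
| maxpool 2×2 | 8×8×64 | 0 |
| batchnorm | 8×8×64 | 256 |
| dropout 0.25 | 8×8×64 | 0 |
| conv 3×3, 64 filters, same, ReLU | 8×8×64 | 36 928 |
| maxpool 2×2 | 4×4×64 | 0 |
| flatten | 1024 | 0 |
| dense 128, ReLU | 128 | 131 200 |
| batchnorm | 128 | 512 |
| dropout 0.5 | 128 | 0 |
| dense 3, softmax | 3 | 387 |

Total 188 803 parameters.  Kernel sizes are not free choices: 3×3 with
"same" padding is the unique standard configuration reproducing the
per-layer parameter counts (896 = 32·(9·3+1), 18 496 = 64·(9·32+1),
36 928 = 64·(9·64+1)) together with the printed output shapes.
Batchnorm is counted at 4 parameters per channel (scale and shift plus
the two running statistics), the total-parameters convention of common
framework summaries.  The second conv block is linear followed by an
explicit LeakyReLU layer; the remaining conv/dense layers use ReLU, and
the output layer is softmax.  Dropout rates are not determined by the
parameter table (dropout has no weights); the defaults 0.25/0.25/0.5
are the common conv/conv/dense convention and are configurable, as is
the LeakyReLU slope (default 0.3).

The network, its layers (convolution, max-pooling, batch normalization,
dropout, dense), softmax cross-entropy and the Adam optimizer are
implemented directly in NumPy (`sscnn.nn`).  Convolution gradients are
verified in the test suite against an independent sliding-window/einsum
reference and end-to-end against float64 finite differences.  All
computation is float32 and single-threaded BLAS; training is
bit-reproducible for a fixed seed.

## Training protocol

Supervised training: Adam (learning rate 0.001, β₁ = 0.9, β₂ = 0.999),
batch size 8, categorical cross-entropy, 60 epochs, no early stopping;
the final-epoch model is the one evaluated.  Data are split
stratified-per-class 80:20 into training and test sets, then the
training portion 75:25 into training and validation subsets.  Per-class
split counts use round-half-up; the remainder goes to the larger part.
The validation subset is used for hyperparameter selection (an
exhaustive grid-search utility is provided) and is never added to the
self-training pools.

### Batchnorm recalibration

Running batchnorm statistics are exponential moving averages collected
while the weights are still moving (momentum 0.9 here; the slower 0.99
convention needs thousands of steps to converge and collapsed inference
on short runs).  Even at momentum 0.9 the averages can sit far from the
final activation distribution when training is short and activations
have low variance — badly enough to flip inference predictions while
training-mode accuracy is perfect.  After every fit the package
therefore pins each batchnorm layer's statistics to the population
statistics of (up to 512 of) the training inputs in one deterministic
front-to-back pass with dropout off.  This is the standard
post-training BN recalibration and affects inference only.

## Self-training loop

The training subset is partitioned per class into a labeled pool (LDS,
m % of each class, minimum one sample) and an unlabeled pool (UDS, the
complement).  Each iteration:

1. the current model predicts class probabilities for every UDS sample;
2. each sample's confidence is its maximum softmax probability (argmax
   ties break toward the lowest class index);
3. for every class present among the predictions, the `per_class` most
   confident samples (default 1; within-class ties break toward the
   smaller sample id) are moved into the LDS carrying their *predicted*
   class as pseudo-label — never the withheld truth;
4. the model is retrained on the enlarged LDS — by default warm-started
   from its current weights and optimizer state for
   `epochs_per_iteration` epochs (default 2), or from scratch for the
   full epoch budget with `cold_start`.

The loop terminates exactly when the UDS is empty; a final remnant
smaller than the class count is promoted wholesale.  Because at least
one sample is promoted per iteration, the loop halts in at most |UDS₀|
iterations.  Sample conservation (|LDS| + |UDS| constant), provenance
tagging (original vs pseudo, with promotion iteration and confidence),
and the m = 100 degenerate case (no iterations; bit-identical to the
supervised trainer under the same seed) are all tested invariants.

The confidence score is deliberately pluggable (`max_softmax`, `margin`,
`neg_entropy`): maximum softmax probability is the default because it is
the standard self-training score for a softmax classifier.  True UDS
labels are retained internally but hidden from the learner; they feed a
pseudo-label-accuracy diagnostic in the per-iteration history.

## Synthetic data generator

Real endoscopy frames are not redistributable inside a test suite, so
the generator produces three visually distinct motif classes as
surrogates: a vertical two-tone boundary (Z-line-like mucosal
transition, contrast 0.40), a bright annulus with a dimmer lumen
(pylorus-like), and a smooth low-frequency sinusoidal texture
(cecum-like), each with a mild characteristic RGB tint.  Per-image
geometric jitter (±10 % on motif position/scale/frequency) prevents the
task from being solvable by a single pixel, and seeded additive Gaussian
pixel noise (`noise_sd`, clipped to [0, 1]) gives a monotone difficulty
dial the real data lacks.  Defaults: 500 images per class, 64×64 pixels
(exercising the resize-to-32 path), `noise_sd` 0.10 — a moderate level
at which the classes remain learnable but single-pixel heuristics fail.

What passing tests on this generator do show: the architecture trains,
the loop's bookkeeping is correct, and the supervised/semisupervised
accuracy pattern (high supervised accuracy; self-training within a few
points at m = 20 %; accuracy non-decreasing in m) is recovered.  What
they do not show: performance on real endoscopic imagery, whose
intra-class variability, lighting and texture are far richer than three
parametric motifs.  An image-folder reader (one subdirectory per class)
accepts a real dataset whenever one is available.

## Problem sizes and numerical choices

* Resize: bilinear, Gaussian prefilter when downscaling; uint8 inputs
  scaled by 1/255.
* Batchnorm: eps 1e-3; Adam eps 1e-7; Glorot-uniform init, zero biases.
* Max-pool gradient ties route to the first maximal entry of the window.
* 0/0 metrics report 0.0 with a warning; AUC uses midranks for ties and
  NaN for a class absent from the truth (macro-AUC averages the rest).
* Micro-F1 is the harmonic mean of micro-precision and micro-recall
  (for single-label data all three equal accuracy).
* The evaluation-scale experiments (acceptance script and the heavier
  tests) use 3×500 images, 5 seeds, 10 supervised epochs at batch 32,
  and self-training with 30 promotions per class per iteration at 1
  warm-start epoch — sizes chosen so the full sweep runs on a single
  CPU core in minutes while leaving the accuracy pattern intact.  The
  package defaults remain the published protocol (60 epochs, batch 8,
  one promotion per class).

## Known limitations

* The per-iteration retraining schedule of the original protocol is not
  fully specified; warm-starting for a few epochs is the package's
  default, with cold-start retraining available.  The two can differ on
  hard data.
* The NumPy engine targets this architecture family (stride-1 same-pad
  convs, 2×2 pools); it is not a general deep-learning framework.
* Batch statistics make training-mode evaluation depend on batch
  composition; all reported metrics use inference mode with
  recalibrated statistics.
* Whether the labeled fraction m is taken of the 1200-sample original
  training set or the 900-sample training subset is ambiguous in the
  source protocol; the package uses the 900-sample training subset
  (validation data never enter the pools).
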