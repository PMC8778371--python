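# Methods

## Problem and approach

Texture directionality is the dominant orientation of local intensity
structure, defined with 180° periodicity (a direction and its opposite
are the same). `texdir` treats directionality estimation as a
classification problem: a CNN maps a grayscale tile to a probability
vector over 180 one-degree classes, and the predicted direction is the
argmax class. Classification (rather than regression) keeps the full
probability vector available, so a low maximum probability can be used
to reject tiles with no meaningful direction, and multimodal direction
content remains visible in principle.

## Synthetic corpus

Training data are synthetic bar gratings with exactly known
orientation. A 1000×1000 16-bit image of vertical bars (background
16,384, foreground 49,151) is defined by bar thickness and period
(rising edge to rising edge), with thickness < period; the canonical
nine patterns are 2/8, 3/6, 4/8, 6/12, 8/16, 16/32, 20/40, 24/48 and
32/64. The image is rotated by an integer angle in [0°, 179°] with a
bilinear affine warp and cropped to the central 500×500 region, which
always lies inside the rotated support (1000/√2 ≈ 707 > 500). Optional
perturbations are applied to the whole 500×500 texture before tiling:
zero-mean additive Gaussian noise (σ ∈ {2000, 4000, 6000, 8000}
intensity units, clipped to [0, 65535] and rounded) or a normalized box
("mean") filter with kernel 3, 5, 7 or 9 (reflect-101 borders; only the
interior is tiled, so the border convention is immaterial but fixed).
Each texture is cut into 49 non-overlapping 64×64 tiles on a centered
7×7 grid (26-pixel margin on each side, avoiding systematic border
bias); every tile inherits the rotation angle as its label. The full
configuration yields 9 × 180 = 1,620 base textures, ×(1+4+4) = 14,580
perturbed textures, ×49 = 714,420 tiles, shuffled and split 1/2 : 1/4 :
1/4 (validation and test sizes round down; train takes the remainder).
One seeded generator drives noise and shuffling in a fixed order, so a
corpus is bit-reproducible from its seed.

**Angle convention.** Labels measure the bar direction
counter-clockwise from vertical as the image is displayed (origin in
the upper-left corner). Generation, the baselines, the mapper overlay
and the polar histogram all share this convention; the suite's
oracle-agreement tests pin it.

## Architectures

Four shallow networks (one unpadded convolution — 17×17 with 180 or 90
filters, or 13×13 with 180 or 90 — followed by global max pooling,
dropout 0.25 and a 180-way softmax) and eight deep networks (three
unpadded convolutions: 17×17 or 7×7 with 16 or 90 filters, then 5×5
with 16 or 32, then 3×3 with 90; 2×2 max pooling and dropout 0.25
after the first two, global max pooling after the third; dense 90,
dropout 0.5, softmax 180). Convolutions are unpadded because padding
would fabricate orientation artifacts at tile edges, and stride 1 —
the only stride consistent with the minimum-input-size relation below.
Global max pooling decouples the classifier from input size; the
smallest admissible square input is obtained by walking the spatial
layers backwards from a 1×1 map (a k-convolution adds k−1, a p-pool
multiplies by p), which gives

    minImSize = (cf8·mp6 + (cf5 − 1))·mp3 + (cf2 − 1)

for the deep layout (36 for DN1–DN4, 26 for DN5–DN8) and simply the
kernel size for the shallow one (17 or 13).

Parameter counting is exact per-layer arithmetic
(k²·C_in·F + F per convolution, (n_in+1)·n_out per dense layer) and is
asserted to equal the instantiated weight sizes. For eleven of the
twelve architectures this reproduces the published totals; the
published DN6 total (56,562) is internally inconsistent with the
published DN6 layer listing, which sums to 64,212 (= the DN2 total
minus the first-convolution difference). The layer listing is taken as
authoritative.

**Numerics.** The networks run on a small numpy engine: channels-last
float32, im2col + GEMM convolutions (input gradients via col2im
scatter-add, skipped for the first layer), floor-semantics 2×2 max
pooling with first-maximum tie-breaking, inverted dropout (active only
in training), Glorot-uniform initialization from a per-replicate seed,
and Adam (lr 1e−3, β₁ 0.9, β₂ 0.999, ε 1e−7). Analytic gradients are
verified against central finite differences in the suite. Hidden
activations: ReLU, ELU, SELU, sigmoid, softplus, softsign, tanh;
softmax is reserved for the output layer. Tile intensities are divided
by 65,535 on entry, identically at training and inference (only
consistency matters).

## Training and evaluation

Loss is the mean categorical cross-entropy over one-hot labels with
natural logarithm (any base only rescales) and the true-class
probability clamped at 1e−12. Batch size 32; the training set is
reshuffled every epoch with the run seed; per-epoch training and
validation losses are recorded; the retained weights are those with
minimum validation loss (several loss curves reach a minimum
mid-training, so last-epoch weights would be worse). Replicates restart
from distinct seeds spawned from the master seed. The optimizer is not
prescribed by the protocol's source; Adam at 1e−3 is the package
default and is exposed in the API.

Prediction quality is scored with the 180°-periodic angular error
`error(α, β) = acos(|cos(α − β)|)` in degrees — symmetric, invariant
to 180° shifts, bounded by 90°, and equal to the integer periodic
distance min(d, 180−d) on integer angles. RMSE is aggregated overall or
grouped by bar thickness, noise σ, or blur kernel. In method
comparisons, rejected tiles are excluded from RMSE and reported as a
separate rejection count; throughput (tiles/s) is logged but is
hardware-dependent and never asserted.

## Scaled-down study

The full protocol (357,210 training tiles, 200 epochs, 84
network/activation combinations, 3 replicates) is a GPU-cluster
computation. The package's study protocol (`texdir.experiments`) keeps
the study conditions — the same generator geometry, all 180 angle
classes, the same batch size, loss, selection rule and metric — at a
desk scale chosen once: one thick-bar pattern (8/16), no perturbation
(8,820 tiles split 4,410/2,205/2,205), SN1-ELU, 6 epochs, one
replicate. Under these conditions the held-out RMSE reaches ≈1.9° and
validation loss is still falling at the last epoch, which is sufficient
to exercise every contract; robustness is probed by regenerating the
test split's parent textures with each mean-blur kernel and scoring the
identical tile positions, reproducing the blur fall-off trend
(monotone RMSE increase from kernel 5 to 9). What the reduced run does
*not* show: the near-zero clean RMSE of the fully trained networks,
noise-robustness levels, or activation/architecture rankings. The
desk-scale model is also globally under-confident (top probability
≈0.13 on clean gratings vs ≈0.015 on structureless noise, where a
fully trained network sits near 1.0 vs ≈1/180), so while confidence
still separates structure from noise by almost an order of magnitude,
the rejection threshold τ must be retuned for such a model rather than
used at its 0.011 default.

## Baselines

Two classical estimators are reimplemented as independent detectors
and oracles; they are deliberately simple and not bit-compatible with
any particular plugin distribution.

* **Fourier.** The square tile is mean-subtracted, Hann-windowed
  (suppressing edge leakage) and zero-padded ×2; spectral power below
  1 cycle/tile radius (DC and the window's main lobe) is excluded. For
  a directional texture the remaining power concentrates along one line
  through the origin, so the orientation is estimated as the
  power-weighted doubled-angle circular mean of the spectral angles —
  free of the angular-bin quantization that a histogram peak would
  suffer at low spatial frequency. Confidence is the peak fraction of a
  1° angular power histogram; zero off-DC power rejects the tile. On
  unperturbed tiles with period ≥ 8 this recovers generator labels to
  within ±2° (suite check: ≥95% of tiles over all such patterns, angles
  sampled at 5° stride, all 49 positions).
* **LGO (local gradient orientation).** Sobel gradients; each pixel
  votes for the structure orientation (perpendicular to its gradient)
  with weight |∇I|², accumulated into 1° bins over [0°, 180°); the peak
  bin is refined by a doubled-angle circular mean within ±5°.
  Confidence is the peak-bin mass fraction; zero gradient mass rejects.

## Directionality mapper

An arbitrary single-channel 8/16-bit image is linearly rescaled from
its [min, max] onto [16,384, 49,151] — the synthetic training regime —
then divided by 65,535 (a constant image maps to the background level);
this normalization is the package's own choice, as the training
corpus fixes only the 16-bit regime. The image is tiled on a regular
grid (default 64/64; overlapping grids allowed; partial border tiles
are skipped rather than padded, since padding would distort edge
directions). Each tile's estimate carries the argmax angle (ties break
to the lower index), the confidence p_max, and an accept flag
p_max ≥ τ with τ = 0.011 ≈ 2/180 by default — roughly twice the
uniform probability; applications with strong structureless regions may
retune τ so that no direction is detected there. Accepted estimates
are drawn as centered red segments and summarized in a 1° polar
histogram (count-weighted by default; confidence weighting available).
The dominant direction is the doubled-angle circular mean (angles
doubled, vector-averaged, halved) and the spread is the circular
standard deviation on the doubled scale, halved; a mean resultant
length below 0.05 (or an empty histogram) flags the dominant direction
as unreliable.

## Known limitations

* One direction per tile: coexisting multiple orientations are not
  separated (the probability vector is retained for callers who want
  to inspect multimodality).
* The synthetic corpus contains ideal gratings plus noise/blur only; it
  has no curvature, branching, intensity gradients or texture mixtures,
  so test performance on it bounds nothing about real micrographs —
  mapper results on real images are qualitative.
* The baselines approximate the classical methods' ideas, not specific
  plugin implementations; published comparison values for those
  implementations are not reproduced (one published LGO blur row is
  non-monotone — 2.61 at 3×3 vs 1.27 at 5×5 — which these
  reimplementations make no attempt to match).
* Pixel-exact reproduction of any externally produced corpus archive is
  out of scope; only counts, statistics and label semantics are
  guaranteed.
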