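# Methods

## Problem and model

A pulmonary nodule on CT is an ordered stack of axial slices with an
in-slice geometric center and diagnosis codes at the nodule and patient
level (0 unknown, 1 benign, 2 primary malignant, 3 metastatic malignant).
The classifier consumes a standardized volume `(Z, M, N, K) = (6, 50, 50,
n_views)` — `K` channels are concentric square crops ("views") of different
physical extent resized to a common grid — and outputs softmax class
probabilities for the binary (benign / malignant) or ternary (benign /
primary / metastatic) task.

The 3D convolution is the plain cross-correlation
`y[z',i',j',k'] = Σ_{z,i,j,k} w[z,i,j,k,k'] · x[z+z', i+i', j+j', k]` with
stride 1 everywhere; ReLU activations; max/average pooling with stride =
window.  Chain networks follow
`m·(MaxP(ReLU(conv))) + fc + softmax` with the standard filter plan
(CNN1: 3×5×5→20; CNN2 adds 3×3×3→50; CNN3: 3×5×5→20, 3×5×5→50, 2×3×3→50;
fc = 128 units; pool 2×2×2).  The DAG networks use a single 3D Inception
module and replace the fully connected layer with a 1×1×1 convolution (32
channels binary / 64 ternary) followed by 2×3×3 average pooling — a
deliberately *partial* move toward global average pooling: with only 2–3
classes, a fully global pool would leave the softmax classifier with a
handful of parameters, so more channels and a smaller pool are kept.
The Inception-ResNet wraps the Inception1 module in a residual connection;
the branch ends in a 1×1×1 projection back to the shortcut width and is
scaled by 0.1 before the add, a scaling known to stabilize training of
residual Inception variants.

## Volume preparation

* **Slice balancing.** Every nodule is represented by 6 slices.  For `n ≥ 6`
  the selection is `{1, n} ∪ {1 + round((n−1)k/5) : k = 1..4}` with
  half-away-from-zero rounding — the unique simple rule consistent with the
  canonical worked example (`n = 10 → [1, 3, 5, 6, 8, 10]`, a regression
  test).  For `n < 6`, all-zero slices are appended.  For every `n ≥ 6` the
  six selected numbers are distinct because consecutive interior offsets
  differ by `(n−1)/5 ≥ 1`.
* **Cropping.** Views default to 40/50/60 px squares centered on the
  nodule; for even sizes the center pixel sits at offset `size // 2` from
  the top-left (rows `[row − size/2, row + size/2 − 1]`).  Out-of-bounds
  regions are zero-filled, consistent with the all-zero padding slices.
* **Resizing.** In-plane cubic spline interpolation (`scipy.ndimage.zoom`,
  mirror boundary, corner-aligned grid) to 50×50; the slice axis is never
  interpolated.  Identity resizes pass through bit-exactly.
* **Labeling.** Nodule-level code decides; code 0 defers to the patient
  level; if both are 0 the lesion is unlabelable and excluded (the source
  protocol does not state this case; exclusion is the conservative choice).
* **Augmentation.** In-plane rotations on a fixed grid `{0, Δ, 2Δ, …} <
  360°` applied to the final resized multi-view volume, identical angle for
  every slice and view.  Quarter turns dispatch to exact array
  transposition/flips; other angles use bilinear interpolation with zero
  fill.  Rotating prepared patches (rather than raw slices) was chosen
  because it is cheaper and exactly equivalent for the rotation-invariant
  crop region; the alternative order is not expressible in the published
  pipeline description either way.
* Intensities pass through unnormalized by default (an optional per-volume
  min–max flag exists); no Hounsfield-unit calibration is assumed.

## Architecture details fixed by this package

The published material leaves several details to the architecture figures,
which state per-layer output sizes separately for the binary and ternary
nets.  This package's documented reading (`configs/inception_figure.yaml`):

* stem conv 3×3×3 → ReLU → max-pool 2×3×3 (the DAG pooling size), then the
  Inception module, then the 1×1×1-conv/average-pool head;
* branch widths (w1, w3, w5) = (10, 20, 24) with stem 12 for the binary
  net and (8, 20, 64) with stem 16 for the ternary net.

Under this reading the multi-view Inception1 totals are exactly 47,000
(binary) and 148,927 (ternary) parameters — the published 0.47·10⁵ and
1.49·10⁵ at two significant figures — and the one-view-one-network
variant 1 ensemble lands at 1.39·10⁵, matching the published "almost 3
times" relation.  The published conv:softmax ratio column is internally
inconsistent with its own totals (under the alternative no-downsampling
reading, the binary softmax layer alone would exceed the printed binary
total), so `R_p` is reported as computed (~28:1 / ~30:1) rather than
matched.

Other fixed choices:

* **Padding** is 'same' for every convolution (stride 1 preserves spatial
  dims).  'valid' padding is shape-infeasible for CNN3's third conv after
  two 2×2×2 pools.
* **Pooling on odd dims** floors the output (Z: 3→1 under 2×2×2); CNN3's
  third pool meets a Z=1 map, where the window is clipped per-axis to the
  input size.
* **Dropout placement**: unit dropout (rate 0.5) on the fc output; spatial
  dropout (whole-channel Bernoulli trials, rate 0.5) after each conv
  activation of the chain nets and after the Inception module.  No batch
  normalization anywhere.
* The fc layer gets a ReLU (unstated in the source; the keras-era default
  for hidden layers).
* **Initialization**: fan-in-scaled normal draws (std `sqrt(2/fan_in)`),
  seeded; all substreams (init, dropout, batch order, folds, cohort) spawn
  from named children of one seed, making cohort→training→evaluation
  bit-reproducible.
* **Loss**: categorical cross-entropy on the softmax outputs; constant
  learning rate (only the initial rate and epoch count are specified
  upstream).
* **One-view fusion**: per-view softmax outputs are averaged (the upstream
  fusion rule is unstated); variant 2 scales channel widths by `1/√3` to
  match the multi-view parameter budget.
* Parameter accounting: totals include biases; `conv_params` and
  `softmax_params` exclude biases for the `R_p` ratio; `R_f` is the input
  channel count of the first conv layer (3 for multi-view, 1 per one-view
  sub-network).

## Training and evaluation

Defaults: lr 0.001, 50 epochs, batch 16, momentum 0.9, weight decay
5·10⁻⁴, dropout 0.5.  Cross-validation is patient-level: patients are
randomly partitioned into k folds differing in size by at most one (96
patients at k = 10 → six folds of 10, four of 9), every sample inherits its
lesion's patient, so augmented copies cannot leak across the split.
Fold metrics are averaged weighted by validation-sample proportion; the
whole k-fold loop is repeated (default 5×) with fresh plans and the final
figure is the unweighted mean over repeats (the same weighting is applied
to sensitivity/specificity/AUC as to the error rate).  Validation sets
include augmented copies.  The ternary task reports the error rate only;
the binary positive class is *malignant*, ROC scores are the malignant
softmax probability, and AUC (computed via scikit-learn's threshold sweep)
equals the Mann–Whitney pairwise statistic, which an independent oracle
test enforces.

## Synthetic cohorts

The generator emulates a diagnostic-subset cohort: per-patient nodule
stacks (slice counts uniform on {3..12}, exercising both the padding and
the selection branch), one diagnosis class per patient, intensities on an
arbitrary [0, 1] scale with additive Gaussian noise.  Class geometry:
benign = one smooth Gaussian ellipsoid; primary = an ellipsoid with an
angularly lobed (spiculated) margin; metastatic = 2–4 small offset blobs.
Default layout is 29/25/42 patients with ~6.4/6.8/10 lesions each
(~186/169/421 lesions in expectation).  The `separation` knob sets how
strongly the classes differ ("easy": distinct radii/contrasts, noise sd
0.05; "hard": similar radii, weak lobes, noise sd ≥ 0.12).

What passing tests show — and what they do not: the synthetic classes are
separable by size, contrast and margin statistics on a clean background,
so success here validates the *pipeline* (shapes, labeling, leakage-free
folds, optimization) rather than clinical discrimination performance;
real-CT error rates require the real cohort and are out of scope.  The
end-to-end checks therefore use scaled-down conditions chosen once: the
cross-validation acceptance run uses ~60 patients (30 benign / 15 primary
/ 15 metastatic, ~3.3 lesions each ≈ 200 lesions), reduced augmentation
(120° interval, 3 copies per lesion), CNN1 for 10 epochs, 2 folds, and
asserts the error is below 0.25 against a 0.5 chance baseline; unit tests
use 6×12×12 volumes.

## Numerical notes and limitations

* float32 arithmetic throughout training; conv forward/backward are im2col
  GEMMs with a col2im scatter for input gradients; the input layer skips
  its (unneeded) input gradient.
* Max-pool gradients split ties evenly among tied window maxima.
* Non-overlapping pooling only (stride = window), which is all the
  networks use; trailing remainders are dropped (floor semantics).
* No GPU path; the chain nets' fc layer dominates their parameter count
  (CNN1 ≈ 4.8M), which is why full-scale 50-epoch 10-fold × 5-repeat runs
  are long on CPU — the library supports them, the shipped checks scale
  down instead.
* Out-of-plane (3D) rotations, nodule detection/segmentation, and LIDC XML
  annotation parsing are out of scope.
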