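# mvcnn3d — 3D multi-view CNNs for lung-nodule classification

`mvcnn3d` is a research library for classifying pulmonary nodules on
thoracic CT as benign vs. malignant (binary task) or benign vs. primary
malignant vs. metastatic malignant (ternary task) with **3D multi-view
convolutional networks**.  It implements the full pipeline:

1. **Volume preparation** — every nodule, given as an ordered stack of
   axial slices with an in-slice center, is standardized to a
   `6 × 50 × 50 × K` tensor: a balanced 6-slice selection
   (`{1, n} ∪ {1 + round((n−1)k/5), k = 1..4}`, zero-padding when `n < 6`),
   square crops of `K` view sizes (40/50/60 px) around the center, cubic
   spline resize to 50 × 50, and in-plane rotation augmentation on a fixed
   angle grid.  The *multi-view-one-network* strategy feeds all views to one
   network as channels; *one-view-one-network* ensembles are also provided.
2. **Networks** — pure-NumPy 3D CNNs with analytic backpropagation:
   * chain nets `m·(MaxP(ReLU(conv(x, w)))) + fc + softmax`, `m ∈ {0..3}`
     (Softmax, CNN1, CNN2, CNN3);
   * a 3D **Inception** net (one module; variant 1 with 1×1×1 / 3×3×3 /
     5×5×5 branches, variant 2 with each n×n×n filter factorized into
     1×1×n, 1×n×1, n×1×1), whose fully connected layer is replaced by a
     1×1×1 convolution (32 ch binary / 64 ch ternary) + 2×3×3 average pool;
   * a 3D **Inception-ResNet** whose residual branch is scaled by 0.1
     before the shortcut add.
3. **Training & evaluation** — mini-batch SGD (lr 0.001, momentum 0.9,
   weight decay 5·10⁻⁴, batch 16, dropout 0.5 / spatial dropout on conv
   maps), repeated **patient-level k-fold cross-validation** with
   validation-proportion-weighted averaging, and confusion-matrix metrics:
   sensitivity TP/(TP+FN), specificity TN/(TN+FP), error rate
   (FP+FN)/total, plus ROC/AUC for the binary task.
4. **Synthetic cohorts** — a generator of CT-like nodule stacks with
   class-dependent 3D intensity structure (smooth ellipsoid / spiculated
   blob / multi-blob mixture) so everything above is testable with no
   dataset download.

There is no deep-learning framework dependency: the 3D convolution,
pooling, dropout and SGD machinery are implemented in NumPy (im2col GEMMs),
which keeps the package runnable on a single CPU.

## Worked example

```bash
python examples/count_parameters.py
```

prints, among other rows,

```
Inception1                  binary         47,000     28.3:1    3:1
Inception1                  ternary       148,927     30.0:1    3:1
```

i.e. the multi-view Inception1 nets have 0.47·10⁵ (binary) and 1.49·10⁵
(ternary) parameters; `R_p` is the conv:softmax weight ratio and `R_f = 3:1`
says each first-hidden-layer channel receives one filter per view.  A small
cross-validation demo:

```bash
python examples/cross_validate.py
```

```
41 lesions -> 82 samples after augmentation
CV error rate : 0.256  (chance baseline ~0.5)
sensitivity   : 0.879
specificity   : 0.639
AUC           : 0.888
```

on toy 6×12×12 volumes — already far from chance; full-size volumes and
more epochs (see the acceptance script below) drive the error below 1%.

A thin CLI wraps the same library end to end:

```bash
mvcnn3d simulate --out cohort/ --patients 29,25,42 --seed 0
mvcnn3d prepare  --manifest cohort/manifest.csv --out samples.npz \
                 --task binary --augment 'benign=9,malignant=30'
mvcnn3d cv       --data samples.npz --arch inception1 --folds 10 \
                 --repeats 5 --out results/
mvcnn3d count-params --arch inception1 --task ternary
```

Real data enters through the same manifest schema (per-slice rows with
`patient_id, nodule_id, center_row, center_col, nodule_diag, patient_diag`
and `slice_path` or `volume_path`+`slice_index`; DICOM and NIfTI are both
read).

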