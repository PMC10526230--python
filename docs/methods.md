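# Methods

## The problem

Radiologists grade pulmonary nodules on interpretable ordinal scales —
margin sharpness, sphericity, subtlety (conspicuity), internal texture,
calcification pattern — and these semantic attributes carry most of the
evidence for a benign/malignant call.  A hierarchical multi-task network
makes that reasoning explicit: five branch networks each predict one
binary semantic attribute from a 3D intensity patch, and a final
disease-level head predicts malignancy from the concatenated branch
feature vectors *and* the five semantic probabilities.  The package
implements two variants sharing one code path:

* the **shared-extractor baseline** (`arch="hscnn"`): one 3D
  convolutional feature extractor feeds all five semantic heads
  (2 conv blocks by default);
* the **five-extractor network** (`arch="hsnet"`): one dedicated, deeper
  extractor per semantic task (3 conv blocks by default), with branch
  features tapped at the activation output so that dropout never
  perturbs the representation handed to the fusion head.

## Label model

Each 5-level ordinal attribute binarizes as levels 1–3 → 0 and 4–5 → 1.
Calcification is 6-level: levels 1–5 are distinct calcification
patterns (popcorn, laminated, solid, non-central, central) and map to 0;
level 6 ("absent") maps to 1 — the positive class is *absence* of
calcification, which is the malignancy-relevant state.

## Network and training recipe

Each conv block is Conv3x3x3 → BatchNorm → ReLU → pool(2) → Dropout,
with max pooling by default and average pooling available per config
(average pooling preserves mean-intensity information at the cost of
peak sensitivity).  Default widths are 8/16/32 filters, a 32-unit
branch feature vector and a 64-unit malignancy hidden layer; every
width is a config field.  These sizes were chosen so the whole recipe —
implemented as a from-scratch NumPy/Numba engine with hand-written
backward passes — trains on a single CPU core at interactive time
scales; the scientific claims the package tests are structural
(separate extractors, deeper branches, activation-layer feature tap,
probability fusion), not tied to any particular layer width.  Dropout
defaults to 0 (off): with batch normalization plus 6× symmetry
augmentation the networks are already regularized, and at desk-scale
sample sizes dropout rates of 0.1–0.3 measurably stall optimization
before the shape- and contrast-sensitive heads start learning.  The
rate remains a config field for larger-data regimes.

The training loop supports the full published recipe:

* **multi-task loss** — mean binary cross-entropy per head, weighted sum
  (uniform weights by default);
* **optimizers** — SGD with momentum 0.9 (default), Adam, RMSProp;
* **cyclical learning rate** — triangular wave between `base_lr` and
  `max_lr` (defaults 2e-3 and 8e-3) with a half-cycle of two epochs of
  iterations and no amplitude decay;
* **stochastic weight averaging** — end-of-epoch snapshots from
  `swa_start_epoch` (default 0.75 × epochs) folded into a running mean
  W ← (W·n + W_epoch)/(n+1); batch-norm statistics are recomputed over
  the training set (dropout disabled) before the averaged model is
  returned;
* **early stopping** — the returned weights are the end-of-epoch
  checkpoint with the highest validation malignancy-head accuracy.
  When SWA is enabled the averaged model is returned instead and the
  checkpoint trace is reported in the history; the two selection rules
  are not combined because evaluating the running average with fresh
  batch-norm statistics at every epoch would roughly double training
  cost.

Determinism contract: same platform, same seed, single-threaded →
identical history and weights.  Cross-platform bit-equality is not
promised.

## Synthetic nodule phantoms

The phantom generator renders cubic HU-like intensity patches
(default 32³, background N(−800, 50²)) in which each ordinal level
controls one image property through a monotone lookup table:

| attribute | render control | default table (levels 1→5) |
|---|---|---|
| sphericity | oblate aspect ratio | 3.0, 2.2, 1.6, 1.25, 1.0 |
| margin | edge blur sigma (voxels) | 2.5, 2.0, 1.5, 1.0, 0.5 |
| subtlety | shell contrast over background | 100, 200, 300, 450, 600 |
| texture | inner-core density | −600, −450, −300, −150, 50 |
| malignancy | size scale (voxels) / spike amplitude | 5.0→7.0 / 0→1.6 |
| calcification | inclusion pattern at +800 | popcorn, laminated, solid, non-central, central, absent |

The nodule is a two-zone oblate ellipsoid — inner core (normalized
radius ρ ≤ 0.6) at the texture density, outer shell at background +
contrast — with radial spikes whose count and amplitude grow with the
malignancy level, and calcification inclusions unless the pattern level
is "absent".  Size-like quantities are specified for the reference
32-voxel grid and rescale with `grid_size`.  Continuous parameters get
±10% multiplicative jitter within a level so adjacent levels overlap.

Two rendering choices matter and were set after inspecting what
information survives at this patch scale:

* **oblate rather than prolate ellipsoids** — a prolate shape is thin in
  two axes and at aspect ratio 3 its interior all but vanishes inside a
  32³ grid; the oblate form is thin in one axis only, which preserves an
  interior while realizing the same long/short moment ratio;
* **edge-localized blur** — the margin blur is blended in only within a
  band around the nodule boundary (Gaussian weight with width
  0.9 × sigma).  A global blur at sigma 2.5 voxels would erase the
  interior two-zone structure of small nodules entirely, collapsing the
  subtlety and texture signals that other heads must learn.

Every attribute is verifiably recoverable: a threshold classifier on a
single matched image statistic reaches AUC > 0.8 per attribute on 200
default-config samples.  The statistics are deliberately robust:
second-moment anisotropy of the segmented nodule (sphericity), the
90th-percentile boundary gradient normalized by peak excess (margin),
the median interior excess over background after one erosion with
hyperdense voxels excluded (subtlety — erosion drops the blur halo and
the exclusion keeps calcification from masquerading as contrast), the
median density of the deepest non-calcified voxels (texture), the
volume maximum (calcification) and the segmented volume (malignancy
via size).  This property is what the learning
demonstrations lean on: it guarantees the tasks are solvable before any
network enters the picture.

What the phantoms do **not** emulate: lung anatomy (vessels, airways,
pleural attachment), scanner physics (beam hardening, slice anisotropy),
inter-annotator label noise, or the class imbalance of clinical
cohorts (ordinal levels are uniform by default; priors are a config
field).  Passing results on phantoms therefore demonstrate that the
implementation learns and evaluates correctly, not that it would reach
any particular accuracy on clinical data.

## Evaluation statistics

* Confusion matrices at threshold 0.5, ties predicted positive.
* ROC-AUC in the Mann–Whitney form (midranks; ties count 1/2), checked
  in tests against exhaustive pair counting.
* Fold summaries report the mean with both standard-deviation
  conventions; the published four-fold tables use the population (÷n)
  convention, which is what `FoldSummary.format` prints.
* Paired t-test on per-fold metric differences: t = d̄/(s/√n), df = n−1,
  two-sided p, 95% CI from the t quantile.
* The two-classifier significance statistic
  Ps = |e1−e2| / √(q(1−q)(1/n1+1/n2)), q = (e1+e2)/2, with
  significance declared at Ps ≥ 1.96.  Error rates may be formed from
  accuracy or from 1 − AUC; the published comparison table is
  reproduced by the 1 − AUC reading with n1 = n2 = 1063.

## Cross-validation harness

Samples are split once into four folds (sizes within one of each other;
stratified on binarized malignancy by default) and rotated through the
fixed experiment plan: train on folds (2,3), validate on 4, test on 1,
then (3,4|1|2), (4,1|2|3), (1,2|3|4).  Training folds are expanded 6×
with cube symmetries (the original plus five distinct non-identity
elements of the 48-element transpose/flip group, sampled without
replacement per sample); validation and test folds are never expanded,
and the harness asserts id-level disjointness between (augmented)
training data and the test fold on every run.  The validation fold is
used for early-stopping checkpoint selection only.

## Numerical and engineering choices

* float32 weights and activations; float64 accumulation in
  batch-norm moment and reduction kernels.
* The convolution, batch-norm and their backward passes are compiled
  with Numba (row-vectorized, single-threaded); everything else is
  NumPy.  First use per process pays a one-time JIT compilation cost.
* Max-pool gradient goes to the earliest element on ties.
* Probabilities are clipped to (1e-7, 1−1e-7) inside the loss.
* Degenerate inputs raise typed errors rather than returning NaN:
  single-class AUC, zero-variance paired t, pooled error rate 0 or 1 in
  the Ps test, nodules that cannot fit the grid.

## Scale of the bundled demonstrations

The learning demonstration in the acceptance test suite trains the
default five-extractor network on a few hundred phantoms for tens of
epochs — problem sizes chosen so the whole suite runs on one CPU core
in well under half an hour while still exercising the full recipe
(augmentation, CLR, SWA, early stopping, both architectures).  The
published experiments ran 300 epochs on 4252 LIDC-derived nodule crops;
reproducing those absolute accuracies is explicitly out of scope.
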