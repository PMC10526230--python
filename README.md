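# hsnet3d

Hierarchical multi-task 3D convolutional networks for lung-nodule
characterization, with a synthetic nodule phantom generator, a four-fold
cross-validation harness, and the classifier-comparison statistics used
to decide whether one model is significantly better than another.

## Who this is for

Researchers in computer-aided diagnosis (CADx) who want an
interpretable nodule classifier: instead of predicting malignancy
directly from voxels, the network first predicts five radiologist
semantic attributes of a nodule patch — **calcification** (pattern
present vs absent), **margin** (poorly defined vs sharp), **sphericity**
(lesser vs high roundness), **subtlety** (poor vs high contrast against
surroundings) and **texture** (non-solid vs solid) — and then fuses the
per-attribute feature vectors and probabilities into a benign/malignant
prediction.  The malignancy call therefore comes with the semantic
evidence that supports it.

Two architectures share one code path:

* `arch="hscnn"` — baseline: one shared 3D feature extractor feeds all
  five semantic heads;
* `arch="hsnet"` — one dedicated, deeper extractor per attribute, with
  branch features tapped at the activation layer (before dropout).

The training recipe is the published one: multi-task binary
cross-entropy, SGD with a triangular cyclical learning rate (CLR),
stochastic weight averaging (SWA, Eq. W ← (W·n + W_epoch)/(n+1)),
early stopping on validation malignancy accuracy, and 6× training-set
expansion by random axis transposition/flipping (the 48-element cube
symmetry group).  Everything runs on plain CPU: the 3D CNN engine is
written in NumPy with Numba-compiled convolution kernels — no deep
learning framework required.

## Worked example

```python
import numpy as np
from hsnet3d import (PhantomConfig, generate_arrays, expand_training_set,
                     HSNetClassifier, evaluate, roc_auc)

# 1. synthetic nodule patches whose appearance is controlled by the
#    semantic ordinal levels (see docs/methods.md for the tables)
X, table, y = generate_arrays(300, PhantomConfig(), seed=42)
X_train, y_train, X_test, y_test = X[:150], y[:150], X[150:], y[150:]

# 2. 6x expansion of the training set by cube symmetries
aug = expand_training_set(X_train, y_train, factor=6, seed=1)

# 3. five-extractor network, SGD-CLR + SWA
clf = HSNetClassifier(arch="hsnet", epochs=14, swa_start_epoch=11,
                      batch_size=16, random_state=1,
                      validation_fraction=0.08).fit(aug.volumes, aug.labels)

# 4. six-head evaluation on untouched test nodules
report = evaluate(clf, X_test, y_test)
for feat, m in report.metrics.items():
    print(f"{feat:14s} acc={m['accuracy']:.3f} auc={m['auc']:.3f}")
```

which prints (single CPU core, ~15 minutes):

```
calcification  acc=0.980 auc=0.998
margin         acc=0.873 auc=0.951
sphericity     acc=0.887 auc=0.966
subtlety       acc=0.693 auc=0.849
texture        acc=0.853 auc=0.931
malignancy     acc=0.780 auc=0.932
```

Each row is one binary head: accuracy at threshold 0.5 and ROC-AUC
(probability that a random positive nodule outscores a random negative
one).  The malignancy row is the disease-level prediction fused from the
five semantic branches.  AUC is the primary figure of merit here —
after stochastic weight averaging the probability scale can shift, so
accuracy at the fixed 0.5 threshold may lag the ranking quality.

Comparing two classifiers uses the statistics module: `paired_t` runs
the four-fold paired t-test on per-fold AUC differences, and `ps_test`
computes the error-rate significance statistic
Ps = |e1−e2| / √(q(1−q)(1/n1+1/n2)), q = (e1+e2)/2, significant at
Ps ≥ 1.96:

```python
from hsnet3d import ps_test
ps_test(1 - 0.930, 1 - 0.994, 1063, 1063).ps   # -> 7.717
```

A command-line interface mirrors the library:
`hsnet3d generate | train | crossval | evaluate | compare`.

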