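"""Four-fold cross-validation harness and model-comparison orchestration.

The dataset is split once into four folds of (near-)equal size, then
rotated through four experiments: train on two folds, early-stop on a
validation fold, test on the remaining untouched fold.  Training folds
are expanded with cube-symmetry augmentation; validation and test folds
never are.  When a baseline architecture is supplied, the harness also
runs the per-label paired t-test on the per-fold AUCs and the Ps
error-rate significance test on the mean AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .augment3d import expand_training_set
from .estimator import HSNetClassifier
from .evalstats import (evaluate, fold_summary, paired_t, ps_test,
                        DegenerateStatError)
from .semantics import ALL_FEATURES


@dataclass(frozen=True)
class FoldSplit:
    """Partition of sample ids into folds numbered 1..k."""

    assignment: dict            # id -> fold number
    k: int
    seed: int
    stratified: bool

    def members(self, fold: int) -> list:
        return [i for i, f in self.assignment.items() if f == fold]


@dataclass(frozen=True)
class Rotation:
    train_folds: tuple
    val_fold: int
    test_fold: int


def make_folds(ids, k: int = 4, seed: int = 0, stratify_on=None) -> FoldSplit:
    """Seeded split into k folds whose sizes differ by at most one.

    ``stratify_on`` may be a binary label per id (same order), typically
    binarized malignancy, to balance classes across folds.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(ids) < k:
        raise ValueError("fewer samples than folds")
    idx = np.arange(len(ids))
    if stratify_on is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        parts = splitter.split(idx, np.asarray(stratify_on))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        parts = splitter.split(idx)
    assignment = {}
    for fold, (_, members) in enumerate(parts, start=1):
        for m in members:
            assignment[ids[m]] = fold
    return FoldSplit(assignment=assignment, k=k, seed=seed,
                     stratified=stratify_on is not None)


def plan_rotations(split: FoldSplit) -> list:
    """The four train/validation/test rotations of the 4-fold design:
    (2+3 | 4 | 1), (3+4 | 1 | 2), (4+1 | 2 | 3), (1+2 | 3 | 4)."""
    if split.k != 4:
        raise ValueError("the rotation plan is defined for exactly 4 folds")
    return [
        Rotation((2, 3), 4, 1),
        Rotation((3, 4), 1, 2),
        Rotation((4, 1), 2, 3),
        Rotation((1, 2), 3, 4),
    ]


@dataclass
class CrossvalResult:
    fold_split: FoldSplit
    rotations: list
    reports: list                      # MetricReport per rotation
    summary: dict = field(default_factory=dict)
    baseline_reports: list | None = None
    comparison: dict | None = None

    def as_dict(self) -> dict:
        out = {
            "folds": {str(k): v for k, v in self.fold_split.assignment.items()},
            "rotations": [vars(r) for r in self.rotations],
            "reports": [r.as_dict() for r in self.reports],
            "summary": self.summary,
        }
        if self.comparison is not None:
            out["comparison"] = self.comparison
            out["baseline_reports"] = [r.as_dict() for r in self.baseline_reports]
        return out


def _subset(X, y, ids, fold_ids):
    wanted = set(fold_ids)
    mask = np.array([i in wanted for i in ids])
    return X[mask], y[mask], [i for i, m in zip(ids, mask) if m]


def _summarize(reports) -> dict:
    summary = {}
    for feat in ALL_FEATURES:
        summary[feat] = {}
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            vals = [r.metrics[feat][metric] for r in reports]
            try:
                fs = fold_summary(vals)
                summary[feat][metric] = {
                    "values": list(fs.values), "mean": fs.mean,
                    "sample_sd": fs.sample_sd, "population_sd": fs.population_sd,
                }
            except DegenerateStatError:
                summary[feat][metric] = {"values": vals}
    return summary


def compare_models(reports_a, reports_b, test_sizes) -> dict:
    """Per-label paired t-test on per-fold AUCs plus the Ps test on mean AUCs.

    Model A is the candidate, model B the baseline; differences are A - B
    and Ps uses error rates e = 1 - mean AUC with the per-model mean test
    size.
    """
    n = int(round(float(np.mean(test_sizes))))
    out = {}
    for feat in ALL_FEATURES:
        auc_a = [r.metrics[feat]["auc"] for r in reports_a]
        auc_b = [r.metrics[feat]["auc"] for r in reports_b]
        entry = {"auc_a": auc_a, "auc_b": auc_b}
        try:
            entry["paired_t"] = paired_t(np.subtract(auc_a, auc_b)).as_dict()
        except DegenerateStatError as err:
            entry["paired_t"] = {"error": str(err)}
        try:
            entry["ps"] = ps_test(1.0 - float(np.mean(auc_a)),
                                  1.0 - float(np.mean(auc_b)), n, n).as_dict()
        except DegenerateStatError as err:
            entry["ps"] = {"error": str(err)}
        out[feat] = entry
    return out


def run_crossval(X, y, ids=None, model_params=None, baseline_params=None,
                 k: int = 4, augment_factor: int = 6, seed: int = 0,
                 stratify: bool = True, rotations=None) -> CrossvalResult:
    """Full rotation experiment; optionally against a baseline architecture.

    ``model_params`` / ``baseline_params`` are keyword dicts for
    :class:`HSNetClassifier`; the baseline defaults to the shared-extractor
    variant of the same training recipe.  ``rotations`` may name a subset
    of rotation indices (0-based) to run.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    split = make_folds(ids, k=k, seed=seed,
                       stratify_on=y[:, -1] if stratify else None)
    plan = plan_rotations(split)
    if rotations is not None:
        plan = [plan[i] for i in rotations]

    model_params = dict(model_params or {})
    model_params.setdefault("random_state", seed)

    def run_arch(params):
        reports, sizes = [], []
        for rot in plan:
            train_ids = split.members(rot.train_folds[0]) + split.members(rot.train_folds[1])
            x_tr, y_tr, id_tr = _subset(X, y, ids, train_ids)
            x_va, y_va, _ = _subset(X, y, ids, split.members(rot.val_fold))
            x_te, y_te, id_te = _subset(X, y, ids, split.members(rot.test_fold))
            aug = expand_training_set(x_tr, y_tr, factor=augment_factor,
                                      seed=seed, ids=id_tr)
            leaked = set(aug.source_ids) & set(id_te)
            if leaked:
                raise RuntimeError(f"train/test leakage: {sorted(leaked)[:3]} ...")
            est = HSNetClassifier(**params)
            est.fit(aug.volumes, aug.labels, X_val=x_va, y_val=y_va)
            reports.append(evaluate(est, x_te, y_te, ids=id_te))
            sizes.append(len(id_te))
        return reports, sizes

    reports, sizes = run_arch(model_params)
    result = CrossvalResult(fold_split=split, rotations=plan, reports=reports,
                            summary=_summarize(reports))
    if baseline_params is not None:
        baseline_params = dict(baseline_params)
        baseline_params.setdefault("arch", "hscnn")
        baseline_params.setdefault("random_state", seed)
        base_reports, _ = run_arch(baseline_params)
        result.baseline_reports = base_reports
        result.comparison = compare_models(reports, base_reports, sizes)
    return result
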