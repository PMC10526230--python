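"""Classification metrics and classifier-comparison statistics.

Covers the evaluation toolkit for the six binary nodule tasks: confusion
matrices, accuracy / sensitivity / specificity, ROC-AUC in the
Mann-Whitney formulation (ties count 0.5), per-fold summaries under both
standard-deviation conventions, the paired-sample t-test used to compare
two models' per-fold AUCs, and the two-classifier error-rate significance
statistic

    Ps = |e1 - e2| / sqrt( q (1 - q) (1/n1 + 1/n2) ),   q = (e1 + e2) / 2,

where e1, e2 are the two models' error rates on test sets of sizes n1, n2.
Ps >= 1.96 declares a significant performance difference at 95% confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .semantics import ALL_FEATURES

#: Significance cutoff for the Ps statistic (two-sided 95% normal quantile).
PS_CUTOFF = 1.96


class DegenerateStatError(ValueError):
    """A statistic is undefined for the given input (zero variance, one class...)."""


# ---------------------------------------------------------------------------
# Confusion matrix and threshold metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        """True-positive rate among actual positives."""
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        """True-negative rate among actual negatives."""
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionMatrix:
    """Threshold scores and cross-tabulate against binary labels.

    A score >= threshold predicts positive (ties go to the positive class).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if scores.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the probability that a uniformly random positive sample outscores
    a uniformly random negative one, with score ties counted as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateStatError("AUC is undefined when only one class is present")
    ranks = stats.rankdata(scores)  # midranks handle ties as 0.5
    rank_sum_pos = float(ranks[labels == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# Fold summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSummary:
    """Mean of a per-fold metric plus both SD conventions.

    ``sample_sd`` uses the n-1 denominator; ``population_sd`` uses n.  The
    published fold tables quote the population convention, so that is what
    :meth:`format` prints.
    """

    values: tuple
    mean: float
    sample_sd: float
    population_sd: float

    def format(self, digits: int = 3) -> str:
        return f"{self.mean:.4f} ({self.population_sd:.{digits}f})"


def fold_summary(values) -> FoldSummary:
    values = tuple(float(v) for v in values)
    if len(values) < 2:
        raise DegenerateStatError("need at least 2 fold values for an SD")
    arr = np.asarray(values)
    return FoldSummary(
        values=values,
        mean=float(arr.mean()),
        sample_sd=float(arr.std(ddof=1)),
        population_sd=float(arr.std(ddof=0)),
    )


# ---------------------------------------------------------------------------
# Paired t-test on per-fold metric differences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    mean_diff: float
    t_statistic: float
    df: int
    p_two_sided: float
    ci95: tuple

    def as_dict(self) -> dict:
        return asdict(self)


def paired_t(differences) -> PairedTResult:
    """Paired-sample t-test on per-fold metric differences (model A - model B).

    t = mean / (s / sqrt(n)) with s the sample SD (n-1); two-sided p from
    Student's t with n-1 degrees of freedom; 95% CI = mean +/- t_{0.975, n-1}
    * s / sqrt(n).
    """
    d = np.asarray([float(v) for v in differences])
    n = d.size
    if n < 2:
        raise DegenerateStatError("need at least 2 paired differences")
    s = d.std(ddof=1)
    if s == 0:
        raise DegenerateStatError("paired t-test is degenerate: zero variance")
    mean = float(d.mean())
    se = s / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.975, df)) * se
    return PairedTResult(
        mean_diff=mean,
        t_statistic=float(t),
        df=df,
        p_two_sided=p,
        ci95=(mean - half, mean + half),
    )


# ---------------------------------------------------------------------------
# Two-classifier significance statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsResult:
    e1: float
    e2: float
    q: float
    n1: int
    n2: int
    ps: float

    @property
    def significant(self) -> bool:
        return self.ps >= PS_CUTOFF

    def as_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def ps_test(e1: float, e2: float, n1: int, n2: int) -> PsResult:
    """Two-proportion significance statistic for two classifiers' error rates.

    Symmetric in the two models; zero iff the error rates coincide.  Error
    rates may come from accuracy (1 - acc) or, when AUC is the figure of
    merit, from 1 - AUC.
    """
    if not (0.0 <= e1 <= 1.0 and 0.0 <= e2 <= 1.0):
        raise ValueError("error rates must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("test-set sizes must be >= 1")
    q = (e1 + e2) / 2.0
    if q in (0.0, 1.0):
        raise DegenerateStatError("Ps is undefined when the pooled error rate is 0 or 1")
    ps = abs(e1 - e2) / math.sqrt(q * (1.0 - q) * (1.0 / n1 + 1.0 / n2))
    return PsResult(e1=e1, e2=e2, q=q, n1=int(n1), n2=int(n2), ps=float(ps))


# ---------------------------------------------------------------------------
# Whole-model evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-attribute metrics for one evaluated test set."""

    metrics: dict = field(default_factory=dict)          # feature -> dict
    confusions: dict = field(default_factory=dict)       # feature -> ConfusionMatrix
    predictions: pd.DataFrame | None = None              # per-sample table
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "metrics": self.metrics,
            "confusions": {k: v.as_dict() for k, v in self.confusions.items()},
        }


def evaluate_scores(scores: np.ndarray, labels: np.ndarray,
                    ids=None, threshold: float = 0.5,
                    features=ALL_FEATURES) -> MetricReport:
    """Build a MetricReport from per-sample head scores and binary labels.

    ``scores`` and ``labels`` are (n_samples, n_features) arrays in the
    canonical feature order.  The per-sample prediction table lists, per
    nodule, the actual and predicted binary label for every attribute.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have matching shapes")
    if scores.ndim != 2 or scores.shape[1] != len(features):
        raise ValueError(f"expected (n, {len(features)}) arrays")
    report = MetricReport(threshold=threshold)
    rows = {"id": ids if ids is not None else np.arange(scores.shape[0])}
    for j, feat in enumerate(features):
        cm = confusion(scores[:, j], labels[:, j], threshold)
        entry = {
            "accuracy": cm.accuracy,
            "sensitivity": cm.sensitivity,
            "specificity": cm.specificity,
        }
        try:
            entry["auc"] = roc_auc(scores[:, j], labels[:, j])
        except DegenerateStatError:
            entry["auc"] = float("nan")
        report.confusions[feat] = cm
        report.metrics[feat] = entry
        rows[feat + "_actual"] = labels[:, j].astype(int)
        rows[feat + "_predicted"] = (scores[:, j] >= threshold).astype(int)
        rows[feat + "_score"] = scores[:, j]
    report.predictions = pd.DataFrame(rows)
    return report


def evaluate(model, volumes: np.ndarray, labels: np.ndarray,
             ids=None, threshold: float = 0.5) -> MetricReport:
    """Run a fitted model on a labeled test set and report all six tasks.

    ``model`` is anything with a ``predict_proba(volumes) -> (n, 6)`` method
    returning head probabilities in canonical feature order.
    """
    scores = model.predict_proba(volumes)
    return evaluate_scores(scores, labels, ids=ids, threshold=threshold)


def roc_points(scores, labels) -> pd.DataFrame:
    """FPR/TPR pairs over all score thresholds, for ROC plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
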