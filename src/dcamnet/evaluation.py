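"""Split protocols, metrics, fold statistics, and secondary analyses.

Two evaluation protocols are provided.  The *subject-mixed* protocol splits
at the segment level with stratified random sampling, so one subject's
epochs may land on both sides — an upper-bound estimate.  The
*leave-one-subject-out* (LOSO) protocol holds out each subject in turn,
eliminating within-subject leakage; it is the deployment-relevant test.
Fold-level comparisons use the paired t-test, the Wilcoxon signed-rank test
(exact null for n <= 25 folds), and the paired Cohen's d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split

__all__ = [
    "SplitPlan",
    "Fold",
    "ConfusionMatrix",
    "MetricsReport",
    "FoldResults",
    "StatTestResult",
    "make_subject_mixed_split",
    "make_loso_folds",
    "confusion_metrics",
    "aggregate_folds",
    "paired_fold_tests",
    "balanced_subject_subset",
    "resample_stability",
    "kernel_weight_summary",
]


@dataclass
class Fold:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    held_out: object = None  # subject id under LOSO


@dataclass
class SplitPlan:
    mode: str  # 'subject_mixed' | 'loso'
    folds: list[Fold]
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.folds:
            parts = np.concatenate([f.train_idx, f.val_idx, f.test_idx])
            if len(np.unique(parts)) != len(parts):
                raise ValueError("train/val/test indices overlap within a fold")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with the fatigued class as positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )


@dataclass
class MetricsReport:
    """Percentages in [0, 100]; NaN marks a metric with a zero denominator."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    error_rate: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("accuracy", "precision", "recall", "f1", "sensitivity", "specificity", "error_rate")
        }


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return 100.0 * num / den


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Standard binary metrics (percent); sensitivity = recall of the fatigued class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undef: list[str] = []
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", undef)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", undef)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", undef)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        undef.append("f1")
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        sensitivity=recall,
        specificity=specificity,
        error_rate=100.0 - accuracy,
        undefined=undef,
    )


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _carve_validation(train_idx, labels, val_fraction, seed):
    n_classes = len(np.unique(labels[train_idx]))
    n_val = int(round(len(train_idx) * val_fraction))
    if val_fraction <= 0 or n_val < n_classes:
        return train_idx, np.array([], dtype=int)
    tr, va = train_test_split(
        train_idx,
        test_size=val_fraction,
        stratify=labels[train_idx],
        random_state=seed,
    )
    return tr, va


def make_subject_mixed_split(
    labels,
    subjects=None,
    train_fraction: float = 0.7,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> SplitPlan:
    """Segment-level stratified split (same subject may occur on both sides).

    `val_fraction` of the *training* portion is further held out, stratified,
    for early stopping; the test set is never touched.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples in each of 2 classes")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    train_idx, val_idx = _carve_validation(train_idx, labels, val_fraction, seed)
    fold = Fold(np.sort(train_idx), np.sort(val_idx), np.sort(test_idx))
    return SplitPlan("subject_mixed", [fold], seed=seed)


def make_loso_folds(
    subjects, labels=None, val_fraction: float = 0.1, seed: int = 0
) -> SplitPlan:
    """One fold per subject: test = that subject, train = all others."""
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("LOSO requires at least 2 distinct subjects")
    labels = np.asarray(labels) if labels is not None else np.zeros(len(subjects), int)
    folds = []
    for s in uniq:
        test_idx = np.flatnonzero(subjects == s)
        rest = np.flatnonzero(subjects != s)
        if val_fraction > 0 and len(np.unique(labels[rest])) > 1:
            tr, va = _carve_validation(rest, labels, val_fraction, seed)
        else:
            tr, va = rest, np.array([], dtype=int)
        folds.append(Fold(np.sort(tr), np.sort(va), np.sort(test_idx), held_out=s))
    return SplitPlan("loso", folds, seed=seed)


# ---------------------------------------------------------------------------
# fold aggregation and statistics
# ---------------------------------------------------------------------------


@dataclass
class FoldResults:
    accuracies: np.ndarray  # percent, one per fold
    matrices: list[ConfusionMatrix]
    mean: float
    sd: float
    ci95: tuple[float, float]
    aggregate: ConfusionMatrix


def aggregate_folds(matrices: list[ConfusionMatrix]) -> FoldResults:
    """Unweighted fold mean/sd, normal-approximation 95% CI, summed matrix."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 folds")
    acc = np.array([confusion_metrics(m).accuracy for m in matrices])
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    half = 1.96 * sd / math.sqrt(len(acc))
    agg = matrices[0]
    for m in matrices[1:]:
        agg = agg + m
    return FoldResults(acc, list(matrices), mean, sd, (mean - half, mean + half), agg)


@dataclass
class StatTestResult:
    t_stat: float
    t_p: float
    wilcoxon_w: float
    wilcoxon_p: float
    cohens_d: float
    flags: list[str] = field(default_factory=list)


def paired_fold_tests(acc_a, acc_b) -> StatTestResult:
    """Paired comparison of two per-fold accuracy vectors (a vs b).

    Two-sided paired t-test; Wilcoxon signed-rank with zero differences
    dropped (exact null for n <= 25 folds, normal approximation with
    continuity correction above); Cohen's d = mean(diff) / sd(diff, ddof=1).
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or len(a) < 5:
        raise ValueError("need two equal-length fold vectors with n >= 5")
    diff = a - b
    flags: list[str] = []
    sd = diff.std(ddof=1)
    if sd == 0:
        flags.append("zero-variance differences: t and d undefined")
        t_stat = t_p = d = math.nan
    else:
        t_stat, t_p = stats.ttest_rel(a, b)
        d = float(diff.mean() / sd)
    nz = diff[diff != 0]
    if len(nz) == 0:
        flags.append("all differences zero: signed-rank undefined")
        w = w_p = math.nan
    else:
        method = "exact" if len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz) else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(
                a, b, zero_method="wilcox", alternative="two-sided",
                method=method, correction=(method == "approx"),
            )
        # report W as the sum of positive-difference ranks (T+)
        ranks = stats.rankdata(np.abs(nz))
        w, w_p = float(ranks[nz > 0].sum()), float(res.pvalue)
    return StatTestResult(float(t_stat), float(t_p), w, w_p, d, flags)


# ---------------------------------------------------------------------------
# secondary analyses
# ---------------------------------------------------------------------------


def balanced_subject_subset(
    labels, subjects, per_class: int, seed: int, classes=(0, 1)
) -> np.ndarray:
    """Indices of a balanced subset with (near-)equal per-subject representation.

    Per-subject quota is ``floor(per_class / n_subjects)`` per class; the
    remainder is filled by a seeded draw from the leftover samples.  Scales
    down (with a warning) when a class has fewer than `per_class` samples.
    """
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    rng = np.random.default_rng(seed)
    uniq = np.unique(subjects)
    chosen: list[np.ndarray] = []
    for cls in classes:
        avail = int(np.sum(labels == cls))
        target = per_class
        if avail < per_class:
            warnings.warn(
                f"class {cls}: only {avail} samples available, scaling subset "
                f"down from {per_class}",
                stacklevel=2,
            )
            target = avail
        quota = target // len(uniq)
        picked: list[np.ndarray] = []
        leftovers: list[np.ndarray] = []
        for s in uniq:
            pool = np.flatnonzero((labels == cls) & (subjects == s))
            pool = rng.permutation(pool)
            picked.append(pool[:quota])
            leftovers.append(pool[quota:])
        picked_arr = np.concatenate(picked)
        remainder = target - len(picked_arr)
        if remainder > 0:
            pool = rng.permutation(np.concatenate(leftovers))
            picked_arr = np.concatenate([picked_arr, pool[:remainder]])
        chosen.append(picked_arr)
    return np.sort(np.concatenate(chosen))


def resample_stability(
    X,
    y,
    subjects,
    fit_eval,
    per_class: int = 400,
    seeds=(100, 200, 300, 400, 500),
    train_fraction: float = 0.7,
) -> dict:
    """Repeat the subject-mixed experiment on independently drawn subsets.

    For each seed a balanced subset is drawn (equal per-subject
    representation), split stratified, and handed to `fit_eval(X_tr, y_tr,
    X_te, y_te, seed) -> accuracy-%`.  Returns per-seed accuracies plus their
    mean and standard deviation.
    """
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    accs = []
    for seed in seeds:
        sel = balanced_subject_subset(y, subjects, per_class, seed)
        plan = make_subject_mixed_split(
            y[sel], train_fraction=train_fraction, val_fraction=0.0, seed=seed
        )
        fold = plan.folds[0]
        tr, te = sel[fold.train_idx], sel[fold.test_idx]
        accs.append(float(fit_eval(X[tr], y[tr], X[te], y[te], seed)))
    accs_arr = np.array(accs)
    return {
        "per_seed": dict(zip(list(seeds), accs)),
        "mean": float(accs_arr.mean()),
        "sd": float(accs_arr.std(ddof=1)) if len(accs) > 1 else 0.0,
    }


def kernel_weight_summary(clf, X, y) -> dict:
    """Mean kernel-attention vector per class (each mean lies on the simplex)."""
    pi = clf.kernel_attention(X)
    y = np.asarray(y)
    return {cls: pi[y == cls].mean(axis=0) for cls in np.unique(y)}
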