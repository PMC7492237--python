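"""Repeated stratified cross-validation and the six performance metrics.

The evaluation protocol mirrors the small-cohort setting: k-fold (default 5)
cross-validation repeated over many iterations (default 50), each iteration
re-splitting the target cohort with a fresh seed.  Per iteration the per-fold
metrics are averaged; the mean and SD over iterations summarize performance.
Metrics: balanced accuracy (BA), sensitivity (Sen), specificity (Spe),
positive likelihood ratio (LR+), false positive rate (FPR) and AUC, with the
internal identities BA = (Sen + Spe)/2 and FPR = 100 - Spe holding exactly.
Two models are compared metric-wise by a two-sided t-test on the
iteration-level values (Welch by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import SubjectRecord

__all__ = [
    "MetricSet",
    "CVSummary",
    "ModelComparison",
    "confusion_metrics",
    "auc_score",
    "make_folds",
    "cross_validate",
    "compare_models",
    "round_half_up",
]

METRICS = ("balanced_accuracy", "sensitivity", "specificity", "lr_plus", "fpr", "auc")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Table-style display rounding: half-up, unlike banker's rounding."""
    if not np.isfinite(x):
        return x
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricSet:
    """One evaluation's metrics; percentages on the 0-100 scale, AUC in [0, 1]."""

    balanced_accuracy: float
    sensitivity: float
    specificity: float
    lr_plus: float
    fpr: float
    auc: float | None = None

    def display(self) -> dict:
        out = {
            "balanced_accuracy": round_half_up(self.balanced_accuracy, 1),
            "sensitivity": round_half_up(self.sensitivity, 1),
            "specificity": round_half_up(self.specificity, 1),
            "lr_plus": round_half_up(self.lr_plus, 1),
            "fpr": round_half_up(self.fpr, 1),
        }
        if self.auc is not None:
            out["auc"] = round_half_up(self.auc, 2)
        return out


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    """Sensitivity/specificity-derived metrics from hard binary predictions.

    LR+ is sensitivity / FPR, reported as +inf when FPR is zero.  Full
    precision is retained; :meth:`MetricSet.display` applies half-up
    rounding to one decimal.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) != len(y_pred):
        raise ValueError("prediction/label length mismatch")
    if y_true.min() == y_true.max():
        raise ValueError(
            "y_true contains a single class; sensitivity or specificity undefined"
        )
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sen = 100.0 * tp / (tp + fn)
    spe = 100.0 * tn / (tn + fp)
    fpr = 100.0 - spe
    lr_plus = sen / fpr if fpr > 0 else float("inf")
    return MetricSet((sen + spe) / 2.0, sen, spe, lr_plus, fpr)


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    y_true = np.asarray(y_true)
    if y_true.min() == y_true.max():
        raise ValueError("y_true contains a single class; AUC undefined")
    return float(roc_auc_score(y_true, scores))


def make_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (array of fold ids, sizes differing by <= 1).

    ``labels`` should be the rarest task's binary labels so its positives
    spread as evenly as possible.  Fewer positives than folds triggers a
    warning (some folds will then be single-class).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    n_pos = int(min(labels.sum(), n - labels.sum()))
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} minority samples for {k} folds; some folds will "
            "contain no minority sample",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    assignment = np.empty(n, dtype=int)
    for fold, (_tr, te) in enumerate(skf.split(np.zeros(n), labels)):
        assignment[te] = fold
    return assignment


def _random_folds(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold in range(k):
        assignment[order[fold::k]] = fold
    return assignment


@dataclass
class CVSummary:
    """Per-iteration, per-task metrics with mean/SD aggregation."""

    task_names: list[str]
    # values[iteration, task, metric] following METRICS order
    values: np.ndarray
    k: int
    iterations: int
    seeds: list[int]

    def mean(self, metric: str, task: str) -> float:
        return float(np.nanmean(self.values[:, self._t(task), self._m(metric)]))

    def sd(self, metric: str, task: str) -> float:
        return float(np.nanstd(self.values[:, self._t(task), self._m(metric)], ddof=1))

    def iteration_values(self, metric: str, task: str) -> np.ndarray:
        return self.values[:, self._t(task), self._m(metric)]

    def _t(self, task: str) -> int:
        return self.task_names.index(task)

    @staticmethod
    def _m(metric: str) -> int:
        return METRICS.index(metric)

    def summary_frame(self) -> pd.DataFrame:
        """Table-style 'mean ± SD' report, one row per task."""
        rows = {}
        for task in self.task_names:
            row = {}
            for metric in METRICS:
                nd = 2 if metric == "auc" else 1
                row[metric] = (
                    f"{round_half_up(self.mean(metric, task), nd)} ± "
                    f"{round_half_up(self.sd(metric, task), nd)}"
                )
            rows[task] = row
        return pd.DataFrame(rows).T


@dataclass
class ModelComparison:
    metric: str
    task: str
    values_a: np.ndarray
    values_b: np.ndarray
    t_statistic: float
    p_value: float


def cross_validate(
    records: list[SubjectRecord],
    fit_fn,
    predict_fn,
    task_names: list[str],
    k: int = 5,
    iterations: int = 50,
    seed: int = 0,
    stratify: bool = True,
    threshold: float = 0.5,
    pooled: bool = False,
) -> CVSummary:
    """Repeated k-fold cross-validation of a fit/predict pipeline.

    ``fit_fn(train_records, seed) -> model`` must fit every data-dependent
    transform (normalization, clinical encoding, network training) on the
    training records only; ``predict_fn(model, records) -> (m, C)`` returns
    positive-class probabilities.  Per iteration, per-fold metrics are
    averaged across folds (``pooled=True`` instead pools the out-of-fold
    predictions and scores them once); folds where a metric is undefined
    (single-class test labels) are skipped in the average.
    """
    Y = np.array([[r.labels[t] for t in task_names] for r in records], dtype=int)
    n, C = Y.shape
    rarest = int(np.argmin(np.minimum(Y.sum(0), n - Y.sum(0))))
    values = np.full((iterations, C, len(METRICS)), np.nan)
    seeds = [int(seed + it) for it in range(iterations)]
    for it, it_seed in enumerate(seeds):
        folds = (
            make_folds(Y[:, rarest], k, it_seed)
            if stratify
            else _random_folds(n, k, it_seed)
        )
        fold_metrics = np.full((k, C, len(METRICS)), np.nan)
        pooled_probs = np.full((n, C), np.nan)
        for fold in range(k):
            te = np.flatnonzero(folds == fold)
            tr = np.flatnonzero(folds != fold)
            model = fit_fn([records[i] for i in tr], it_seed * k + fold)
            probs = np.atleast_2d(predict_fn(model, [records[i] for i in te]))
            pooled_probs[te] = probs
            for c in range(C):
                y_te = Y[te, c]
                if y_te.min() == y_te.max():
                    continue
                ms = confusion_metrics(y_te, (probs[:, c] >= threshold).astype(int))
                ms.auc = auc_score(y_te, probs[:, c])
                fold_metrics[fold, c] = [getattr(ms, m) for m in METRICS]
        if pooled:
            for c in range(C):
                ms = confusion_metrics(
                    Y[:, c], (pooled_probs[:, c] >= threshold).astype(int)
                )
                ms.auc = auc_score(Y[:, c], pooled_probs[:, c])
                values[it, c] = [getattr(ms, m) for m in METRICS]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                values[it] = np.nanmean(fold_metrics, axis=0)
            # LR+ per iteration as ratio of averaged Sen and FPR: a single
            # zero-FPR fold would otherwise make the mean of ratios infinite
            lr_i, sen_i, fpr_i = (METRICS.index(m) for m in
                                  ("lr_plus", "sensitivity", "fpr"))
            for c in range(C):
                fpr_val = values[it, c, fpr_i]
                values[it, c, lr_i] = (
                    values[it, c, sen_i] / fpr_val if fpr_val > 0 else np.inf
                )
    return CVSummary(list(task_names), values, k, iterations, seeds)


def compare_models(
    a: CVSummary,
    b: CVSummary,
    metric: str,
    task: str,
    equal_var: bool = False,
) -> ModelComparison:
    """Two-sided t-test (Welch by default) on iteration-level metric values."""
    va = a.iteration_values(metric, task)
    vb = b.iteration_values(metric, task)
    if len(va) != len(vb):
        raise ValueError("summaries have different iteration counts")
    va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
    if np.std(va) < 1e-12 and np.std(vb) < 1e-12:
        if abs(np.mean(va) - np.mean(vb)) < 1e-12:
            t, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero variance in both samples with different means", stacklevel=2
            )
            t, p = float("inf") * np.sign(np.mean(va) - np.mean(vb)), 0.0
    else:
        t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
    return ModelComparison(metric, task, va, vb, float(t), float(p))
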