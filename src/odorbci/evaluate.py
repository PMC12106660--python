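"""Evaluation protocol: AUC-ROC, nested cross-validation with
validation-weighted ensembling, best-window selection, significance tests,
and the plain-K-fold optimism-bias demonstration.

Nested CV keeps an untouched outer test fold per iteration: model and
hyperparameter selection see only the inner folds, so the reported test
AUC is unbiased. Selecting on the same validation folds that are reported
(``plain_kfold_with_selection``) is deliberately leaky and exists to
demonstrate the optimism bias that nested CV removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RocCurve",
    "FoldPlan",
    "EvalResult",
    "TestResult",
    "auc_roc",
    "roc_curve",
    "make_fold_plan",
    "nested_cv",
    "ensemble_predict",
    "ensemble_weights",
    "best_window_select",
    "ttest_one_sample",
    "ttest_paired",
    "plain_kfold_with_selection",
]


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    trial scores higher, ties counted 1/2; identical to trapezoidal
    integration of the ROC curve but free of threshold-grid choices.
    A label-independent scorer gives 0.5 in expectation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray  # TP / (TP + FN)
    fpr: np.ndarray  # FP / (FP + TN)


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Explicit ROC sweep (TPR vs FPR over score thresholds)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = int((labels == 1).sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    keep = np.r_[np.diff(s) != 0, True]  # one point per distinct threshold
    tpr = np.r_[0.0, tp[keep] / n_pos]
    fpr = np.r_[0.0, fp[keep] / n_neg]
    thr = np.r_[np.inf, s[keep]]
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr)


@dataclass
class FoldPlan:
    """Nested-CV assignments: outer test folds partition all trials; inner
    folds partition each outer-train set. Stratified by class."""

    k_outer: int
    k_inner: int
    outer: list[tuple[np.ndarray, np.ndarray]]               # (train_idx, test_idx)
    inner: list[list[tuple[np.ndarray, np.ndarray]]]         # per outer: (train, val)
    seed: int = 0
    stratified: bool = True

    def validate(self, n_trials: int) -> None:
        all_test = np.concatenate([t for _, t in self.outer])
        if len(all_test) != n_trials or len(np.unique(all_test)) != n_trials:
            raise AssertionError("outer test folds must partition all trials")
        for (otr, ote), inner in zip(self.outer, self.inner):
            if np.intersect1d(otr, ote).size:
                raise AssertionError("outer train and test overlap")
            all_val = np.concatenate([v for _, v in inner])
            if sorted(all_val.tolist()) != sorted(otr.tolist()):
                raise AssertionError("inner validation folds must partition outer-train")
            for itr, iva in inner:
                if np.intersect1d(itr, ote).size or np.intersect1d(iva, ote).size:
                    raise AssertionError("outer test trials leaked into inner folds")


def make_fold_plan(labels: np.ndarray, k_outer: int = 10, k_inner: int = 10,
                   seed: int = 0) -> FoldPlan:
    labels = np.asarray(labels)
    counts = np.bincount(labels.astype(int))
    if counts.min() < k_outer:
        raise ValueError(
            f"each class needs >= k_outer={k_outer} trials, got {counts.tolist()}")
    outer_cv = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    outer, inner = [], []
    idx = np.arange(len(labels))
    for i, (otr, ote) in enumerate(outer_cv.split(idx, labels)):
        outer.append((otr, ote))
        inner_counts = np.bincount(labels[otr].astype(int))
        if inner_counts.min() < k_inner:
            raise ValueError(
                f"outer-train class counts {inner_counts.tolist()} too small "
                f"for k_inner={k_inner}")
        inner_cv = StratifiedKFold(n_splits=k_inner, shuffle=True,
                                   random_state=seed + 1000 + i)
        inner.append([(otr[itr], otr[iva])
                      for itr, iva in inner_cv.split(otr, labels[otr])])
    plan = FoldPlan(k_outer=k_outer, k_inner=k_inner, outer=outer, inner=inner,
                    seed=seed)
    plan.validate(len(labels))
    return plan


@dataclass
class EvalResult:
    fold_aucs: np.ndarray
    selected: list = field(default_factory=list)   # chosen hyperparameter per fold
    weights: list = field(default_factory=list)    # ensemble weights per fold
    inner_val_aucs: list = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def ensemble_weights(validation_aucs: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Validation-performance weights: proportional to max(AUC - 0.5, eps).

    Chance-level members get ~0 weight; if every member is at or below
    chance the ensemble degrades gracefully to a plain average."""
    w = np.maximum(np.asarray(validation_aucs, dtype=float) - 0.5, eps)
    return w / w.sum()


def ensemble_predict(models: list, validation_aucs: np.ndarray,
                     X: np.ndarray) -> np.ndarray:
    """Weighted mean of member probabilities."""
    if not models:
        raise ValueError("need at least one model")
    w = ensemble_weights(validation_aucs)
    probs = np.stack([_positive_proba(m, X) for m in models])
    return np.einsum("m,mn->n", w, probs)


def _positive_proba(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return np.asarray(model.predict(X), dtype=float)


def nested_cv(X: np.ndarray, y: np.ndarray, model_factory, plan: FoldPlan,
              param_grid: np.ndarray | list | None = None) -> EvalResult:
    """Leakage-free nested cross-validation with inner-fold ensembling.

    Per outer fold: if a hyperparameter grid is given, each candidate is
    scored by its mean inner-validation AUC and the best is chosen (ties
    toward the smaller value); k_inner models are then trained on the inner
    training splits with the chosen setting, ensembled with validation-AUC
    weights, and scored once on the untouched outer test fold.

    ``model_factory`` is a callable: ``model_factory(param) -> unfitted
    estimator`` with fit/predict_proba (param omitted when grid is None).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    plan.validate(len(y))
    fold_aucs, selected, weights, inner_aucs = [], [], [], []
    for (otr, ote), inner in zip(plan.outer, plan.inner):
        if param_grid is not None:
            cand_scores = []
            for p in param_grid:
                vals = [auc_roc(_positive_proba(
                            model_factory(p).fit(X[itr], y[itr]), X[iva]), y[iva])
                        for itr, iva in inner]
                cand_scores.append(np.mean(vals))
            best = int(np.argmax(cand_scores))  # argmax -> first (smallest) on ties
            param = param_grid[best]
        else:
            param = None
        models, vaucs = [], []
        for itr, iva in inner:
            m = model_factory(param) if param is not None else model_factory()
            if hasattr(m, "fit_with_val"):
                # nets use the inner validation fold for checkpoint selection
                m.fit_with_val(X[itr], y[itr], X[iva], y[iva])
            else:
                m.fit(X[itr], y[itr])
            models.append(m)
            vaucs.append(auc_roc(_positive_proba(m, X[iva]), y[iva]))
        vaucs = np.asarray(vaucs)
        scores = ensemble_predict(models, vaucs, X[ote])
        fold_aucs.append(auc_roc(scores, y[ote]))
        selected.append(param)
        weights.append(ensemble_weights(vaucs))
        inner_aucs.append(vaucs)
    return EvalResult(fold_aucs=np.asarray(fold_aucs), selected=selected,
                      weights=weights, inner_val_aucs=inner_aucs)


def best_window_select(per_window: dict) -> tuple:
    """Pick the analysis window with maximal validation AUC; report its test
    AUC. Ties break toward the earliest window start."""
    if not per_window:
        raise ValueError("need at least one window")
    items = sorted(per_window.items(), key=lambda kv: kv[0].t_start
                   if hasattr(kv[0], "t_start") else kv[0])
    best = max(items, key=lambda kv: kv[1][0])  # max is stable -> earliest wins ties
    return best[0], best[1][1]


@dataclass
class TestResult:
    t: float
    p: float
    df: int


def ttest_one_sample(values: np.ndarray, mu: float = 0.5,
                     alternative: str = "greater") -> TestResult:
    """One-sample t-test of mean(values) against mu (default: AUC vs chance)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need n >= 2")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero variance: t-test undefined")
    res = stats.ttest_1samp(values, mu, alternative=alternative)
    return TestResult(t=float(res.statistic), p=float(res.pvalue), df=len(values) - 1)


def ttest_paired(a: np.ndarray, b: np.ndarray,
                 alternative: str = "two-sided") -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two aligned samples with n >= 2")
    if np.std(a - b, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t-test undefined")
    res = stats.ttest_rel(a, b, alternative=alternative)
    return TestResult(t=float(res.statistic), p=float(res.pvalue), df=len(a) - 1)


def plain_kfold_with_selection(X: np.ndarray, y: np.ndarray, model_factory,
                               param_grid, k: int = 10, seed: int = 0) -> float:
    """Deliberately leaky protocol: hyperparameter selection and the
    reported score use the same validation folds (no held-out test split).

    Returns the best candidate's mean validation AUC — an optimistically
    biased estimate on null data, which nested CV avoids."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    means = []
    for p in param_grid:
        vals = [auc_roc(_positive_proba(model_factory(p).fit(X[tr], y[tr]), X[va]),
                        y[va]) for tr, va in folds]
        means.append(np.mean(vals))
    return float(np.max(means))
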