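"""Kernel-SVM classification with stratified CV and permutation testing.

Four SVM kernels (linear, polynomial, RBF, sigmoid) are evaluated with
stratified 5-fold cross-validation.  Inside each fold, features are
standardized on the training subjects, the selection strategy runs on
the training subjects only, an SVM (C=1, degree 3, gamma='scale') is
fitted on the selected columns, and the held-out fold is scored by
continuous decision values.  AUC uses the rank (Mann-Whitney)
formulation with ties contributing one half; accuracy, sensitivity and
specificity threshold the decision value at zero.  Reported metrics are
the means over folds.

The permutation test permutes labels over the whole cohort and re-runs
the *entire* pipeline — fold split, selection, fitting — per
permutation (the only unbiased variant); a faster "frozen" mode reuses
the observed selections for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import sklearn.metrics
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import select

__all__ = [
    "KERNELS",
    "auc_score",
    "roc_curve",
    "FoldMetrics",
    "ModelMetrics",
    "run_cv",
    "permutation_test",
]

KERNELS = ("linear", "poly", "rbf", "sigmoid")


def auc_score(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation (ties count 1/2)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(y: np.ndarray, scores: np.ndarray):
    """ROC points (fpr, tpr, thresholds) and the rank-based AUC."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = sklearn.metrics.roc_curve(y, scores)
    return fpr, tpr, thr, auc_score(y, scores)


def _threshold_metrics(y: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    pred = scores > 0
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
    }


@dataclass
class FoldMetrics:
    fold: int
    kernel: str
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_selected: int
    scores: np.ndarray
    y_true: np.ndarray


@dataclass
class ModelMetrics:
    """Fold-level and fold-mean metrics for one strategy across kernels."""

    strategy: str
    folds: list[FoldMetrics]
    selections: list[list[str]]
    flags: list[str] = field(default_factory=list)

    def mean(self) -> pd.DataFrame:
        rows = []
        for kernel in sorted({f.kernel for f in self.folds}):
            fs = [f for f in self.folds if f.kernel == kernel]
            rows.append(
                {
                    "strategy": self.strategy,
                    "kernel": kernel,
                    "AUC": float(np.mean([f.auc for f in fs])),
                    "accuracy": float(np.mean([f.accuracy for f in fs])),
                    "sensitivity": float(np.mean([f.sensitivity for f in fs])),
                    "specificity": float(np.mean([f.specificity for f in fs])),
                }
            )
        return pd.DataFrame(rows)

    def mean_auc(self, kernel: str) -> float:
        fs = [f for f in self.folds if f.kernel == kernel]
        if not fs:
            raise KeyError(f"no folds evaluated for kernel {kernel!r}")
        return float(np.mean([f.auc for f in fs]))


def _make_svm(kernel: str, svm_c: float, degree: int) -> SVC:
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; pick from {KERNELS}")
    return SVC(kernel=kernel, C=svm_c, degree=degree, gamma="scale")


def run_cv(
    x: pd.DataFrame,
    y: np.ndarray,
    strategy: str = "spearman",
    kernels: tuple = KERNELS,
    n_folds: int = 5,
    seed: int | None = 0,
    svm_c: float = 1.0,
    degree: int = 3,
    selection_kwargs: dict | None = None,
    precomputed_selections: list[list[str]] | None = None,
) -> ModelMetrics:
    """Stratified k-fold CV of the select-then-classify pipeline.

    Selection happens independently inside every training fold; test
    subjects never inform it.  ``precomputed_selections`` (one list per
    fold) bypasses selection — used only by the frozen permutation mode.
    """
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("run_cv needs exactly two classes")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: list[FoldMetrics] = []
    selections: list[list[str]] = []
    flags: list[str] = []
    for fold_i, (tr, te) in enumerate(skf.split(x, y)):
        y_tr, y_te = y[tr], y[te]
        if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
            raise ValueError(f"fold {fold_i} is degenerate (single class)")
        x_tr, x_te = x.iloc[tr], x.iloc[te]
        if precomputed_selections is not None:
            selected = precomputed_selections[fold_i]
        else:
            res = select(
                strategy,
                x_tr,
                y_tr,
                seed=None if seed is None else seed + fold_i,
                **(selection_kwargs or {}),
            )
            selected = res.selected
            flags.extend(f"fold {fold_i}: {f}" for f in res.flags)
        selections.append(list(selected))
        if not selected:
            flags.append(f"fold {fold_i}: empty selection, kernels skipped")
            continue
        scaler = StandardScaler().fit(x_tr[selected].to_numpy(float))
        z_tr = scaler.transform(x_tr[selected].to_numpy(float))
        z_te = scaler.transform(x_te[selected].to_numpy(float))
        for kernel in kernels:
            clf = _make_svm(kernel, svm_c, degree).fit(z_tr, y_tr)
            scores = clf.decision_function(z_te)
            m = _threshold_metrics(y_te, scores)
            folds.append(
                FoldMetrics(
                    fold=fold_i,
                    kernel=kernel,
                    auc=auc_score(y_te, scores),
                    n_selected=len(selected),
                    scores=scores,
                    y_true=y_te,
                    **m,
                )
            )
    return ModelMetrics(strategy=strategy, folds=folds, selections=selections, flags=flags)


def permutation_test(
    x: pd.DataFrame,
    y: np.ndarray,
    strategy: str,
    kernel: str,
    n_permutations: int = 5000,
    n_folds: int = 5,
    seed: int | None = 0,
    frozen_selection: bool = False,
    **cv_kwargs,
) -> dict:
    """Permutation p-value for one strategy/kernel's mean CV AUC.

    ``p = (1 + #{perm AUC >= observed AUC}) / (n_permutations + 1)``.
    With ``frozen_selection`` the observed per-fold selections are reused
    under permutation (biased but fast; comparison only).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = run_cv(
        x, y, strategy=strategy, kernels=(kernel,), n_folds=n_folds, seed=seed, **cv_kwargs
    )
    obs_auc = observed.mean_auc(kernel)
    rng = np.random.default_rng(seed)
    perm_aucs = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        mm = run_cv(
            x,
            y_perm,
            strategy=strategy,
            kernels=(kernel,),
            n_folds=n_folds,
            seed=seed,
            precomputed_selections=observed.selections if frozen_selection else None,
            **cv_kwargs,
        )
        perm_aucs[i] = mm.mean_auc(kernel)
    p = (1.0 + float(np.sum(perm_aucs >= obs_auc))) / (n_permutations + 1.0)
    return {
        "observed_auc": obs_auc,
        "p_value": p,
        "n_permutations": n_permutations,
        "perm_auc_mean": float(perm_aucs.mean()),
    }
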