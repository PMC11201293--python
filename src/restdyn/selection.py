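"""Feature-selection strategies, applied to training data only.

Three strategies mirror common radiomics practice:

* ``spearman`` — rank features by |Spearman rho| against the binary
  group label and keep the top 1% (``ceil``, minimum 1);
* ``lasso`` — L1-penalized logistic regression over a 100-point
  log-spaced penalty path, penalty chosen by inner 5-fold deviance;
  features with nonzero coefficients survive;
* ``t_lasso`` — unadjusted two-sided independent-samples t-test filter
  at p < 0.05, then the LASSO step on the survivors.

Selection must only ever see training subjects; cross-validation
wrappers (see :mod:`restdyn.classify`) call these per fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import l1_min_c

__all__ = [
    "SelectionResult",
    "select_spearman",
    "select_lasso",
    "select_t_lasso",
    "select",
    "STRATEGIES",
]

STRATEGIES = ("spearman", "lasso", "t_lasso")


@dataclass
class SelectionResult:
    strategy: str
    selected: list[str]
    scores: pd.Series  # per selected feature: rho, |coef| or p-value
    flags: list[str] = field(default_factory=list)


def _check_xy(x: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if x.shape[0] != y.size:
        raise ValueError("features and labels disagree on subject count")
    if np.unique(y).size < 2:
        raise ValueError("selection needs both classes present")
    return y


def spearman_rho(x: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Spearman rho of every column against ``y`` (constant columns -> 0)."""
    xr = scipy.stats.rankdata(x.to_numpy(float), axis=0)
    yr = scipy.stats.rankdata(np.asarray(y, float))
    xr = xr - xr.mean(axis=0)
    yr = yr - yr.mean()
    xs = np.sqrt((xr**2).sum(axis=0))
    ys = math.sqrt((yr**2).sum())
    denom = xs * ys
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (xr.T @ yr) / denom
    rho[denom == 0] = 0.0
    return pd.Series(rho, index=x.columns)


def select_spearman(
    x: pd.DataFrame, y: np.ndarray, top_frac: float = 0.01
) -> SelectionResult:
    """Keep the ``ceil(top_frac * P)`` features with the largest |rho|.

    Ties break by column order (stable sort), so 1% of 1,267 features is
    exactly 13 columns.
    """
    y = _check_xy(x, y)
    rho = spearman_rho(x, y)
    k = max(1, math.ceil(top_frac * x.shape[1]))
    order = np.argsort(-np.abs(rho.to_numpy()), kind="stable")[:k]
    sel = [x.columns[i] for i in sorted(order)]
    return SelectionResult("spearman", sel, rho.iloc[sorted(order)])


def select_lasso(
    x: pd.DataFrame,
    y: np.ndarray,
    n_lambda: int = 100,
    inner_folds: int = 5,
    seed: int | None = 0,
) -> SelectionResult:
    """Nonzero-coefficient features of an L1 logistic path.

    Features are standardized on the training data; the penalty is the
    deviance-best point of an ``n_lambda``-value log-spaced path under
    inner stratified CV.  If nothing survives at the chosen penalty, the
    weakest penalty that keeps at least one feature is used instead and
    the result is flagged.
    """
    y = _check_xy(x, y)
    flags: list[str] = []
    xs = StandardScaler().fit_transform(x.to_numpy(float))
    inner = StratifiedKFold(
        n_splits=min(inner_folds, int(np.bincount(y).min())),
        shuffle=True,
        random_state=None if seed is None else seed,
    )
    clf = LogisticRegressionCV(
        Cs=n_lambda,
        cv=inner,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        refit=True,
        random_state=None if seed is None else seed,
    )
    with warnings.catch_warnings():
        # sklearn 1.9 deprecation chatter about the future l1_ratios API
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(xs, y)
    coef = clf.coef_.ravel()
    if not np.any(coef != 0):
        flags.append("empty selection at the CV-chosen penalty; fell back")
        c_min = l1_min_c(xs, y, loss="log")
        fallback = LogisticRegression(
            penalty="l1", C=float(c_min) * 4.0, solver="liblinear", max_iter=2000,
            random_state=None if seed is None else seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            warnings.filterwarnings("ignore", message="Inconsistent values")
            fallback.fit(xs, y)
        coef = fallback.coef_.ravel()
        if not np.any(coef != 0):
            nz = np.argmax(np.abs(spearman_rho(x, y).to_numpy()))
            coef = np.zeros_like(coef)
            coef[nz] = 1.0
            flags.append("fallback penalty also empty; kept the top-rho feature")
    mask = coef != 0
    sel = [c for c, m in zip(x.columns, mask) if m]
    scores = pd.Series(coef[mask], index=sel)
    return SelectionResult("lasso", sel, scores, flags)


def select_t_lasso(
    x: pd.DataFrame,
    y: np.ndarray,
    p_cut: float = 0.05,
    equal_var: bool = True,
    n_lambda: int = 100,
    seed: int | None = 0,
) -> SelectionResult:
    """t-test filter (p < ``p_cut``, no multiplicity correction), then LASSO.

    ``equal_var=False`` switches to Welch's test.  An empty filter (or
    ``p_cut=0``) returns an empty, flagged selection.
    """
    y = _check_xy(x, y)
    if np.bincount(y).min() < 2:
        raise ValueError("need at least 2 subjects per class for the t-test")
    a = x.to_numpy(float)[y == 1]
    b = x.to_numpy(float)[y == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = scipy.stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    pvals = np.nan_to_num(pvals, nan=1.0)
    survivors = pvals < p_cut
    if not survivors.any():
        return SelectionResult(
            "t_lasso", [], pd.Series(dtype=float), ["no feature passed the t filter"]
        )
    sub = x.loc[:, survivors]
    inner = select_lasso(sub, y, n_lambda=n_lambda, seed=seed)
    scores = pd.Series(pvals[survivors], index=sub.columns).loc[inner.selected]
    return SelectionResult("t_lasso", inner.selected, scores, inner.flags)


def select(
    strategy: str, x: pd.DataFrame, y: np.ndarray, seed: int | None = 0, **kwargs
) -> SelectionResult:
    """Dispatch by strategy name ('spearman', 'lasso' or 't_lasso')."""
    if strategy == "spearman":
        return select_spearman(x, y, **kwargs)
    if strategy == "lasso":
        return select_lasso(x, y, seed=seed, **kwargs)
    if strategy == "t_lasso":
        return select_t_lasso(x, y, seed=seed, **kwargs)
    raise ValueError(f"unknown strategy {strategy!r}; pick one of {STRATEGIES}")
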