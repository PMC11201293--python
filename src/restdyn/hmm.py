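"""Group-level Gaussian HMM brain states: fractional occupancy and switching rate.

One K-state multivariate-Gaussian HMM (diagonal covariance by default)
is fitted on all subjects' z-scored node series concatenated, with
subject boundaries respected so no transition is learned across
subjects; each subject is then Viterbi-decoded under the shared model.
A per-subject fit would make occupancies incomparable across subjects,
which is why the model is shared.

From the decoded path of length T:

* fractional occupancy ``FO_k`` = fraction of the T time points spent in
  state k (sums to 1);
* switching rate ``SR`` = fraction of the T-1 consecutive pairs at which
  the state changes.

Fitting is EM (Baum-Welch) via :mod:`hmmlearn`, wrapped to add seeded
k-means restarts (best final log-likelihood kept), a full per-iteration
log-likelihood history (EM guarantees it is non-decreasing, and the
wrapper asserts it), and a covariance floor against degenerate states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM

__all__ = [
    "StatePath",
    "HMMResult",
    "standardize_series",
    "fit_hmm",
    "decode_states",
    "decode_cohort",
    "hmm_features",
    "extract_hmm_features",
]


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def _reset(self):
        super()._reset()
        self.full_history = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


@dataclass
class StatePath:
    """Decoded state sequence with its occupancy/switching summaries."""

    subject: str
    states: np.ndarray  # (T,), 0-based state indices
    fo: np.ndarray  # (K,), sums to 1
    sr: float  # transitions / (T - 1)


@dataclass
class HMMResult:
    """Fitted group HMM plus fitting diagnostics."""

    model: GaussianHMM
    n_states: int
    log_likelihood: float
    ll_history: list[float]
    restart_lls: list[float]
    flags: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        m = self.model
        payload = {
            "n_states": self.n_states,
            "startprob": m.startprob_.tolist(),
            "transmat": m.transmat_.tolist(),
            "means": m.means_.tolist(),
            "covars_diag": np.asarray([np.diag(c) for c in m.covars_]).tolist(),
            "log_likelihood": self.log_likelihood,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def standardize_series(x: np.ndarray) -> np.ndarray:
    """Z-score each column (node) within subject; constant columns -> 0."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    # a constant column's computed sd is O(eps * |mu|), not exactly 0
    const = sd <= 1e-12 * (np.abs(mu) + 1.0)
    z = (x - mu) / np.where(const, 1.0, sd)
    z[:, const] = 0.0
    return z


def _stack(series) -> tuple[np.ndarray, list[int], list[str]]:
    if isinstance(series, dict):
        items = list(series.items())
    else:
        items = [(f"sub-{i:03d}", s) for i, s in enumerate(series)]
    subjects = [k for k, _ in items]
    mats = [standardize_series(v) for _, v in items]
    lengths = [m.shape[0] for m in mats]
    return np.vstack(mats), lengths, subjects


def fit_hmm(
    series,
    n_states: int = 6,
    seed: int | None = 0,
    n_restarts: int = 3,
    max_iter: int = 500,
    covariance_type: str = "diag",
    min_covar: float = 1e-6,
) -> HMMResult:
    """Fit the group HMM on concatenated z-scored series.

    ``series`` is a dict ``subject -> (T, N)`` or a list of matrices.
    The first restart initializes state means by k-means; further
    restarts draw their initial means from randomly chosen observation
    frames (k-means is nearly deterministic across seeds, so reseeding
    it alone gives no real diversity and EM can stay trapped in a
    duplicated-state local optimum).  The restart with the best final
    log-likelihood wins.  Convergence is declared when the
    log-likelihood gain drops below ``1e-6`` per frame or after
    ``max_iter`` EM iterations.
    """
    x, lengths, _ = _stack(series)
    n_frames, n_dims = x.shape
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_frames <= n_states:
        raise ValueError("fewer frames than states")
    flags: list[str] = []
    n_free = n_states * (2 * n_dims + n_states)
    if n_frames < n_free:
        flags.append(
            f"only {n_frames} frames for ~{n_free} free parameters; "
            "estimates may be unstable"
        )
    tol = 1e-6 * n_frames  # ~relative tolerance on the per-frame likelihood
    ss = np.random.SeedSequence(seed)
    best: HMMResult | None = None
    restart_lls: list[float] = []
    for restart_i, child in enumerate(ss.spawn(max(1, n_restarts))):
        rng_seed = int(child.generate_state(1)[0] % (2**32 - 1))
        model = GaussianHMM(
            n_components=n_states,
            covariance_type=covariance_type,
            min_covar=min_covar,
            n_iter=max_iter,
            tol=tol,
            random_state=rng_seed,
        )
        if restart_i > 0:
            # diversify the basin: seed the means from random frames
            rng = np.random.default_rng(child)
            idx = rng.choice(n_frames, size=n_states, replace=False)
            model.init_params = "stc"
            model.means_ = x[np.sort(idx)].copy()
        model.monitor_ = _HistoryMonitor(model.tol, model.n_iter, model.verbose)
        model.fit(x, lengths)
        hist = model.monitor_.full_history
        for a, b in zip(hist, hist[1:]):
            if b < a - 1e-8 * (1.0 + abs(a)):
                raise RuntimeError("EM log-likelihood decreased during fitting")
        ll = hist[-1] if hist else model.score(x, lengths)
        restart_lls.append(ll)
        if best is None or ll > best.log_likelihood:
            best = HMMResult(
                model=model,
                n_states=n_states,
                log_likelihood=ll,
                ll_history=list(hist),
                restart_lls=[],
                flags=flags,
            )
    best.restart_lls = restart_lls
    return best


def _path_summary(states: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    t_len = states.size
    fo = np.bincount(states, minlength=k) / t_len
    sr = float(np.mean(np.diff(states) != 0)) if t_len > 1 else 0.0
    return fo, sr


def decode_states(
    result: HMMResult, x: np.ndarray, subject: str = "", method: str = "viterbi"
) -> StatePath:
    """Decode one subject (same z-scoring as fitting) into a StatePath.

    ``method='viterbi'`` (default) takes the most probable path and hard
    state counts; ``'posterior'`` keeps the Viterbi path but computes FO
    from the smoothed posteriors instead of hard assignments.
    """
    z = standardize_series(x)
    states = result.model.predict(z)
    fo, sr = _path_summary(states, result.n_states)
    if method == "posterior":
        fo = result.model.predict_proba(z).mean(axis=0)
    elif method != "viterbi":
        raise ValueError("method must be 'viterbi' or 'posterior'")
    return StatePath(subject=subject, states=states, fo=fo, sr=sr)


def decode_cohort(
    result: HMMResult, series: dict[str, np.ndarray], method: str = "viterbi"
) -> dict[str, StatePath]:
    return {
        sub: decode_states(result, x, subject=sub, method=method)
        for sub, x in series.items()
    }


def hmm_features(
    paths: dict[str, StatePath], n_states: int = 6, require_states: int | None = None
) -> pd.DataFrame:
    """Per-subject feature block ``FO1..FOK, SR`` (K+1 columns).

    ``require_states`` enforces the expected state count (the reference
    configuration uses K=6, giving the 6+1=7 HMM features of the
    817-feature dynamic block).
    """
    if require_states is not None and n_states != require_states:
        raise ValueError(
            f"configuration requires K={require_states} states, got {n_states}"
        )
    rows = {}
    for sub, path in paths.items():
        if path.fo.size != n_states:
            raise ValueError(f"subject {sub} has {path.fo.size} states, expected {n_states}")
        rows[sub] = list(path.fo) + [path.sr]
    cols = [f"FO{k}" for k in range(1, n_states + 1)] + ["SR"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def extract_hmm_features(
    series: dict[str, np.ndarray],
    n_states: int = 6,
    seed: int | None = 0,
    n_restarts: int = 3,
    max_iter: int = 500,
    method: str = "viterbi",
) -> tuple[pd.DataFrame, HMMResult, dict[str, StatePath]]:
    """Fit + decode + summarize in one call (the pipeline's HMM stage)."""
    result = fit_hmm(
        series, n_states=n_states, seed=seed, n_restarts=n_restarts, max_iter=max_iter
    )
    paths = decode_cohort(result, series, method=method)
    return hmm_features(paths, n_states=n_states), result, paths
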