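"""Sliding-window multilayer networks, modularity, and node flexibility.

A subject's parcel time series is cut into heavily overlapping windows
(window 40 TRs, overlap 0.975 -> step 1 TR, so T=230 gives 191 layers);
each window's Pearson correlation matrix, with negative entries
truncated to zero and the diagonal removed, is one layer of an ordinal
multilayer network.  Communities are found by maximizing the multilayer
modularity

    Q = (1/2mu) * sum_ijsr [ (A_ijs - gamma * k_is k_js / 2m_s) d_sr
                             + d_ij * omega * 1(|s-r|=1) ] d(g_is, g_jr)

with a Newman-Girvan null inside each layer (resolution ``gamma``) and
uniform ordinal coupling ``omega`` between copies of a node in adjacent
layers; ``2mu`` is the total weight including coupling.  Optimization is
a GenLouvain-style iterated greedy pass over the sparse supra-modularity
matrix: local node moves until no single move improves Q, then community
aggregation, repeated until convergence, with seeded restarts (best Q
kept).  Node flexibility is the fraction of adjacent layer pairs at
which a node's community label changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sparse
from numba import njit

__all__ = [
    "sliding_windows",
    "supra_modularity_matrix",
    "multilayer_modularity",
    "node_flexibility",
    "flexibility_grid",
    "CommunitySequence",
]

DEFAULT_GAMMAS = (0.9, 1.0, 1.1)
DEFAULT_OMEGAS = (0.5, 0.75, 1.0)


@dataclass
class CommunitySequence:
    """Layer-by-node community labels plus the achieved modularity."""

    labels: np.ndarray  # (L, N), positive integers
    quality: float

    @property
    def n_layers(self) -> int:
        return self.labels.shape[0]


def sliding_windows(
    x: np.ndarray, window: int = 40, overlap: float = 0.975
) -> np.ndarray:
    """Windowed correlation layers: ``(L, N, N)`` non-negative, zero diagonal.

    ``step = round(window * (1 - overlap))`` (>= 1) and
    ``L = floor((T - window) / step) + 1``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be (T, N)")
    t_len, n = x.shape
    if t_len < window:
        raise ValueError(f"T={t_len} is shorter than the window ({window})")
    step = int(round(window * (1.0 - overlap)))
    if step < 1:
        raise ValueError("window/overlap give a step below 1 sample")
    n_layers = (t_len - window) // step + 1
    layers = np.empty((n_layers, n, n))
    for li in range(n_layers):
        seg = x[li * step : li * step + window]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.corrcoef(seg.T)
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 0.0)
        layers[li] = np.clip(r, 0.0, None)
    return layers


def supra_modularity_matrix(
    layers: np.ndarray, gamma: float, omega: float
) -> tuple[sparse.csr_matrix, float, list[int]]:
    """Sparse supra-matrix B and normalization 2mu.

    Supra-node ``s * N + i`` is node ``i`` in layer ``s``.  Layers with
    zero total weight contribute no null term and are reported as
    flagged layer indices.
    """
    layers = np.asarray(layers, dtype=float)
    n_layers, n, _ = layers.shape
    blocks = []
    two_mu = 0.0
    flagged: list[int] = []
    for s in range(n_layers):
        a = layers[s]
        k = a.sum(axis=0)
        m2 = k.sum()
        if m2 > 0:
            b = a - gamma * np.outer(k, k) / m2
        else:
            b = a.copy()
            flagged.append(s)
        two_mu += m2
        blocks.append(sparse.csr_matrix(b))
    b_supra = sparse.block_diag(blocks, format="csr")
    if n_layers > 1 and omega != 0.0:
        off = np.full(n * (n_layers - 1), omega)
        coupling = sparse.diags([off, off], offsets=[n, -n], format="csr")
        b_supra = (b_supra + coupling).tocsr()
    two_mu += 2.0 * omega * n * (n_layers - 1)
    return b_supra, two_mu, flagged


@njit(cache=True)
def _local_moves(indptr, indices, data, comm, order, max_passes=200):
    n = comm.shape[0]
    comm_size = np.zeros(n, np.int64)
    for v in range(n):
        comm_size[comm[v]] += 1
    w = np.zeros(n, np.float64)
    seen = np.zeros(n, np.uint8)
    touched = np.empty(n, np.int64)
    free = np.empty(n, np.int64)
    n_free = 0
    total_moves = 0
    for _ in range(max_passes):
        moves = 0
        for oi in range(n):
            v = order[oi]
            c0 = comm[v]
            nt = 0
            for p in range(indptr[v], indptr[v + 1]):
                j = indices[p]
                if j == v:
                    continue
                c = comm[j]
                if seen[c] == 0:
                    seen[c] = 1
                    w[c] = 0.0
                    touched[nt] = c
                    nt += 1
                w[c] += data[p]
            base = w[c0] if seen[c0] == 1 else 0.0
            best_gain = 0.0
            best_c = c0
            for q in range(nt):
                c = touched[q]
                if c == c0:
                    continue
                g = w[c] - base
                if g > best_gain + 1e-12:
                    best_gain = g
                    best_c = c
            # leaving for a fresh singleton community
            if comm_size[c0] > 1 and -base > best_gain + 1e-12:
                best_gain = -base
                best_c = -1
            if best_c != c0 and best_gain > 1e-12:
                comm_size[c0] -= 1
                if comm_size[c0] == 0:
                    free[n_free] = c0
                    n_free += 1
                if best_c == -1:
                    n_free -= 1
                    best_c = free[n_free]
                comm[v] = best_c
                comm_size[best_c] += 1
                moves += 1
            for q in range(nt):
                seen[touched[q]] = 0
        total_moves += moves
        if moves == 0:
            break
    return total_moves


def _genlouvain_once(
    b: sparse.csr_matrix, two_mu: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    b_cur = b.tocsr().astype(np.float64)
    n0 = b_cur.shape[0]
    global_labels = np.arange(n0)
    q_prev = -np.inf
    while True:
        n = b_cur.shape[0]
        comm = np.arange(n)
        order = rng.permutation(n)
        moves = _local_moves(
            b_cur.indptr, b_cur.indices, b_cur.data, comm, order
        )
        _, comm_c = np.unique(comm, return_inverse=True)
        nc = comm_c.max() + 1
        proj = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), comm_c)), shape=(n, nc)
        )
        b_next = (proj.T @ b_cur @ proj).tocsr()
        q = float(b_next.diagonal().sum()) / two_mu
        # greedy moves can only raise Q; tolerate float round-off only
        assert q >= q_prev - 1e-9 * (1.0 + abs(q_prev)), "modularity decreased"
        global_labels = comm_c[global_labels]
        if moves == 0 or nc == n:
            return global_labels, q
        b_cur = b_next
        q_prev = q


def multilayer_modularity(
    layers: np.ndarray,
    gamma: float = 1.0,
    omega: float = 1.0,
    seed: int | None = 0,
    n_restarts: int = 3,
) -> CommunitySequence:
    """Maximize multilayer modularity; best of ``n_restarts`` seeded runs.

    Node sweep order is shuffled per restart; the run with the highest Q
    wins (first one on ties), so the result is deterministic given
    ``seed``.
    """
    layers = np.asarray(layers, dtype=float)
    if layers.ndim != 3 or layers.shape[1] != layers.shape[2]:
        raise ValueError("layers must be (L, N, N)")
    n_layers, n, _ = layers.shape
    b, two_mu, flagged = supra_modularity_matrix(layers, gamma, omega)
    if flagged:
        warnings.warn(
            f"layers {flagged} have zero total weight; their null term was skipped",
            stacklevel=2,
        )
    if two_mu <= 0:
        # entirely empty network: everything in one community
        return CommunitySequence(np.ones((n_layers, n), dtype=int), 0.0)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best: tuple[float, np.ndarray] | None = None
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        labels, q = _genlouvain_once(b, two_mu, rng)
        if best is None or q > best[0] + 1e-12:
            best = (q, labels)
    q, flat = best
    return CommunitySequence(flat.reshape(n_layers, n) + 1, q)


def node_flexibility(cs: CommunitySequence | np.ndarray) -> np.ndarray:
    """Fraction of adjacent layer pairs at which each node changes community."""
    labels = cs.labels if isinstance(cs, CommunitySequence) else np.asarray(cs)
    if labels.ndim != 2 or labels.shape[0] < 2:
        raise ValueError("need a (L, N) label array with L >= 2")
    changes = labels[1:] != labels[:-1]
    return changes.mean(axis=0)


def flexibility_grid(
    x: np.ndarray,
    gammas: tuple = DEFAULT_GAMMAS,
    omegas: tuple = DEFAULT_OMEGAS,
    window: int = 40,
    overlap: float = 0.975,
    seed: int | None = 0,
    n_restarts: int = 3,
) -> pd.DataFrame:
    """Node flexibility for every (gamma, omega) cell of the grid.

    Returns a (parcel x cell) frame with columns ``NF_g{i}_o{j}`` —
    90 parcels x a 3x3 grid = 810 features at the defaults.  Each cell
    gets an independent child seed, so a single-cell grid equals the
    direct call.
    """
    if len(gammas) == 0 or len(omegas) == 0:
        raise ValueError("gamma/omega grids must be non-empty")
    layers = sliding_windows(x, window=window, overlap=overlap)
    n = layers.shape[1]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(gammas) * len(omegas)))
    out = {}
    for gi, gamma in enumerate(gammas, start=1):
        for oi, omega in enumerate(omegas, start=1):
            cs = multilayer_modularity(
                layers,
                gamma=gamma,
                omega=omega,
                seed=next(children),
                n_restarts=n_restarts,
            )
            out[f"NF_g{gi}_o{oi}"] = node_flexibility(cs)
    idx = pd.RangeIndex(1, n + 1, name="parcel")
    return pd.DataFrame(out, index=idx)
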