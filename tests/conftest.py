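import numpy as np
import pytest

import restdyn as rd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small node-mode cohort shared by read-only tests."""
    cfg = rd.SimulationConfig(
        n_patients=8, n_controls=8, n_parcels=10, n_volumes=230, seed=77
    )
    return rd.generate_cohort(cfg)


def brute_force_kendall_w(series: np.ndarray) -> float:
    """Independent textbook Kendall-W oracle (explicit rank sums)."""
    import scipy.stats

    k, n = series.shape
    ranks = np.array([scipy.stats.rankdata(row) for row in series])
    rank_sums = ranks.sum(axis=0)
    s = np.sum((rank_sums - rank_sums.mean()) ** 2)
    return 12.0 * s / (k**2 * (n**3 - n))


def brute_force_q(layers, gamma, omega, flat_labels) -> float:
    """Multilayer modularity evaluated directly from its definition."""
    layers = np.asarray(layers, dtype=float)
    n_layers, n, _ = layers.shape
    lab = np.asarray(flat_labels).reshape(n_layers, n)
    total = 0.0
    two_mu = 0.0
    for s in range(n_layers):
        a = layers[s]
        k = a.sum(axis=0)
        m2 = k.sum()
        two_mu += m2
        for i in range(n):
            for j in range(n):
                null = gamma * k[i] * k[j] / m2 if m2 > 0 else 0.0
                if lab[s, i] == lab[s, j]:
                    total += a[i, j] - null
    for s in range(n_layers - 1):
        for i in range(n):
            if lab[s, i] == lab[s + 1, i]:
                total += 2.0 * omega
    two_mu += 2.0 * omega * n * (n_layers - 1)
    return total / two_mu


def set_partitions(n: int):
    """All partitions of range(n) as restricted-growth label strings."""
    a = [0] * n
    b = [0] * n
    while True:
        yield list(a)
        i = n - 1
        while i > 0 and a[i] == b[i] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
        for j in range(1, n):
            b[j] = max(b[j - 1], a[j - 1])
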