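import numpy as np
import pytest

from kinhmm.counts import PairWindowData, SiteReadCounts
from kinhmm.layout import build_window_grid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_grid():
    """Two chromosomes, 5 + 3 windows of 10 bp."""
    return build_window_grid([("1", 50), ("2", 30)], window_size=10)


@pytest.fixture()
def toy_counts():
    """Three tiny individuals on a shared 6-site universe."""

    def make(name, derived, total):
        pos = np.array([3, 12, 18, 25, 33, 47])
        return SiteReadCounts(
            name, {"1": (pos, np.asarray(derived, float), np.asarray(total, float))}
        )

    a = make("A", [2, 0, 1, 0, 3, 1], [2, 1, 2, 0, 3, 2])
    b = make("B", [0, 1, 1, 1, 0, 0], [1, 1, 2, 2, 1, 0])
    c = make("C", [1, 0, 0, 1, 2, 1], [2, 2, 1, 1, 2, 1])
    return a, b, c


def brute_force_hmm(log_e, A, pi, chrom_slices=None):
    """Exhaustive path enumeration: posteriors, loglik and best path.

    Independent oracle for forward-backward/Viterbi on tiny instances.
    Ties in the best path resolve toward the lexicographically smallest
    state sequence (matching lower-state tie-breaking).
    """
    import itertools

    log_e = np.asarray(log_e, float)
    L, K = log_e.shape
    if chrom_slices is None:
        chrom_slices = [slice(0, L)]
    with np.errstate(divide="ignore"):
        logA, logpi = np.log(A), np.log(pi)
    total_ll = 0.0
    gamma = np.zeros((L, K))
    best_path = np.zeros(L, dtype=int)
    for sl in chrom_slices:
        e = log_e[sl]
        n = e.shape[0]
        probs = {}
        for path in itertools.product(range(K), repeat=n):
            lp = logpi[path[0]] + e[0, path[0]]
            for t in range(1, n):
                lp += logA[path[t - 1], path[t]] + e[t, path[t]]
            probs[path] = lp
        lls = np.array(list(probs.values()))
        m = lls.max()
        z = m + np.log(np.exp(lls - m).sum())
        total_ll += z
        g = np.zeros((n, K))
        for path, lp in probs.items():
            w = np.exp(lp - z)
            for t, s in enumerate(path):
                g[t, s] += w
        gamma[sl] = g
        best = min(probs, key=lambda p: (-probs[p], p))
        best_path[sl] = best
    return gamma, total_ll, best_path


@pytest.fixture()
def pair_data_sim(rng):
    """Beta-binomial pair data with known levels, for recovery tests."""

    def make(L, N, p, delta, seed=0):
        r = np.random.default_rng(seed)
        q = r.beta(p * delta, (1 - p) * delta, size=L)
        D = r.binomial(N, q).astype(float)
        return PairWindowData(("x", "y"), D, np.full(L, float(N)))

    return make
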