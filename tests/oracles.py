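"""Independent brute-force reference implementations used only by the tests.

Every function here is a deliberately naive loop written straight from the
defining formulas, kept separate from (and structurally unlike) the vectorized
library code so the two can serve as mutual checks.
"""

import math

import numpy as np


def pseknc_theta_naive(seq_dna: str, table, lam: int) -> list[float]:
    """theta_j for j=1..lam by explicit double loop over tuple positions."""
    K = table.K
    L = len(seq_dna)
    n_tuples = L - K + 1
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        count = 0
        for i in range(n_tuples - j):
            t1 = seq_dna[i : i + K]
            t2 = seq_dna[i + j : i + j + K]
            h1 = table.values[t1]
            h2 = table.values[t2]
            acc = 0.0
            for n in range(table.n_properties):
                acc += (h1[n] - h2[n]) ** 2
            total += acc / table.n_properties
            count += 1
        thetas.append(total / count)
    return thetas


def pseknc_vector_naive(seq_dna: str, table, lam: int, omega: float) -> list[float]:
    """Full pseudo composition vector by direct evaluation."""
    K = table.K
    from itertools import product

    tuples = ["".join(p) for p in product("ACGT", repeat=K)]
    n_windows = len(seq_dna) - K + 1
    freqs = []
    for t in tuples:
        c = sum(1 for i in range(n_windows) if seq_dna[i : i + K] == t)
        freqs.append(c / n_windows)
    thetas = pseknc_theta_naive(seq_dna, table, lam)
    denom = sum(freqs) + omega * sum(thetas)
    return [f / denom for f in freqs] + [omega * t / denom for t in thetas]


def dct_naive(signal, n_components: int) -> list[float]:
    """First coefficients of the orthonormal DCT-II by direct O(L^2) summation."""
    L = len(signal)
    out = []
    for k in range(n_components):
        a = math.sqrt(1.0 / L) if k == 0 else math.sqrt(2.0 / L)
        s = 0.0
        for n in range(L):
            s += signal[n] * math.cos((2 * n + 1) * k * math.pi / (2 * L))
        out.append(a * s)
    return out


def bigram_naive(matrix) -> list[float]:
    """B[m, n] = sum_i P[i, m] P[i+1, n] by triple loop, flattened row-major."""
    L = len(matrix)
    out = []
    for m in range(20):
        for n in range(20):
            s = 0.0
            for i in range(L - 1):
                s += matrix[i][m] * matrix[i + 1][n]
            out.append(s)
    return out


def autocovariance_naive(scores, max_lag: int) -> list[float]:
    L = len(scores)
    dbar = sum(scores) / L
    out = []
    for lag in range(1, max_lag + 1):
        s = 0.0
        for i in range(L - lag):
            s += (scores[i] - dbar) * (scores[i + lag] - dbar)
        out.append(s / (L - lag))
    return out


def relief_naive(X, y, n_neighbors: int = 1) -> np.ndarray:
    """Relief weights with range-normalized diffs, every instance sampled,
    Manhattan nearest hits/misses, averaged over the k neighbors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = hi - lo
    rng[rng < 1e-12] = 1.0
    Z = (X - lo) / rng
    w = np.zeros(d)
    for i in range(n):
        dists = [sum(abs(Z[i, p] - Z[j, p]) for p in range(d)) for j in range(n)]
        hits, misses = [], []
        for j in sorted(range(n), key=lambda j: (dists[j], j)):
            if j == i:
                continue
            (hits if y[j] == y[i] else misses).append(j)
        for p in range(d):
            hit_diff = sum(abs(Z[i, p] - Z[j, p]) for j in hits[:n_neighbors]) / min(
                n_neighbors, len(hits)
            )
            miss_diff = sum(abs(Z[i, p] - Z[j, p]) for j in misses[:n_neighbors]) / min(
                n_neighbors, len(misses)
            )
            w[p] += (miss_diff - hit_diff) / n
    return w
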