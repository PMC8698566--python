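"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: plain-loop fuzzy c-means,
combinatorial tail enumeration for hypergeometric/Fisher tests, an O(N^3)
triple scan for cascades, and a closed-form consensus-marker null.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_fcm(X, k, m, seed=0, max_iter=2000, tol=1e-12):
    """Loop-based fuzzy c-means, run to tight convergence.

    Returns (U, V, J).  Written with explicit per-point loops so it cannot
    share a vectorization bug with the package implementation.
    """
    rng = np.random.default_rng(seed)
    n, d = X.shape
    U = rng.dirichlet(np.ones(k), size=n)
    for _ in range(max_iter):
        V = np.zeros((k, d))
        for c in range(k):
            num = np.zeros(d)
            den = 0.0
            for i in range(n):
                w = U[i, c] ** m
                num += w * X[i]
                den += w
            V[c] = num / den
        U_new = np.zeros_like(U)
        for i in range(n):
            dists = [float(np.sum((X[i] - V[c]) ** 2)) for c in range(k)]
            if min(dists) <= 1e-300:
                for c in range(k):
                    U_new[i, c] = 1.0 if dists[c] <= 1e-300 else 0.0
                U_new[i] /= U_new[i].sum()
            else:
                for c in range(k):
                    s = sum((dists[c] / dists[j]) ** (1.0 / (m - 1.0))
                            for j in range(k))
                    U_new[i, c] = 1.0 / s
        if np.abs(U_new - U).max() < tol:
            U = U_new
            break
        U = U_new
    V = np.zeros((k, d))
    for c in range(k):
        w = U[:, c] ** m
        V[c] = (w[:, None] * X).sum(axis=0) / w.sum()
    J = 0.0
    for i in range(n):
        for c in range(k):
            J += (U[i, c] ** m) * float(np.sum((X[i] - V[c]) ** 2))
    return U, V, J


def hypergeom_upper_tail(x, M, K, n):
    """P[X >= x] for X ~ Hypergeometric(M, K, n), by direct enumeration."""
    denom = math.comb(M, n)
    total = 0
    for i in range(x, min(K, n) + 1):
        if n - i <= M - K:
            total += math.comb(K, i) * math.comb(M - K, n - i)
    return total / denom


def fisher_greater(a, b, c, d):
    """One-sided (enrichment) Fisher exact p for [[a, b], [c, d]].

    Equals the hypergeometric upper tail with M = a+b+c+d, K = a+c,
    n = a+b, x = a.
    """
    return hypergeom_upper_tail(a, a + b + c + d, a + c, a + b)


def brute_force_cascades(graph, labels, annotations=None,
                         terminal_type=None):
    """All (c, d, e) triples with labels C/D/E, edges {c,d} and {d,e}, c != e,
    by scanning every ordered node triple."""
    nodes = list(graph.nodes)
    out = set()
    for c, d, e in itertools.permutations(nodes, 3):
        if labels.get(c) != "C" or labels.get(d) != "D" or labels.get(e) != "E":
            continue
        if not (graph.has_edge(c, d) and graph.has_edge(d, e)):
            continue
        if terminal_type is not None and annotations is not None:
            if annotations.get(e) != terminal_type:
                continue
        out.add((c, d, e))
    return out


def consensus_null_probability(k_datasets, alpha=0.05):
    """P[a null gene becomes a consensus marker] across k datasets.

    Per dataset, a two-sided t-test on continuous null data is significant-up
    with probability alpha/2 and significant-down with alpha/2.  A gene is a
    marker iff exactly one direction reaches >= 2 supporting datasets.
    """
    p = alpha / 2.0
    q = 1.0 - alpha
    total = 0.0
    for u in range(k_datasets + 1):
        for d in range(k_datasets + 1 - u):
            rest = k_datasets - u - d
            prob = (math.comb(k_datasets, u) * math.comb(k_datasets - u, d)
                    * p ** (u + d) * q ** rest)
            if (u >= 2) != (d >= 2):
                total += prob
    return total
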