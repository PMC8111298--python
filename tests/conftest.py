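"""Shared fixtures and independent oracles for the test suite.

The brute-force oracles here deliberately share no code with the package:
they use plain loops, explicit matrix inverses and naive sorting so they can
serve as independent references for the vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvsnmf.graphs import SimilarityGraph, gaussian_kernel_similarity


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_similarity_graph(rng: np.random.Generator, n: int, dim: int = 3) -> SimilarityGraph:
    """A dense Gaussian-kernel graph over random points (generic weights)."""
    X = rng.random((n, dim)) * 4.0
    return gaussian_kernel_similarity(X, d=min(5, n - 1))


def vicus_bruteforce(W: np.ndarray, K: int, alpha: float) -> np.ndarray:
    """Straight-line Vicus construction: per-node subnetwork, explicit inverse.

    Neighbour ranking: descending similarity, ties to the lower index —
    implemented here with python sorting, not the package's lexsort helper.
    """
    n = W.shape[0]
    K = min(K, n - 1)
    B = np.zeros((n, n))
    for i in range(n):
        others = [j for j in range(n) if j != i]
        others.sort(key=lambda j: (-W[i, j], j))
        nb = others[:K]
        nodes = nb + [i]
        P = np.array([[W[a, b] for b in nodes] for a in nodes])
        for r in range(K + 1):
            P[r, r] = 0.0
        S = np.zeros_like(P)
        for r in range(K + 1):
            s = P[r].sum()
            if s > 0:
                S[r] = P[r] / s
            else:
                S[r] = 1.0 / K
                S[r, r] = 0.0
        M = np.linalg.inv(np.eye(K + 1) - alpha * S)
        beta = (1.0 - alpha) * M[K, :]
        denom = 1.0 - beta[K]
        for pos, j in enumerate(nb):
            B[i, j] = beta[pos] / denom
    IB = np.eye(n) - B
    return IB.T @ IB


def accuracy_exhaustive(true_labels, pred_labels) -> float:
    """Clustering accuracy by exhaustive search over all label mappings."""
    from itertools import permutations

    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    t_vals = sorted(set(t.tolist()))
    p_vals = sorted(set(p.tolist()))
    small, large = (p_vals, t_vals) if len(p_vals) <= len(t_vals) else (t_vals, p_vals)
    ref, other = (t, p) if len(p_vals) <= len(t_vals) else (p, t)
    best = 0
    for perm in permutations(large, len(small)):
        mapping = dict(zip(small, perm))
        best = max(best, sum(mapping[v] == r for v, r in zip(other, ref)))
    return best / len(t)
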