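"""Vicus local-spectral matrix via per-node label diffusion.

Where the Laplacian encodes the global smoothness of a graph, the Vicus
operator encodes its fine-grained local topology.  For every sample *i* a
local subnetwork over its K nearest neighbours (plus *i* itself) is
extracted, and the steady state of label diffusion on that subnetwork,
``(1 - alpha) (I - alpha S_i)^{-1}``, yields the weights with which the
neighbours linearly reconstruct the centre node.  Stacking those weights
into a row-stochastic reconstruction matrix ``B`` gives

    V = (I - B)^T (I - B),

a symmetric positive-semidefinite operator that, like the Laplacian,
annihilates the constant vector.  The factorization consumes the sign split
``V = V+ - V-`` so its multiplicative update stays non-negative.

Subnetwork weights are taken from the *dense* Gaussian kernel (before kNN
sparsification): the local neighbourhood size K is a parameter of its own,
independent of the global graph's sparsification level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graphs import SimilarityGraph, _neighbor_order

__all__ = [
    "LocalSubnetwork",
    "VicusMatrix",
    "extract_local_subnetwork",
    "build_reconstruction_row",
    "vicus_matrix",
]

DEFAULT_NEIGHBORHOOD_SIZE = 15  # K
DEFAULT_DIFFUSION_ALPHA = 0.9   # restart weight of the label diffusion

#: 1 - beta[center] below this means the centre is effectively isolated and
#: reconstruction weights degenerate; fall back to uniform weights.
_ISOLATION_TOL = 1e-12


@dataclass(frozen=True)
class LocalSubnetwork:
    """Subnetwork around one sample: its K neighbours plus the sample itself.

    Nodes are ordered ``[neighbors..., center]`` so the centre sits at
    position K+1 (index K).  ``P`` is the restriction of the dense kernel to
    these nodes (zero diagonal); ``S`` is ``P`` row-normalized.
    """

    center: int
    neighbors: np.ndarray  # K global sample indices, descending similarity
    P: np.ndarray          # (K+1, K+1) local weights
    S: np.ndarray          # (K+1, K+1) row-stochastic transition matrix

    @property
    def K(self) -> int:
        return len(self.neighbors)


@dataclass(frozen=True)
class VicusMatrix:
    """The assembled local-spectral operator and its building blocks."""

    V: np.ndarray        # n x n, symmetric PSD, V @ 1 = 0
    B: np.ndarray        # n x n reconstruction matrix, rows sum to 1
    beta: np.ndarray     # n x (K+1) terminal diffusion rows
    diffusion_alpha: float
    K: int
    V_plus: np.ndarray   # element-wise non-negative, V = V_plus - V_minus
    V_minus: np.ndarray

    @property
    def n(self) -> int:
        return self.V.shape[0]


def extract_local_subnetwork(G: SimilarityGraph, i: int, K: int = DEFAULT_NEIGHBORHOOD_SIZE) -> LocalSubnetwork:
    """Restrict the graph to sample ``i`` and its K most similar samples.

    Neighbours are ranked by descending ``w_ij`` with ties broken by the
    lower sample index; ``K`` is clipped to ``n - 1``.  A row of the local
    weight matrix that sums to zero is replaced by a uniform distribution
    over the other nodes so the transition matrix stays row-stochastic.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    n = G.n
    K_eff = min(int(K), n - 1)
    neighbors = _neighbor_order(G.W[i], i)[:K_eff]
    nodes = np.append(neighbors, i)  # centre last, position K+1

    P = G.W[np.ix_(nodes, nodes)].copy()
    np.fill_diagonal(P, 0.0)
    S = P.copy()
    row_sums = S.sum(axis=1)
    for r in np.flatnonzero(row_sums <= 0):
        S[r] = 1.0 / K_eff
        S[r, r] = 0.0
        row_sums[r] = 1.0
    S /= row_sums[:, None]
    return LocalSubnetwork(center=i, neighbors=neighbors, P=P, S=S)


def build_reconstruction_row(
    sub: LocalSubnetwork, diffusion_alpha: float = DEFAULT_DIFFUSION_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruction weights of the centre node from its neighbours.

    ``beta`` is the centre's row of the terminal diffusion operator
    ``(1 - alpha)(I - alpha S)^{-1}`` (a probability vector: the operator is
    row-stochastic for any row-stochastic S and alpha in (0, 1)).  The
    reconstruction weight on the j-th neighbour is
    ``beta[j] / (1 - beta[K+1])``; the returned weights sum to 1.

    Returns
    -------
    beta, weights
        The full (K+1)-vector ``beta`` and the length-K weight vector over
        ``sub.neighbors``.
    """
    if not 0.0 < diffusion_alpha < 1.0:
        raise ValueError(f"diffusion_alpha must lie in (0, 1), got {diffusion_alpha}")
    K = sub.K
    M = np.eye(K + 1) - diffusion_alpha * sub.S
    e_center = np.zeros(K + 1)
    e_center[K] = 1.0
    # centre row of the inverse == solve with the transposed system
    beta = (1.0 - diffusion_alpha) * np.linalg.solve(M.T, e_center)

    self_weight = beta[K]
    denom = 1.0 - self_weight
    if denom <= _ISOLATION_TOL:
        warnings.warn(
            f"sample {sub.center}: centre retains all diffusion mass "
            "(isolated in its subnetwork); using uniform reconstruction weights",
            RuntimeWarning,
            stacklevel=2,
        )
        return beta, np.full(K, 1.0 / K)
    return beta, beta[:K] / denom


def vicus_matrix(
    G: SimilarityGraph,
    K: int = DEFAULT_NEIGHBORHOOD_SIZE,
    diffusion_alpha: float = DEFAULT_DIFFUSION_ALPHA,
) -> VicusMatrix:
    """Assemble ``V = (I - B)^T (I - B)`` from all per-node reconstructions.

    Also computes the sign split ``V_plus = (|V| + V)/2``,
    ``V_minus = (|V| - V)/2`` used by the regularized multiplicative update
    (both element-wise non-negative with ``V_plus - V_minus = V`` exactly).
    """
    n = G.n
    K_eff = min(int(K), n - 1)
    B = np.zeros((n, n))
    beta_rows = np.zeros((n, K_eff + 1))
    for i in range(n):
        try:
            sub = extract_local_subnetwork(G, i, K_eff)
            beta, weights = build_reconstruction_row(sub, diffusion_alpha)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"Vicus subnetwork solve failed for {G.sample_name(i)}") from exc
        B[i, sub.neighbors] = weights
        beta_rows[i] = beta

    IB = np.eye(n) - B
    V = IB.T @ IB  # Gram product: exactly symmetric in floating point
    absV = np.abs(V)
    V_plus = (absV + V) / 2.0
    V_minus = (absV - V) / 2.0
    return VicusMatrix(
        V=V, B=B, beta=beta_rows, diffusion_alpha=diffusion_alpha,
        K=K_eff, V_plus=V_plus, V_minus=V_minus,
    )
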