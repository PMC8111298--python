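"""Affinity-graph construction for sample-by-feature matrices.

The clustering pipeline never factorizes the feature matrix directly; it
operates on a sample-sample similarity graph.  This module builds that graph:

1. a Gaussian kernel with per-sample adaptive bandwidths (``sigma_i`` = the
   Euclidean distance from sample *i* to its ``d``-th nearest neighbour),
2. k-nearest-neighbour sparsification under the symmetric OR rule,
3. the degree-normalized affinity ``A = D^{-1/2} W D^{-1/2}`` that the
   symmetric factorization consumes, and
4. unnormalized (``L = D - W``) and normalized (``L = I - A``) graph
   Laplacians used as the global smoothness regularizer.

Distances are computed on the rows of the feature matrix as given; any
log/CLR or other compositional preprocessing is the caller's responsibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FeatureMatrix",
    "SimilarityGraph",
    "NormalizedAffinity",
    "LaplacianMatrix",
    "gaussian_kernel_similarity",
    "knn_sparsify",
    "symmetric_normalize",
    "laplacian",
]

#: Lower bound on kernel bandwidths; duplicated samples would otherwise
#: produce sigma = 0 and a division by zero in the Gaussian kernel.
BANDWIDTH_FLOOR = 1e-12

DEFAULT_BANDWIDTH_NEIGHBOR = 7   # d: which neighbour sets the kernel bandwidth
DEFAULT_SPARSIFY_NEIGHBORS = 12  # p: neighbours kept by kNN sparsification


@dataclass(frozen=True)
class FeatureMatrix:
    """A non-negative samples x features matrix with identifiers.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_features)``; all entries must be
        finite and non-negative (abundances, expression, counts ...).
    sample_ids
        ``n_samples`` unique strings naming the rows.
    feature_ids
        ``n_features`` strings naming the columns.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got shape {values.shape}")
        n, m = values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(f"non-finite entry at row {bad[0]}, column {bad[1]}")
        if np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative entry {values[bad[0], bad[1]]!r} at row {bad[0]}, "
                f"column {bad[1]}; the matrix must be non-negative"
            )
        sample_ids = tuple(str(s) for s in self.sample_ids)
        feature_ids = tuple(str(f) for f in self.feature_ids)
        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} rows")
        if len(feature_ids) != m:
            raise ValueError(f"{len(feature_ids)} feature ids for {m} columns")
        if len(set(sample_ids)) != n:
            seen: set[str] = set()
            dup = next(s for s in sample_ids if s in seen or seen.add(s))
            raise ValueError(f"duplicate sample id {dup!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "feature_ids", feature_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values: np.ndarray, sample_ids=None, feature_ids=None) -> "FeatureMatrix":
        """Wrap a bare array, inventing ``s000...``/``f000...`` ids if absent."""
        values = np.asarray(values, dtype=float)
        n, m = values.shape
        if sample_ids is None:
            sample_ids = tuple(f"s{i:04d}" for i in range(n))
        if feature_ids is None:
            feature_ids = tuple(f"f{j:04d}" for j in range(m))
        return cls(values, tuple(sample_ids), tuple(feature_ids))


@dataclass(frozen=True)
class SimilarityGraph:
    """Symmetric weighted affinity over samples.

    ``W`` holds Gaussian-kernel similarities in ``[0, 1]`` with a zero
    diagonal (self-similarity removed).  ``sigma`` records the per-sample
    bandwidths used to build the kernel; ``d`` the bandwidth neighbour index
    and ``p`` the sparsification neighbour count (``None`` before
    sparsification).
    """

    W: np.ndarray
    sigma: np.ndarray
    d: int
    p: int | None = None
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        n = W.shape[0]
        if W.shape != (n, n):
            raise ValueError(f"W must be square, got {W.shape}")
        if not np.allclose(W, W.T, atol=1e-12, rtol=0.0):
            raise ValueError("W must be symmetric")
        if np.any(W < 0) or np.any(W > 1):
            raise ValueError("similarities must lie in [0, 1]")
        if np.any(np.diagonal(W) != 0):
            raise ValueError("diagonal of W must be exactly zero")
        if sigma.shape != (n,) or np.any(sigma <= 0):
            raise ValueError("sigma must be a strictly positive length-n vector")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def sample_name(self, i: int) -> str:
        return self.sample_ids[i] if self.sample_ids is not None else f"sample #{i}"


@dataclass(frozen=True)
class NormalizedAffinity:
    """Degree-normalized affinity ``A = D^{-1/2} W D^{-1/2}``.

    Symmetric, non-negative, zero diagonal; largest eigenvalue at most 1.
    ``degrees`` are the row sums of the *unnormalized* W it came from.
    """

    A: np.ndarray
    degrees: np.ndarray

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class LaplacianMatrix:
    """Graph Laplacian, unnormalized ``D - W`` or normalized ``I - A``."""

    L: np.ndarray
    normalized: bool
    source_degrees: np.ndarray


def _pairwise_sq_distances(values: np.ndarray) -> np.ndarray:
    D2 = squareform(pdist(values, metric="sqeuclidean"))
    return D2


def gaussian_kernel_similarity(
    X: FeatureMatrix | np.ndarray, d: int = DEFAULT_BANDWIDTH_NEIGHBOR
) -> SimilarityGraph:
    """Build the adaptive-bandwidth Gaussian kernel affinity.

    ``w_ij = exp(-||x_i - x_j||^2 / (sigma_i sigma_j))`` for ``i != j``, where
    ``sigma_i`` is the Euclidean distance from sample *i* to its ``d``-th
    nearest *other* sample (``d`` clipped to ``n - 1``; bandwidths floored at
    :data:`BANDWIDTH_FLOOR`).  The diagonal is forced to zero.

    Parameters
    ----------
    X
        Feature matrix (or bare array, wrapped via
        :meth:`FeatureMatrix.from_array`).
    d
        Bandwidth neighbour index, default 7.
    """
    if not isinstance(X, FeatureMatrix):
        X = FeatureMatrix.from_array(np.asarray(X, dtype=float))
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    n = X.n_samples
    d_eff = min(int(d), n - 1)

    D2 = _pairwise_sq_distances(X.values)
    dist = np.sqrt(D2)
    # distance to the d-th nearest other sample: mask self with +inf and sort
    masked = dist + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    sigma = np.sort(masked, axis=1)[:, d_eff - 1]
    sigma = np.maximum(sigma, BANDWIDTH_FLOOR)

    W = np.exp(-D2 / np.outer(sigma, sigma))
    np.fill_diagonal(W, 0.0)
    return SimilarityGraph(W=W, sigma=sigma, d=d_eff, p=None, sample_ids=X.sample_ids)


def _neighbor_order(row: np.ndarray, self_index: int) -> np.ndarray:
    """Indices ordered by descending similarity, ties to the lower index,
    the node itself excluded."""
    n = row.shape[0]
    order = np.lexsort((np.arange(n), -row))
    return order[order != self_index]


def knn_sparsify(G: SimilarityGraph, p: int = DEFAULT_SPARSIFY_NEIGHBORS) -> SimilarityGraph:
    """Keep only edges between p-nearest neighbours (symmetric OR rule).

    Edge ``(i, j)`` survives iff *i* is among the ``p`` most similar samples
    of *j* **or** vice versa, which preserves symmetry by construction.
    Neighbourhoods are ranked by descending similarity with ties broken by
    the lower sample index.  ``p`` is clipped to ``n - 1``.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    n = G.n
    p_eff = min(int(p), n - 1)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        mask[i, _neighbor_order(G.W[i], i)[:p_eff]] = True
    keep = mask | mask.T
    W = np.where(keep, G.W, 0.0)
    np.fill_diagonal(W, 0.0)
    return dataclasses.replace(G, W=W, p=p_eff)


def symmetric_normalize(G: SimilarityGraph) -> NormalizedAffinity:
    """``A = D^{-1/2} W D^{-1/2}`` with ``D_ii`` the row sums of W.

    Raises
    ------
    ValueError
        If any sample has zero degree (isolated node); the message names
        the offending sample.
    """
    deg = G.degrees()
    if np.any(deg <= 0):
        i = int(np.argmin(deg))
        raise ValueError(
            f"isolated node: {G.sample_name(i)} has zero degree; "
            "cannot normalize the affinity"
        )
    inv_sqrt = 1.0 / np.sqrt(deg)
    A = G.W * np.outer(inv_sqrt, inv_sqrt)
    return NormalizedAffinity(A=A, degrees=deg)


def laplacian(G: SimilarityGraph, normalized: bool = False) -> LaplacianMatrix:
    """Graph Laplacian of the similarity graph.

    Unnormalized: ``L = D - W`` (row sums zero, PSD).  Normalized (the
    spectral-clustering form): ``L = I - D^{-1/2} W D^{-1/2}``; requires
    strictly positive degrees.
    """
    deg = G.degrees()
    if normalized:
        A = symmetric_normalize(G).A  # raises on zero degree
        L = np.eye(G.n) - A
    else:
        L = np.diag(deg) - G.W
    return LaplacianMatrix(L=L, normalized=normalized, source_degrees=deg)
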