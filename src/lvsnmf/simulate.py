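"""Seeded generators of clustered non-negative matrices with known labels.

Three regimes cover the data shapes the clustering pipeline targets:

* :func:`make_blobs` — well-separated isotropic Gaussian clusters, the
  easiest sanity regime (expression-like continuous values);
* :func:`make_compositional` — Dirichlet-multinomial taxon-count profiles
  with cluster-specific dominant taxa, emulating species-level relative
  abundance tables (microbiome body-site style);
* :func:`make_manifold` — two concentric rings, a nonlinear geometry where
  centroid methods fail but graph-based clustering succeeds.

Every generator is a pure function of its parameters and the seed (a single
``numpy.random.default_rng(seed)`` stream consumed in documented order), so
identical calls reproduce identical datasets on any platform.  Gaussian
outputs are shifted by their minimum and clipped at zero, since the
factorization requires non-negative input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.spatial.distance import pdist

from .graphs import FeatureMatrix

__all__ = ["SyntheticDataset", "make_blobs", "make_compositional", "make_manifold"]


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated feature matrix, its ground-truth labels and provenance."""

    X: FeatureMatrix
    labels: np.ndarray
    generator_params: dict[str, Any]

    @property
    def n_clusters(self) -> int:
        return int(np.max(self.labels)) + 1


def _wrap(values: np.ndarray, labels: np.ndarray, params: dict[str, Any]) -> SyntheticDataset:
    X = FeatureMatrix.from_array(values)
    return SyntheticDataset(X=X, labels=np.asarray(labels, dtype=int), generator_params=params)


def make_blobs(
    k: int = 3,
    n_per_cluster: int = 30,
    dim: int = 10,
    separation: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Isotropic Gaussian clusters with a guaranteed centre separation.

    Cluster centres are drawn standard-normal and rescaled so the minimum
    pairwise centre distance equals ``separation``; each sample adds
    isotropic noise of standard deviation ``noise_sd`` per coordinate.
    The defaults (separation 10, unit noise) give well-separated clusters.
    Stream order: centres, then noise.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if dim < 2:
        raise ValueError(f"dim must be >= 2, got {dim}")
    if separation <= 0:
        raise ValueError(f"separation must be positive, got {separation}")
    if n_per_cluster < 1:
        raise ValueError(f"n_per_cluster must be >= 1, got {n_per_cluster}")
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(k, dim))
    centers *= separation / pdist(centers).min()
    labels = np.repeat(np.arange(k), n_per_cluster)
    X = centers[labels] + noise_sd * rng.normal(size=(k * n_per_cluster, dim))
    X -= X.min()
    X = np.clip(X, 0.0, None)
    params = dict(kind="blobs", k=k, n_per_cluster=n_per_cluster, dim=dim,
                  separation=separation, noise_sd=noise_sd, seed=seed)
    return _wrap(X, labels, params)


def make_compositional(
    k: int = 3,
    n_per_cluster: int = 30,
    n_taxa: int = 100,
    concentration: float = 0.5,
    depth: int = 10_000,
    seed: int = 0,
    dominance: float = 20.0,
    relative: bool = True,
) -> SyntheticDataset:
    """Dirichlet-multinomial taxon counts with cluster signatures.

    Each cluster owns a contiguous block of ``n_taxa // k`` "dominant" taxa
    whose Dirichlet concentration is multiplied by ``dominance``; the
    cluster's taxon-probability vector is one Dirichlet draw over all taxa,
    and each sample is a multinomial of size ``depth`` from its cluster's
    probabilities.  A small ``concentration`` (default 0.5) yields sparse,
    strongly distinct signatures, loosely mimicking body-site abundance
    profiles.  With ``relative=True`` rows are normalized to proportions
    (sum 1); otherwise raw counts (row sums exactly ``depth``) are returned.
    Stream order: one Dirichlet per cluster, then one multinomial per sample
    in label order.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n_taxa < k:
        raise ValueError(f"need n_taxa >= k, got n_taxa={n_taxa}, k={k}")
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    block = n_taxa // k
    probs = np.empty((k, n_taxa))
    for c in range(k):
        alpha = np.full(n_taxa, concentration)
        alpha[c * block:(c + 1) * block] *= dominance
        probs[c] = rng.dirichlet(alpha)
    labels = np.repeat(np.arange(k), n_per_cluster)
    X = np.array([rng.multinomial(depth, probs[c]) for c in labels], dtype=float)
    if relative:
        X /= X.sum(axis=1, keepdims=True)
    params = dict(kind="compositional", k=k, n_per_cluster=n_per_cluster,
                  n_taxa=n_taxa, concentration=concentration, depth=depth,
                  dominance=dominance, relative=relative, seed=seed)
    ds = _wrap(X, labels, params)
    return SyntheticDataset(
        X=FeatureMatrix.from_array(
            ds.X.values, ds.X.sample_ids,
            tuple(f"taxon{j:04d}" for j in range(n_taxa)),
        ),
        labels=ds.labels, generator_params=params,
    )


def make_manifold(
    n_per_class: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
    radius_inner: float = 1.0,
    radius_outer: float = 3.0,
) -> SyntheticDataset:
    """Two concentric noisy rings in 2-D, shifted non-negative.

    The ring geometry is linearly inseparable by centroids yet trivially
    separable on a neighbourhood graph — the regime motivating graph-based
    over centroid-based clustering.  Stream order: inner angles, outer
    angles, inner noise, outer noise.
    """
    if n_per_class < 10:
        raise ValueError(f"n_per_class must be >= 10, got {n_per_class}")
    if radius_outer <= radius_inner:
        raise ValueError("radius_outer must exceed radius_inner")
    rng = np.random.default_rng(seed)
    th_in = rng.uniform(0.0, 2 * np.pi, n_per_class)
    th_out = rng.uniform(0.0, 2 * np.pi, n_per_class)
    inner = radius_inner * np.c_[np.cos(th_in), np.sin(th_in)]
    outer = radius_outer * np.c_[np.cos(th_out), np.sin(th_out)]
    inner = inner + noise_sd * rng.normal(size=inner.shape)
    outer = outer + noise_sd * rng.normal(size=outer.shape)
    X = np.vstack([inner, outer])
    labels = np.repeat([0, 1], n_per_class)
    X -= X.min()
    X = np.clip(X, 0.0, None)
    params = dict(kind="manifold", n_per_class=n_per_class, noise_sd=noise_sd,
                  radius_inner=radius_inner, radius_outer=radius_outer, seed=seed)
    return _wrap(X, labels, params)
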