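"""Clustering evaluation: accuracy under optimal matching, and NMI.

Both metrics compare two partitions through their contingency table and are
invariant to relabeling of either side.  Accuracy (AC) finds the best
one-to-one mapping between predicted and true cluster names (a linear
assignment problem, solved by the Hungarian method) and reports the matched
fraction.  Normalized mutual information (NMI) is the mutual information of
the two partitions normalized by their entropies; the geometric-mean
normalization ``MI / sqrt(H(T) H(P))`` is the default, with arithmetic and
max normalizations exposed for comparability with other conventions.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["clustering_accuracy", "nmi", "contingency"]


def _check_pair(true_labels, pred_labels) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.shape[0]} vs {p.shape[0]}")
    if t.size == 0:
        raise ValueError("need at least one sample")
    return t, p


def contingency(true_labels, pred_labels) -> np.ndarray:
    """Co-occurrence counts, rows = true clusters, columns = predicted."""
    t, p = _check_pair(true_labels, pred_labels)
    return contingency_matrix(t, p)


def clustering_accuracy(true_labels, pred_labels) -> float:
    """Fraction correct after the optimal one-to-one label matching.

    The contingency table is padded to square with zero-count dummy labels
    when the two partitions have different numbers of clusters, so the
    assignment is always one-to-one.
    """
    t, p = _check_pair(true_labels, pred_labels)
    C = contingency_matrix(t, p)
    r, c = C.shape
    size = max(r, c)
    padded = np.zeros((size, size), dtype=C.dtype)
    padded[:r, :c] = C
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum()) / t.size


def nmi(true_labels, pred_labels, normalization: str = "geometric") -> float:
    """Normalized mutual information of two partitions.

    Natural logarithms throughout (the normalization cancels the base).
    Conventions for degenerate partitions: if both sides are a single
    cluster the partitions are identical and NMI is 1; if only one side has
    zero entropy no information is shared and NMI is 0.
    """
    t, p = _check_pair(true_labels, pred_labels)
    C = contingency_matrix(t, p).astype(float)
    n = C.sum()
    pt = C.sum(axis=1) / n
    pp = C.sum(axis=0) / n

    h_t = -float(np.sum(pt * np.log(pt, where=pt > 0, out=np.zeros_like(pt))))
    h_p = -float(np.sum(pp * np.log(pp, where=pp > 0, out=np.zeros_like(pp))))
    if h_t == 0.0 and h_p == 0.0:
        return 1.0
    if h_t == 0.0 or h_p == 0.0:
        return 0.0

    nz = C > 0
    pij = C[nz] / n
    outer = np.outer(pt, pp)[nz]
    mi = float(np.sum(pij * np.log(pij / outer)))

    if normalization == "geometric":
        denom = np.sqrt(h_t * h_p)
    elif normalization == "arithmetic":
        denom = (h_t + h_p) / 2.0
    elif normalization == "max":
        denom = max(h_t, h_p)
    else:
        raise ValueError(
            f"unknown normalization {normalization!r}; "
            "choose geometric, arithmetic or max"
        )
    return float(np.clip(mi / denom, 0.0, 1.0))
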