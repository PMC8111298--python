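"""Symmetric NMF solvers with optional Laplacian and Vicus regularization.

Given a normalized affinity ``A`` the base problem is

    min_{H >= 0}  || A - H H^T ||_F^2,

whose n x k factor ``H`` acts as a soft cluster indicator (rank = number of
clusters).  The regularized objective adds graph-smoothness penalties,

    || A - H H^T ||_F^2  +  alpha * [ tr(H^T L H) + tr(H^T V H) ],

with ``L = D - P`` the (unnormalized) Laplacian of the sparsified graph and
``V`` the Vicus local-spectral operator.  Toggling the two penalty terms
yields the four method variants: plain SNMF, SNMF+Laplacian, SNMF+Vicus and
the full model (LVSNMF).

The solver is a damped multiplicative update.  With ``V = V+ - V-`` and
``L = D - P`` split into their non-negative parts, the raw rule

    h <- h * (A H + alpha (P + V-) H) / (H H^T H + alpha (D + V+) H)

preserves non-negativity and has the stationary points of the objective as
fixed points, but taken at full step length it overshoots (the quartic
reconstruction term makes the undamped rule non-monotone).  We therefore
apply it with damping beta:  ``h <- h * ((1 - beta) + beta * ratio)``, with
beta = 1/2 by default — for the unregularized problem this is the provably
monotone symmetric-NMF rule — and :func:`fit` additionally backtracks on
beta whenever a step would increase the objective, terminating when no
decrease is possible.  The fixed points are damping-independent.

Initialization is deterministic NNDSVD (non-negative sections of the
truncated SVD), which removes the need for random restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graphs import NormalizedAffinity, SimilarityGraph
from .vicus import VicusMatrix

__all__ = [
    "ALPHA_GRID",
    "FitConfig",
    "FitResult",
    "nndsvd_init",
    "snmf_step",
    "lvsnmf_step",
    "objective",
    "fit",
    "assign_clusters",
]

logger = logging.getLogger(__name__)

#: Regularization-weight grid used by parameter sweeps.
ALPHA_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 10.0)

#: Perturbation applied to exact zeros of the NNDSVD start; multiplicative
#: updates cannot escape exact zeros.
NNDSVD_ZERO_FILL = 1e-6

_EPS_DIV = 1e-12  # denominator guard inside the multiplicative ratio


@dataclass(frozen=True)
class FitConfig:
    """Solver settings for one factorization run.

    ``reg_alpha`` is the shared weight of the Laplacian and Vicus penalty
    terms (the two are weighted equally).  ``use_laplacian``/``use_vicus``
    select the model variant.  ``damping`` is the multiplicative step
    damping beta in (0, 1]; the fit loop halves it transiently whenever a
    step would increase the objective.
    """

    reg_alpha: float = 0.01
    use_laplacian: bool = True
    use_vicus: bool = True
    max_iter: int = 500
    tol: float = 1e-6
    damping: float = 0.5
    epsilon_div: float = _EPS_DIV

    def __post_init__(self) -> None:
        if self.reg_alpha < 0:
            raise ValueError(f"reg_alpha must be >= 0, got {self.reg_alpha}")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError(f"damping must lie in (0, 1], got {self.damping}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")

    @property
    def variant(self) -> str:
        return {
            (False, False): "snmf",
            (True, False): "laplacian",
            (False, True): "vicus",
            (True, True): "lvsnmf",
        }[(self.use_laplacian, self.use_vicus)]

    @classmethod
    def for_variant(cls, variant: str, **kwargs) -> "FitConfig":
        """Build a config for one of the four method variants by name."""
        table = {
            "snmf": (False, False),
            "laplacian": (True, False),
            "vicus": (False, True),
            "lvsnmf": (True, True),
        }
        if variant not in table:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(table)}")
        ul, uv = table[variant]
        return cls(use_laplacian=ul, use_vicus=uv, **kwargs)


@dataclass
class FitResult:
    """Outcome of a factorization run."""

    H: np.ndarray
    rank: int
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    labels: np.ndarray
    config: FitConfig


def _as_affinity(A) -> np.ndarray:
    return A.A if isinstance(A, NormalizedAffinity) else np.asarray(A, dtype=float)


def nndsvd_init(A, k: int) -> np.ndarray:
    """Deterministic NNDSVD start for the symmetric factorization.

    For each of the leading ``k`` singular vectors of ``A`` (sign-fixed so
    the largest-magnitude coordinate is positive) the dominant non-negative
    section is scaled by the square root of the singular value, so that
    ``H0 H0^T`` roughly tracks the best rank-k approximation of ``A``.
    Exact zeros are perturbed to :data:`NNDSVD_ZERO_FILL`.
    """
    A = _as_affinity(A)
    n = A.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"rank k={k} must satisfy 1 <= k <= n={n}")
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    H0 = np.empty((n, k))
    for j in range(k):
        x = U[:, j]
        if x[int(np.argmax(np.abs(x)))] < 0:
            x = -x
        xp = np.clip(x, 0.0, None)
        xn = np.clip(-x, 0.0, None)
        section = xp if np.linalg.norm(xp) >= np.linalg.norm(xn) else xn
        H0[:, j] = np.sqrt(s[j]) * section
    H0[H0 == 0.0] = NNDSVD_ZERO_FILL
    return H0


def _damped_ratio_step(H: np.ndarray, num: np.ndarray, den: np.ndarray,
                       damping: float, eps: float) -> np.ndarray:
    ratio = num / np.maximum(den, eps)
    return H * ((1.0 - damping) + damping * ratio)


def snmf_step(A, H: np.ndarray, damping: float = 0.5, eps: float = _EPS_DIV) -> np.ndarray:
    """One damped multiplicative update of plain symmetric NMF.

    ``h <- h * ((1 - beta) + beta * (A H) / (H H^T H))`` element-wise.
    Non-negativity is preserved; ``A = H H^T`` is a fixed point.
    """
    A = _as_affinity(A)
    num = A @ H
    den = H @ (H.T @ H)
    return _damped_ratio_step(H, num, den, damping, eps)


def _unpack_graph(P) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(P, SimilarityGraph):
        return P.W, P.degrees()
    P = np.asarray(P, dtype=float)
    return P, P.sum(axis=1)


def lvsnmf_step(
    A,
    H: np.ndarray,
    P=None,
    D: np.ndarray | None = None,
    V: VicusMatrix | None = None,
    reg_alpha: float = 0.01,
    use_laplacian: bool = True,
    use_vicus: bool = True,
    damping: float = 0.5,
    eps: float = _EPS_DIV,
) -> np.ndarray:
    """One damped multiplicative update of the regularized objective.

    ``h <- h * ((1-beta) + beta * (A H + alpha (P + V-) H)
    / (H H^T H + alpha (D + V+) H))`` with disabled terms dropped.  With
    ``reg_alpha = 0`` (or both terms disabled) this is exactly
    :func:`snmf_step` — same arithmetic, bit-identical result.

    Parameters
    ----------
    P
        Sparsified similarity graph (or its weight matrix); required when
        ``use_laplacian``.  ``D`` defaults to its row sums.
    V
        :class:`~lvsnmf.vicus.VicusMatrix`; required when ``use_vicus``.
    """
    A = _as_affinity(A)
    n = A.shape[0]
    if H.shape[0] != n:
        raise ValueError(f"H has {H.shape[0]} rows but A is {n} x {n}")
    active = reg_alpha > 0 and (use_laplacian or use_vicus)
    if not active:
        return snmf_step(A, H, damping=damping, eps=eps)

    num = A @ H
    den = H @ (H.T @ H)
    if use_laplacian:
        if P is None:
            raise ValueError("use_laplacian=True requires the graph P")
        W, deg = _unpack_graph(P)
        if W.shape != (n, n):
            raise ValueError(f"P has shape {W.shape}, expected ({n}, {n})")
        if D is not None:
            deg = np.asarray(D, dtype=float)
            if deg.shape != (n,):
                raise ValueError(f"D has shape {deg.shape}, expected ({n},)")
        num = num + reg_alpha * (W @ H)
        den = den + reg_alpha * (deg[:, None] * H)
    if use_vicus:
        if V is None:
            raise ValueError("use_vicus=True requires the Vicus matrix V")
        if V.V.shape != (n, n):
            raise ValueError(f"V has shape {V.V.shape}, expected ({n}, {n})")
        num = num + reg_alpha * (V.V_minus @ H)
        den = den + reg_alpha * (V.V_plus @ H)
    return _damped_ratio_step(H, num, den, damping, eps)


def objective(
    A,
    H: np.ndarray,
    L: np.ndarray | None = None,
    V=None,
    reg_alpha: float = 0.01,
    use_laplacian: bool = True,
    use_vicus: bool = True,
) -> float:
    """Regularized reconstruction objective at ``H``.

    ``|| A - H H^T ||_F^2 + alpha [ tr(H^T L H) + tr(H^T V H) ]`` with
    disabled terms omitted.  Both trace terms are non-negative (L and V are
    PSD), so the objective is bounded below by zero.
    """
    A = _as_affinity(A)
    R = A - H @ H.T
    val = float(np.sum(R * R))
    if reg_alpha > 0:
        if use_laplacian:
            if L is None:
                raise ValueError("use_laplacian=True requires L")
            LH = L @ H
            val += reg_alpha * float(np.sum(H * LH))
        if use_vicus:
            if V is None:
                raise ValueError("use_vicus=True requires V")
            Vmat = V.V if isinstance(V, VicusMatrix) else np.asarray(V, dtype=float)
            VH = Vmat @ H
            val += reg_alpha * float(np.sum(H * VH))
    return val


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Hard labels: per-row argmax of H, ties to the lowest column index."""
    H = np.asarray(H, dtype=float)
    zero_rows = np.flatnonzero(~H.any(axis=1))
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} sample(s) have an all-zero indicator row; "
            "assigned to cluster 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.argmax(H, axis=1)


_MIN_DAMPING = 1e-6  # backtracking floor; below this a step cannot decrease


def fit(
    A,
    G: SimilarityGraph | None = None,
    V: VicusMatrix | None = None,
    config: FitConfig | None = None,
    k: int = 2,
) -> FitResult:
    """NNDSVD-initialized damped multiplicative solver with backtracking.

    Iterates :func:`lvsnmf_step` from the deterministic NNDSVD start until
    the relative objective change drops below ``config.tol`` or
    ``config.max_iter`` is reached.  A step that would increase the
    objective is retried with halved damping; if no damping yields a
    decrease the iterate is already (numerically) stationary and the run
    stops as converged.  The recorded objective trace is therefore
    non-increasing by construction.
    """
    if config is None:
        config = FitConfig()
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    A_mat = _as_affinity(A)
    n = A_mat.shape[0]
    if k > n:
        raise ValueError(f"rank k={k} exceeds the number of samples n={n}")
    if config.use_laplacian and G is None:
        raise ValueError("variant uses the Laplacian term but no graph was given")
    if config.use_vicus and V is None:
        raise ValueError("variant uses the Vicus term but no Vicus matrix was given")

    L = None
    if config.use_laplacian and config.reg_alpha > 0:
        W, deg = _unpack_graph(G)
        L = np.diag(deg) - W

    def _obj(H: np.ndarray) -> float:
        return objective(
            A_mat, H, L=L, V=V, reg_alpha=config.reg_alpha,
            use_laplacian=config.use_laplacian, use_vicus=config.use_vicus,
        )

    H = nndsvd_init(A_mat, k)
    trace = [_obj(H)]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        damping = config.damping
        H_new = lvsnmf_step(
            A_mat, H, P=G, V=V, reg_alpha=config.reg_alpha,
            use_laplacian=config.use_laplacian, use_vicus=config.use_vicus,
            damping=damping, eps=config.epsilon_div,
        )
        obj_new = _obj(H_new)
        while obj_new > trace[-1] and damping > _MIN_DAMPING:
            damping /= 2.0
            H_new = lvsnmf_step(
                A_mat, H, P=G, V=V, reg_alpha=config.reg_alpha,
                use_laplacian=config.use_laplacian, use_vicus=config.use_vicus,
                damping=damping, eps=config.epsilon_div,
            )
            obj_new = _obj(H_new)
        if not np.isfinite(obj_new):
            raise FloatingPointError(
                f"objective became non-finite at iteration {n_iter} "
                f"(value {obj_new}); check the input affinity for scale issues"
            )
        if obj_new > trace[-1]:
            converged = True  # numerically stationary: no damping decreases
            n_iter -= 1
            break
        H = H_new
        rel_change = abs(trace[-1] - obj_new) / max(abs(trace[-1]), np.finfo(float).tiny)
        trace.append(obj_new)
        if rel_change < config.tol:
            converged = True
            break

    if not np.all(H.any(axis=0)):
        logger.warning(
            "degenerate fit: %d of %d clusters unused",
            int(k - np.count_nonzero(H.any(axis=0))), k,
        )
    labels = assign_clusters(H)
    return FitResult(
        H=H, rank=k, objective_trace=np.asarray(trace), n_iter=n_iter,
        converged=converged, labels=labels, config=config,
    )
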