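"""Kernel Mean Matching (KMM) between bulk samples and a single-cell reference.

Bulk samples and reference cells are treated as points in the d-dimensional
common-gene space. KMM estimates per-bulk-sample weights beta approximating
the density ratio p_sc(x)/p_bulk(x) by minimizing the Maximum Mean
Discrepancy between the beta-weighted bulk point cloud and the reference
point cloud in the RKHS of an RBF kernel:

    min_beta  (1/2) beta^T K_bb beta - (n_bulk/n_sc) beta^T K_bs 1
    s.t.      0 <= beta_i <= B,   |mean(beta) - 1| <= epsilon

a convex QP of dimension n_bulk. Defaults follow the method's published
configuration: B = 1000, epsilon = (n_bulk - 1)/n_bulk, and the kernel
bandwidth sigma set to the median of pairwise distances over the pooled
point set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "KmmConfig",
    "KmmResult",
    "median_bandwidth",
    "rbf_gram",
    "empirical_mmd2",
    "solve_kmm",
    "transform_bulk",
]


@dataclass
class KmmConfig:
    """Tunables of the KMM quadratic program.

    ``epsilon=None`` and ``sigma=None`` select the published defaults
    ((n_bulk-1)/n_bulk and the median pairwise-distance heuristic).
    """

    B: float = 1000.0
    epsilon: float | None = None
    sigma: float | None = None
    qp_tol: float = 1e-9
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValidationError("B must be positive")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValidationError("epsilon must be non-negative")
        if self.sigma is not None and self.sigma <= 0:
            raise ValidationError("sigma must be positive")


@dataclass
class KmmResult:
    """Estimated weights and MMD diagnostics of one KMM solve."""

    beta: np.ndarray
    mmd_before: float
    mmd_after: float
    solver_status: str
    sigma: float = float("nan")
    objective: float = float("nan")

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)


def median_bandwidth(points_bulk: np.ndarray, points_sc: np.ndarray) -> float:
    """Median Euclidean distance over all unordered pairs of the pooled
    (bulk plus reference) point set, excluding self-pairs.

    Points are columns (one bulk sample or one cell each).
    """
    pooled = np.hstack([np.atleast_2d(points_bulk), np.atleast_2d(points_sc)]).T
    if pooled.shape[0] < 2:
        raise ValidationError("need at least two pooled points for the median heuristic")
    med = float(np.median(pdist(pooled)))
    if med == 0.0:
        raise ValidationError(
            "all pooled points identical (median distance 0); pass an explicit sigma"
        )
    return med


def rbf_gram(A: np.ndarray, Bm: np.ndarray, sigma: float) -> np.ndarray:
    """RBF Gram matrix K[i, j] = exp(-||a_i - b_j||^2 / (2 sigma^2)).

    Points are columns of ``A`` (d x p) and ``Bm`` (d x q).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    Bm = np.atleast_2d(np.asarray(Bm, dtype=float))
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(Bm))):
        raise ValidationError("non-finite inputs to rbf_gram")
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if A.shape[0] != Bm.shape[0]:
        raise ValidationError("dimension mismatch between point sets")
    sq = (
        (A**2).sum(axis=0)[:, None]
        + (Bm**2).sum(axis=0)[None, :]
        - 2.0 * A.T @ Bm
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * sigma**2))


def empirical_mmd2(
    beta: np.ndarray, K_bb: np.ndarray, K_bs: np.ndarray, K_ss_mean: float
) -> float:
    """Empirical squared MMD between the beta-weighted bulk cloud and the
    reference cloud (the QP objective plus its constant term)."""
    n_b = len(beta)
    n_s = K_bs.shape[1]
    term_bb = beta @ K_bb @ beta / n_b**2
    term_bs = 2.0 * beta @ K_bs.sum(axis=1) / (n_b * n_s)
    return float(term_bb - term_bs + K_ss_mean)


def solve_kmm(
    bulk_points: np.ndarray,
    sc_points: np.ndarray,
    cfg: KmmConfig | None = None,
) -> KmmResult:
    """Solve the KMM QP for per-bulk-sample weights.

    ``bulk_points`` (d x n_bulk) and ``sc_points`` (d x n_sc) hold one
    per-column-normalized sample or cell per column over the common genes.
    """
    cfg = cfg or KmmConfig()
    bulk_points = np.atleast_2d(np.asarray(bulk_points, dtype=float))
    sc_points = np.atleast_2d(np.asarray(sc_points, dtype=float))
    n_bulk = bulk_points.shape[1]
    n_sc = sc_points.shape[1]
    if n_bulk < 1 or n_sc < 1:
        raise ValidationError("need at least one bulk sample and one reference cell")

    if n_bulk == 1:
        # the mean constraint pins a single weight to ~1: nothing to estimate
        warnings.warn("single bulk sample: KMM degenerates to beta = 1", stacklevel=2)
        sigma = cfg.sigma if cfg.sigma is not None else median_bandwidth(bulk_points, sc_points)
        K_bs = rbf_gram(bulk_points, sc_points, sigma)
        K_ss_mean = float(rbf_gram(sc_points, sc_points, sigma).mean())
        mmd = empirical_mmd2(np.ones(1), np.ones((1, 1)), K_bs, K_ss_mean)
        return KmmResult(np.ones(1), mmd, mmd, "optimal", sigma=sigma)

    sigma = cfg.sigma if cfg.sigma is not None else median_bandwidth(bulk_points, sc_points)
    epsilon = cfg.epsilon if cfg.epsilon is not None else (n_bulk - 1) / n_bulk

    K_bb = rbf_gram(bulk_points, bulk_points, sigma)
    K_bb = 0.5 * (K_bb + K_bb.T) + 1e-10 * np.eye(n_bulk)  # jitter: PD guarantee
    K_bs = rbf_gram(bulk_points, sc_points, sigma)
    K_ss_mean = float(rbf_gram(sc_points, sc_points, sigma).mean())

    kappa = (n_bulk / n_sc) * K_bs.sum(axis=1)

    def objective(b: np.ndarray) -> float:
        return 0.5 * b @ K_bb @ b - kappa @ b

    def gradient(b: np.ndarray) -> np.ndarray:
        return K_bb @ b - kappa

    def _solve(eps: float):
        cons = [
            {"type": "ineq", "fun": lambda b: eps + 1.0 - b.mean(), "jac": lambda b: -np.ones(n_bulk) / n_bulk},
            {"type": "ineq", "fun": lambda b: b.mean() - (1.0 - eps), "jac": lambda b: np.ones(n_bulk) / n_bulk},
        ]
        return minimize(
            objective,
            x0=np.ones(n_bulk),
            jac=gradient,
            bounds=[(0.0, cfg.B)] * n_bulk,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 500, "ftol": min(cfg.qp_tol, 1e-12)},
        )

    res = _solve(epsilon)
    status = "optimal"
    if not res.success:
        res = _solve(2.0 * epsilon)  # one relaxation, then give up
        status = "infeasible_relaxed"
        if not res.success:
            raise RuntimeError(f"KMM QP failed: {res.message}")

    beta = np.clip(res.x, 0.0, cfg.B)
    mmd_before = empirical_mmd2(np.ones(n_bulk), K_bb, K_bs, K_ss_mean)
    mmd_after = empirical_mmd2(beta, K_bb, K_bs, K_ss_mean)
    return KmmResult(
        beta, mmd_before, mmd_after, status, sigma=sigma, objective=float(res.fun)
    )


def transform_bulk(bulk: ExpressionMatrix, kmm: KmmResult) -> ExpressionMatrix:
    """Apply the estimated weights: column j of the output is beta_j times
    column j of the input (Y = beta * x_bulk)."""
    if len(kmm.beta) != bulk.n_columns:
        raise ValidationError(
            f"{len(kmm.beta)} weights for {bulk.n_columns} bulk columns"
        )
    return bulk.with_values(bulk.values * kmm.beta[None, :], layer_tag="kmm_transformed")
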