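"""Distances between dynamical systems and between low-rank descriptors.

The Martin distance between two systems ``(A_a, C_a)`` and ``(A_b, C_b)``
is a subspace distance on the Grassmannian of observability subspaces:

    D^2 = -2 * sum_i log(cos theta_i)

where ``theta_i`` are the principal angles between the column spaces of the
two order-L observability matrices.  Two routes to the cosines are provided:

* :func:`principal_angle_cosines` — singular values of ``Ua' Ub`` for
  orthonormal bases ``Ua, Ub`` (the standard numerically-stable route);
* :func:`principal_angle_cosines_eig` — the constrained generalized
  eigenproblem on the Gram blocks ``Oa'Oa, Ob'Ob, Oa'Ob``, kept as an
  independent cross-check of the first route.

Low-rank descriptors (denoised observability matrices) are compared either
by the same subspace distance or by plain Frobenius distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import linalg

from .lds import LDSModel, ObservabilityMatrix, observability_matrix

#: Cosines below this are clipped before the log so near-orthogonal
#: subspaces give a finite (large) distance instead of +inf.
CLIP_EPS = 1e-12


class DegenerateSubspaceError(ValueError):
    """An input matrix does not have full column rank."""


def _orth_basis(M: np.ndarray, name: str, *, allow_rank_deficient: bool = False):
    """Orthonormal basis of the column space of ``M``."""
    M = np.asarray(M, dtype=float)
    U, s, _ = linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < M.shape[1] and not allow_rank_deficient:
        raise DegenerateSubspaceError(
            f"{name} is rank-deficient: rank {rank} < {M.shape[1]} columns"
        )
    return U[:, :rank]


def principal_angle_cosines(
    Oa: np.ndarray, Ob: np.ndarray, *, allow_rank_deficient: bool = False
) -> np.ndarray:
    """Cosines of the principal angles between two column spaces.

    Returns the singular values of ``Ua' Ub`` (orthonormal bases of the two
    column spaces), clipped to [0, 1], nonincreasing.  With
    ``allow_rank_deficient`` the effective rank of each argument is used and
    ``min(rank_a, rank_b)`` cosines are returned; otherwise rank deficiency
    raises :class:`DegenerateSubspaceError` naming the argument.
    """
    Oa, Ob = np.asarray(Oa, float), np.asarray(Ob, float)
    if Oa.shape[0] != Ob.shape[0]:
        raise ValueError(
            f"row counts differ: {Oa.shape[0]} vs {Ob.shape[0]}"
        )
    Ua = _orth_basis(Oa, "first argument", allow_rank_deficient=allow_rank_deficient)
    Ub = _orth_basis(Ob, "second argument", allow_rank_deficient=allow_rank_deficient)
    cos = linalg.svd(Ua.T @ Ub, compute_uv=False)
    return np.clip(cos, 0.0, 1.0)


def principal_angle_cosines_eig(Oa: np.ndarray, Ob: np.ndarray) -> np.ndarray:
    """Principal-angle cosines via the constrained generalized eigenproblem.

    Solves

        [[0, Gab], [Gab', 0]] [x; y] = lambda [[Gaa, 0], [0, Gbb]] [x; y]

    with ``Gaa = Oa'Oa``, ``Gbb = Ob'Ob``, ``Gab = Oa'Ob`` and the
    normalization ``x'Gaa x = y'Gbb y = 1``.  The positive eigenvalues are
    the cosines.  Independent of :func:`principal_angle_cosines`; used as a
    cross-check oracle.
    """
    Oa, Ob = np.asarray(Oa, float), np.asarray(Ob, float)
    na, nb = Oa.shape[1], Ob.shape[1]
    Gaa, Gbb, Gab = Oa.T @ Oa, Ob.T @ Ob, Oa.T @ Ob
    lhs = np.block([[np.zeros((na, na)), Gab], [Gab.T, np.zeros((nb, nb))]])
    rhs = np.block([[Gaa, np.zeros((na, nb))], [np.zeros((nb, na)), Gbb]])
    w = linalg.eigh(lhs, rhs, eigvals_only=True)
    # eigenvalues come in +/- pairs; the largest min(na, nb) are the cosines
    k = min(na, nb)
    cos = np.sort(w)[::-1][:k]
    return np.clip(cos, 0.0, 1.0)


def martin_distance(
    Ma: LDSModel,
    Mb: LDSModel,
    L: int | None = None,
    *,
    pad_states: bool = False,
    return_details: bool = False,
):
    """Squared Martin distance between two fitted systems.

    Builds order-``L`` observability matrices (``L`` defaults to the state
    dimension), computes the principal-angle cosines ``lambda_i`` and
    returns ``-2 * sum_i log(max(lambda_i, eps))``.  Symmetric, zero for
    identical (or state-basis-rotated) systems.

    Parameters
    ----------
    pad_states : bool
        Models with different state dimensions are an error by default;
        with this flag the smaller system is zero-padded to the larger
        dimension (extra unobservable states).
    return_details : bool
        Also return a dict with the cosines and whether eps-clipping was
        engaged (clipped distances are finite but large).
    """
    if Ma.m != Mb.m:
        raise ValueError(
            f"incompatible channel counts: {Ma.m} vs {Mb.m}"
        )
    if Ma.n != Mb.n:
        if not pad_states:
            raise ValueError(
                f"state dimensions differ ({Ma.n} vs {Mb.n}); "
                "pass pad_states=True to zero-pad the smaller model"
            )
        n = max(Ma.n, Mb.n)
        Ma, Mb = _pad_model(Ma, n), _pad_model(Mb, n)
    if L is None:
        L = max(Ma.n, Mb.n)
    Oa = observability_matrix(Ma, L).O
    Ob = observability_matrix(Mb, L).O
    cos = principal_angle_cosines(Oa, Ob, allow_rank_deficient=True)
    clipped = bool(np.any(cos < CLIP_EPS))
    d2 = float(-2.0 * np.sum(np.log(np.maximum(cos, CLIP_EPS))))
    # identical subspaces accumulate ~eps rounding in the log; snap to zero
    d2 = 0.0 if d2 < 1e-12 else max(d2, 0.0)
    if return_details:
        return d2, {"cosines": cos, "clipped": clipped, "L": int(L)}
    return d2


def martin_distance_sqrt(Ma: LDSModel, Mb: LDSModel, L: int | None = None) -> float:
    """Convenience square root of :func:`martin_distance`."""
    return float(np.sqrt(martin_distance(Ma, Mb, L)))


def _pad_model(M: LDSModel, n: int) -> LDSModel:
    if M.n == n:
        return M
    k = n - M.n
    A = np.zeros((n, n))
    A[: M.n, : M.n] = M.A
    C = np.zeros((M.m, n))
    C[:, : M.n] = M.C
    return LDSModel(
        A=A, C=C, ybar=M.ybar, states=M.states,
        singular_values=M.singular_values, meta=dict(M.meta),
    )


def subspace_martin_distance(Da: np.ndarray, Db: np.ndarray) -> float:
    """Martin-style subspace distance between two descriptor matrices.

    ``-2 sum log cos(theta_i)`` over the principal angles between the
    column spaces of ``Da`` and ``Db`` (effective ranks; rank deficiency
    after denoising is expected and allowed).
    """
    cos = principal_angle_cosines(Da, Db, allow_rank_deficient=True)
    return max(float(-2.0 * np.sum(np.log(np.maximum(cos, CLIP_EPS)))), 0.0)


def frobenius_distance(Da: np.ndarray, Db: np.ndarray) -> float:
    """Entrywise Euclidean (Frobenius) distance between equal-shape matrices."""
    Da, Db = np.asarray(Da, float), np.asarray(Db, float)
    if Da.shape != Db.shape:
        raise ValueError(f"shape mismatch: {Da.shape} vs {Db.shape}")
    return float(np.linalg.norm(Da - Db))


def whiten_descriptors(
    descriptors: Sequence[np.ndarray], ridge: float = 1e-6
) -> list[np.ndarray]:
    """Whiten flattened descriptors by their (ridge-regularized) covariance.

    Frobenius distance on the whitened descriptors is a Mahalanobis-style
    distance with covariance estimated from the given (training) set.
    """
    V = np.stack([np.asarray(d, float).ravel() for d in descriptors])
    V = V - V.mean(axis=0)
    cov = V.T @ V / max(len(descriptors) - 1, 1)
    cov += ridge * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    Wh = linalg.inv(linalg.cholesky(cov, lower=True))
    shape = np.asarray(descriptors[0]).shape
    return [(Wh @ np.asarray(d, float).ravel()).reshape(shape) for d in descriptors]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with item bookkeeping."""

    values: np.ndarray
    item_ids: list[Any]
    metric_name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        V = np.asarray(self.values, float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError(f"distance matrix must be square, got {V.shape}")
        if np.any(np.isnan(V)):
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric within 1e-10")
        if np.any(np.diag(V) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        self.values = V


def pairwise_distances(
    items: Sequence,
    metric: str = "martin",
    *,
    L: int | None = None,
    item_ids: Sequence | None = None,
) -> DistanceMatrix:
    """Symmetric pairwise distances among models or descriptor matrices.

    ``metric='martin'`` on :class:`~lrlds.lds.LDSModel` items uses the
    squared Martin distance at order ``L``; on plain descriptor matrices it
    uses the subspace Martin distance between column spaces.
    ``metric='frobenius'`` requires equal-shape matrices (models are not
    supported).  Each unordered pair is computed once.
    """
    items = list(items)
    if not items:
        raise ValueError("empty item list")
    is_model = [isinstance(it, LDSModel) for it in items]
    if any(is_model) and not all(is_model):
        raise TypeError("heterogeneous item list: mix of models and matrices")
    models = all(is_model)
    if metric not in ("martin", "frobenius"):
        raise ValueError(f"unknown metric {metric!r}; choose 'martin' or 'frobenius'")
    if metric == "frobenius" and models:
        raise TypeError("frobenius metric applies to descriptor matrices, not models")

    N = len(items)
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            if metric == "martin" and models:
                d = martin_distance(items[i], items[j], L)
            elif metric == "martin":
                d = subspace_martin_distance(items[i], items[j])
            else:
                d = frobenius_distance(items[i], items[j])
            D[i, j] = D[j, i] = d
    ids = list(item_ids) if item_ids is not None else list(range(N))
    if len(ids) != N:
        raise ValueError("item_ids length does not match item count")
    return DistanceMatrix(
        values=D, item_ids=ids, metric_name=metric,
        params={"L": L, "clip_eps": CLIP_EPS},
    )
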