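"""Low-rank + sparse matrix decompositions by inexact ALM.

Three solvers share the same augmented-Lagrangian machinery:

* :func:`rpca_ialm` — robust PCA, ``min |L|_* + alpha |E|_1  s.t. X = L + E``;
* :func:`three_way_decompose` — the three-component signal model
  ``X = A + B + E`` where ``A`` is low-rank (event-related activity), ``B``
  is a channel-common component (resting-state background, penalized by
  ``beta * sum_{i != j} |B_i - B_j|^2`` over ordered row pairs) and ``E``
  is sparse noise;
* :func:`lrlds_features` — robust PCA applied to an observability matrix,
  yielding the denoised low-rank descriptor used for classification.

The inexact ALM alternates singular-value thresholding for the low-rank
part, entrywise soft thresholding for the sparse part (and a closed-form
row-coupled solve for ``B``), then takes one dual ascent step on the
multiplier ``lambda`` while growing the penalty ``mu`` geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import linalg
from scipy.sparse.linalg import svds

from .lds import ObservabilityMatrix


@dataclass
class ALMConfig:
    """Weights and schedule of the inexact ALM solvers.

    alpha
        Weight of the l1 (sparse) term.  ``None`` selects the standard
        RPCA default ``1 / sqrt(max(rows, cols))`` at solve time.
    beta
        Weight of the channel-common row-coupling penalty (three-way
        decomposition only; ignored by plain RPCA).
    mu0
        Initial penalty; ``None`` selects ``1.25 / sigma_max(X)``.
    rho
        Geometric growth factor of the penalty, > 1.
    tol
        Convergence tolerance on the relative constraint residual
        ``|X - parts|_F / |X|_F``.
    max_iter
        Iteration cap; hitting it returns ``converged=False``, never raises.
    seed
        Unused; kept for API uniformity with the stochastic modules.
    """

    alpha: float | None = None
    beta: float = 1.0
    mu0: float | None = None
    rho: float = 1.5
    tol: float = 1e-7
    max_iter: int = 500
    use_partial_svd: bool = False
    seed: int | None = None

    def validate(self, *, need_beta: bool = False) -> None:
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be nonnegative, got {self.beta}")
        if need_beta and not self.beta > 0:
            raise ValueError(
                "beta must be strictly positive for the three-way decomposition: "
                "with beta = 0 the B-subproblem degenerates to B = M and "
                "annihilates the low-rank and sparse parts"
            )
        if self.mu0 is not None and not self.mu0 > 0:
            raise ValueError(f"mu0 must be positive, got {self.mu0}")
        if not self.rho > 1:
            raise ValueError(f"rho must exceed 1, got {self.rho}")
        if not self.tol > 0:
            raise ValueError(f"tol must be positive, got {self.tol}")


@dataclass
class DecompositionResult:
    """Components and convergence diagnostics of an ALM decomposition."""

    lowrank: np.ndarray
    sparse: np.ndarray
    common: np.ndarray | None = None
    iterations: int = 0
    converged: bool = False
    final_residual: float = np.nan
    rank_lowrank: int = 0
    sparsity_fraction: float = 0.0
    residual_history: list[float] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)


def soft_threshold(M: np.ndarray, t: float) -> np.ndarray:
    """Entrywise shrinkage ``sign(m) * max(|m| - t, 0)``.

    The proximal operator of ``t * |.|_1``.
    """
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    M = np.asarray(M, dtype=float)
    return np.sign(M) * np.maximum(np.abs(M) - t, 0.0)


def svt(M: np.ndarray, t: float) -> np.ndarray:
    """Singular value thresholding — proximal operator of the nuclear norm.

    Shrinks every singular value of ``M`` by ``t`` (clamping at zero) and
    reassembles.
    """
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("input contains non-finite values")
    U, s, Vt = linalg.svd(M, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    return (U * s) @ Vt


def _svt_count(M: np.ndarray, t: float, use_partial: bool) -> tuple[np.ndarray, int]:
    """SVT that also reports the post-shrinkage rank.

    The partial-SVD fast path (Lanczos, top singular triplets only) is
    opt-in; the reference path uses a full SVD for bit-stable results.
    """
    if use_partial:
        k = min(M.shape) - 1
        guess = max(min(10, k), 1)
        while True:
            U, s, Vt = svds(M, k=guess)
            order = np.argsort(s)[::-1]
            U, s, Vt = U[:, order], s[order], Vt[order]
            if s[-1] <= t or guess == k:
                break
            guess = min(2 * guess, k)
        keep = s > t
        if not np.any(keep):
            return np.zeros_like(M), 0
        s = s[keep] - t
        return (U[:, keep] * s) @ Vt[keep], int(keep.sum())
    U, s, Vt = linalg.svd(M, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    return (U * s) @ Vt, int(np.sum(s > 0))


def _sigma_max(X: np.ndarray) -> float:
    return float(linalg.svd(X, compute_uv=False)[0]) if X.size else 0.0


def _default_alpha(shape: tuple[int, int]) -> float:
    return 1.0 / np.sqrt(max(shape))


def _init_lambda(X: np.ndarray, alpha: float) -> np.ndarray:
    # dual initialization lambda_0 = X / J(X), J = max(sigma_max, |X|_F / alpha)
    J = max(_sigma_max(X), np.linalg.norm(X) / alpha)
    return X / J if J > 0 else np.zeros_like(X)


def rpca_ialm(X: np.ndarray, cfg: ALMConfig | None = None) -> DecompositionResult:
    """Robust PCA ``X = L + E`` by the inexact augmented Lagrange method.

    Alternates ``L <- svt(X - E + lambda/mu, 1/mu)`` and
    ``E <- soft_threshold(X - L + lambda/mu, alpha/mu)`` with dual update
    ``lambda <- lambda + mu (X - L - E)`` and ``mu <- rho mu``.  Returns
    ``converged=False`` (never raises) if the iteration cap is hit first.
    """
    cfg = cfg or ALMConfig()
    cfg.validate()
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("input matrix is empty")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")

    alpha = cfg.alpha if cfg.alpha is not None else _default_alpha(X.shape)
    normX = np.linalg.norm(X)
    if normX == 0:
        return DecompositionResult(
            lowrank=np.zeros_like(X), sparse=np.zeros_like(X),
            iterations=0, converged=True, final_residual=0.0,
            params={"alpha": alpha, "mode": "rpca"},
        )
    mu = cfg.mu0 if cfg.mu0 is not None else 1.25 / _sigma_max(X)
    lam = _init_lambda(X, alpha)
    L = np.zeros_like(X)
    E = np.zeros_like(X)
    history: list[float] = []
    converged = False
    rank = 0
    for it in range(1, cfg.max_iter + 1):
        L, rank = _svt_count(X - E + lam / mu, 1.0 / mu, cfg.use_partial_svd)
        E = soft_threshold(X - L + lam / mu, alpha / mu)
        resid_mat = X - L - E
        lam = lam + mu * resid_mat
        mu *= cfg.rho
        resid = np.linalg.norm(resid_mat) / normX
        history.append(resid)
        if resid <= cfg.tol:
            converged = True
            break
    return DecompositionResult(
        lowrank=L, sparse=E, iterations=it, converged=converged,
        final_residual=history[-1], rank_lowrank=rank,
        sparsity_fraction=float(np.mean(E != 0)), residual_history=history,
        params={"alpha": alpha, "mode": "rpca"},
    )


def common_row_solve(M: np.ndarray, beta: float, mu: float) -> np.ndarray:
    """Closed-form minimizer of the channel-common B-subproblem.

    Solves ``min_B beta * sum_{i != j} |B_i - B_j|_F^2 + (mu/2) |M - B|_F^2``
    with the ordered-pair reading of the double sum (each unordered pair
    counted twice).  Setting the gradient per row to zero and summing over
    rows gives ``sum_i B_i = sum_i M_i``, hence the closed form

        B_i = (mu * M_i + 4 beta * sum_j M_j) / (mu + 4 beta m).
    """
    M = np.asarray(M, dtype=float)
    m = M.shape[0]
    colsum = M.sum(axis=0, keepdims=True)
    return (mu * M + 4.0 * beta * colsum) / (mu + 4.0 * beta * m)


def three_way_decompose(
    X: np.ndarray, cfg: ALMConfig | None = None
) -> DecompositionResult:
    """Decompose a trial into low-rank + channel-common + sparse parts.

    Inexact ALM on the augmented Lagrangian of

        min |A|_* + alpha |E|_1 + beta sum_{i != j} |B_i - B_j|_F^2
        s.t. X = A + B + E

    sweeping A (singular value thresholding), E (soft thresholding), then B
    (closed-form row-coupled solve, :func:`common_row_solve`), followed by
    the dual/penalty update.  ``A`` collects event-related activity, ``B``
    the across-channel-common resting background, ``E`` sparse artifacts.
    The A-vs-B split is not identifiable when the common part is itself
    low-rank (a row-constant matrix has rank 1); only the reconstruction,
    the row similarity of ``B`` and the sparsity of ``E`` are contractual.
    """
    cfg = cfg or ALMConfig()
    cfg.validate(need_beta=True)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(
            f"X must be 2-D with at least 2 rows (channels); got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")

    alpha = cfg.alpha if cfg.alpha is not None else _default_alpha(X.shape)
    normX = np.linalg.norm(X)
    if normX == 0:
        z = np.zeros_like(X)
        return DecompositionResult(
            lowrank=z, sparse=z.copy(), common=z.copy(), iterations=0,
            converged=True, final_residual=0.0,
            params={"alpha": alpha, "beta": cfg.beta, "mode": "three-way"},
        )
    mu = cfg.mu0 if cfg.mu0 is not None else 1.25 / _sigma_max(X)
    lam = _init_lambda(X, alpha)
    A = np.zeros_like(X)
    B = np.zeros_like(X)
    E = np.zeros_like(X)
    history: list[float] = []
    converged = False
    rank = 0
    for it in range(1, cfg.max_iter + 1):
        A, rank = _svt_count(X - B - E + lam / mu, 1.0 / mu, cfg.use_partial_svd)
        E = soft_threshold(X - A - B + lam / mu, alpha / mu)
        B = common_row_solve(X - A - E + lam / mu, cfg.beta, mu)
        resid_mat = X - A - B - E
        lam = lam + mu * resid_mat
        mu *= cfg.rho
        resid = np.linalg.norm(resid_mat) / normX
        history.append(resid)
        if resid <= cfg.tol:
            converged = True
            break
    return DecompositionResult(
        lowrank=A, sparse=E, common=B, iterations=it, converged=converged,
        final_residual=history[-1], rank_lowrank=rank,
        sparsity_fraction=float(np.mean(E != 0)), residual_history=history,
        params={"alpha": alpha, "beta": cfg.beta, "mode": "three-way"},
    )


def lrlds_features(
    O: ObservabilityMatrix | np.ndarray, cfg: ALMConfig | None = None
) -> DecompositionResult:
    """Low-rank descriptor of an observability matrix.

    Robust PCA of the stacked observability matrix; the low-rank part ``D``
    is the denoised subspace descriptor used by downstream classification,
    with the same column count ``n`` as the source model's state dimension.
    """
    M = O.O if isinstance(O, ObservabilityMatrix) else np.asarray(O, float)
    cfg = cfg or ALMConfig()
    if cfg.alpha is None:
        # A descriptor matrix is tall and thin (Lm x n) with decaying block
        # rows; the generic 1/sqrt(max(shape)) weight misreads most of its
        # structure as outliers, so the sparse term is priced by the small
        # dimension instead.
        cfg = replace(cfg, alpha=1.0 / np.sqrt(min(M.shape)))
    result = rpca_ialm(M, cfg)
    result.params["mode"] = "lrlds"
    return result
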