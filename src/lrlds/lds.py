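"""Closed-form linear dynamical system identification.

A trial ``Y in R^{m x tau}`` is modeled as a first-order linear Gaussian
state-space system

    x(t+1) = A x(t) + noise,        A in R^{n x n}
    y(t)   = C x(t) + noise + ybar, C in R^{m x n}, C'C = I

and identified in closed form from the SVD of the demeaned trial: the
measurement matrix ``C`` is the leading left singular vectors, the state
trajectory is ``X = Sigma V'``, and the transition matrix ``A`` is the least
squares map from ``X[:, :-1]`` to ``X[:, 1:]`` via pseudoinverse.  The pair
``(A, C)`` is the spatiotemporal feature of the trial; its order-L
observability matrix ``O = [C; CA; ...; CA^{L-1}]`` spans the subspace used
by the Martin distance downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import linalg

from .epochs import EpochSet

logger = logging.getLogger(__name__)

#: Default state dimension; classification accuracy on motor-imagery EEG
#: peaks near this value.
DEFAULT_STATE_DIM = 16

#: Relative singular-value cutoff for pseudoinverses (X1 can be
#: rank-deficient on short epochs).
PINV_RCOND = 1e-10


class DegenerateInputError(ValueError):
    """Raised when the demeaned data cannot support the requested state dim."""


@dataclass
class LDSModel:
    """Fitted linear dynamical system for one trial.

    Attributes
    ----------
    A : (n, n) transition matrix.
    C : (m, n) measurement matrix with orthonormal columns.
    ybar : (m,) per-channel temporal mean removed before the SVD.
    states : (n, tau) estimated state trajectory ``Sigma V'``.
    singular_values : (n,) leading singular values, nonincreasing.
    resid_cov_Q, resid_cov_R : empirical residual covariances of the state
        update and the observation equation; diagnostics only, never used
        by the fit.
    meta : provenance (trial index, source id, ...).
    """

    A: np.ndarray
    C: np.ndarray
    ybar: np.ndarray
    states: np.ndarray
    singular_values: np.ndarray
    resid_cov_Q: np.ndarray | None = None
    resid_cov_R: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.C.shape[0]


@dataclass
class ObservabilityMatrix:
    """Order-L observability matrix ``O = [C; CA; ...; CA^{L-1}]``.

    Its column space is an (at most) n-dimensional subspace of R^{Lm} — a
    point on a Grassmannian that identifies the system up to state-basis
    change.
    """

    O: np.ndarray
    L: int
    source_model_id: Any = None


def _fix_column_signs(U: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # SVD is sign-ambiguous per column; force the largest-magnitude entry of
    # each column of U positive so fits are reproducible bit-for-bit.
    for j in range(U.shape[1]):
        k = int(np.argmax(np.abs(U[:, j])))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
            X[j, :] = -X[j, :]
    return U, X


def estimate_transition(X: np.ndarray) -> np.ndarray:
    """Least-squares transition matrix ``A = X2 @ pinv(X1)``.

    ``X1`` drops the last state sample, ``X2`` the first; the pseudoinverse
    uses a relative cutoff because short epochs can leave ``X1``
    rank-deficient.  ``A`` minimizes ``|X2 - A X1|_F`` over all n x n
    matrices.
    """
    X = np.asarray(X, dtype=float)
    X1, X2 = X[:, :-1], X[:, 1:]
    return X2 @ linalg.pinv(X1, rtol=PINV_RCOND)


def fit_lds(
    Y: np.ndarray,
    n: int = DEFAULT_STATE_DIM,
    *,
    demean: bool = True,
    truncate_rank: bool = False,
    compute_residual_covs: bool = False,
) -> LDSModel:
    """Fit an order-``n`` linear dynamical system to one trial.

    Parameters
    ----------
    Y : (m, tau) array
        One trial, channels by samples.
    n : int
        State dimension; must satisfy ``1 <= n <= min(m, tau - 1)``.
    demean : bool
        Subtract the per-channel temporal mean before the SVD (default, the
        robust choice for signals with DC offsets).  With ``demean=False``
        the SVD factors ``Y`` directly and ``ybar`` is reported as zero;
        this raw path is exact on noiseless data whose channel means are
        zero, whereas mean removal leaves an O(1/tau) bias in ``A`` because
        a finite trajectory of a strictly stable system can never have an
        exactly zero sample mean.
    truncate_rank : bool
        When the (demeaned) trial has numerical rank below ``n``, raise
        :class:`DegenerateInputError` by default; with this flag, truncate
        ``n`` to the effective rank instead (a warning is logged).
    compute_residual_covs : bool
        Also report empirical state-update and observation residual
        covariances (diagnostics; the closed form never uses them).

    Returns
    -------
    LDSModel
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError(f"Y must be 2-D (channels x samples); got shape {Y.shape}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    m, tau = Y.shape
    n_max = min(m, tau - 1)
    if not (1 <= n <= n_max):
        raise ValueError(
            f"state dimension n={n} out of range [1, {n_max}] for shape {Y.shape}"
        )

    if demean:
        ybar = Y.mean(axis=1)
        Yd = Y - ybar[:, None]
    else:
        ybar = np.zeros(m)
        Yd = Y

    U, s, Vt = linalg.svd(Yd, full_matrices=False)
    # numerical rank of the demeaned trial
    tol = max(Yd.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    eff_rank = int(np.sum(s > tol))
    if eff_rank < n:
        if not truncate_rank:
            raise DegenerateInputError(
                f"demeaned trial has effective rank {eff_rank} < requested n={n}"
            )
        logger.warning(
            "truncating state dimension from %d to effective rank %d", n, eff_rank
        )
        n = eff_rank
        if n == 0:
            raise DegenerateInputError("demeaned trial is identically zero")

    C = U[:, :n].copy()
    X = s[:n, None] * Vt[:n, :]
    C, X = _fix_column_signs(C, X)

    A = estimate_transition(X)

    Q = R = None
    if compute_residual_covs:
        X1, X2 = X[:, :-1], X[:, 1:]
        Ew = X2 - A @ X1
        Q = (Ew @ Ew.T) / max(Ew.shape[1] - 1, 1)
        Ev = Yd - C @ X
        R = (Ev @ Ev.T) / max(Ev.shape[1] - 1, 1)

    return LDSModel(
        A=A,
        C=C,
        ybar=ybar,
        states=X,
        singular_values=s[:n].copy(),
        resid_cov_Q=Q,
        resid_cov_R=R,
    )


def observability_matrix(model: LDSModel, L: int | None = None) -> ObservabilityMatrix:
    """Stack ``[C; CA; ...; CA^{L-1}]`` into an ``(L*m, n)`` matrix.

    ``L`` defaults to the state dimension ``n``, matching the power stack
    used by the Martin-distance construction.
    """
    if L is None:
        L = model.n
    if not (isinstance(L, (int, np.integer)) and L >= 1):
        raise ValueError(f"observability order L must be a positive integer, got {L}")
    blocks = []
    block = model.C
    for _ in range(L):
        blocks.append(block)
        block = block @ model.A
    return ObservabilityMatrix(
        O=np.vstack(blocks), L=int(L), source_model_id=model.meta.get("trial")
    )


def fit_epochs(
    epochs: EpochSet,
    n: int = DEFAULT_STATE_DIM,
    *,
    demean: bool = True,
    truncate_rank: bool = False,
) -> list[LDSModel]:
    """Fit one LDS per trial; models are order-aligned with ``epochs.labels``.

    Failures on individual trials are collected and raised together as a
    single :class:`DegenerateInputError` naming the offending trial indices,
    never silently dropped.
    """
    models: list[LDSModel] = []
    failures: list[tuple[int, str]] = []
    for i in range(epochs.n_trials):
        try:
            model = fit_lds(
                epochs.data[i], n, demean=demean, truncate_rank=truncate_rank
            )
            model.meta["trial"] = i
            model.meta["label"] = int(epochs.labels[i])
            models.append(model)
        except (DegenerateInputError, ValueError) as exc:
            failures.append((i, str(exc)))
    if failures:
        detail = "; ".join(f"trial {i}: {msg}" for i, msg in failures)
        raise DegenerateInputError(
            f"{len(failures)} trial(s) could not be fitted — {detail}"
        )
    return models
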