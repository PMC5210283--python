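"""Comparison pipeline: band-pass filtering, CSP/CSSP spatial filters, LDA.

Common spatial patterns (CSP) finds spatial filters ``w`` extremizing the
variance ratio ``w' S1 w / w'(S1 + S2) w`` between two classes of
trial-averaged, trace-normalized covariances — the generalized eigenvectors
of the pencil ``(S1, S1 + S2)``.  The common spatiospectral pattern (CSSP)
is CSP run on trials augmented with a time-delayed copy of every channel,
which adds a rudimentary spectral dimension to the filters.  Features are
log-normalized variances of the filtered signals; classification uses
Fisher LDA with a pooled covariance and midpoint threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .epochs import EpochSet

logger = logging.getLogger(__name__)

#: The 21-electrode motor-cortex montage used for motor-imagery work; the
#: selection is applied only when an epoch set carries matching names.
MOTOR_MONTAGE_21 = [
    "CP6", "CP4", "CP2", "C6", "C4", "C2", "FC6", "FC4", "FC2", "CPZ",
    "CZ", "FCZ", "CP1", "CP3", "CP5", "C1", "C3", "C5", "FC1", "FC3", "FC5",
]

#: Standard motor-imagery band (alpha 8-13 Hz plus beta 14-30 Hz).
DEFAULT_BAND = (8.0, 30.0)


def bandpass_filter(
    epochs: EpochSet, low_hz: float = 8.0, high_hz: float = 30.0, order: int = 4
) -> EpochSet:
    """Zero-phase Butterworth band-pass, applied per channel per trial.

    Forward-backward (filtfilt) application cancels the phase response; the
    effective magnitude response is the square of the designed filter's.
    """
    nyq = epochs.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(
        data=np.ascontiguousarray(filtered),
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        meta={**epochs.meta, "bandpass": (low_hz, high_hz, order)},
    )


@dataclass
class CSPFilters:
    """Selected spatial filters: ``p`` pairs from the two spectrum ends."""

    W: np.ndarray                 # (m, 2p), columns are filters
    eigenvalues: np.ndarray       # 2p values in [0, 1], sorted descending
    n_pairs: int
    delay_tau: int | None = None  # present => filters were fit on CSSP-augmented data
    meta: dict = field(default_factory=dict)


def _class_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    classes = epochs.classes
    if len(classes) != 2:
        raise ValueError(
            f"CSP requires exactly 2 classes, got {len(classes)}: {classes}"
        )
    covs = []
    for c in classes:
        trials = epochs.data[epochs.labels == c]
        per_trial = []
        for Y in trials:
            S = Y @ Y.T
            tr = np.trace(S)
            if tr <= 0:
                raise ValueError("trial with zero variance cannot be normalized")
            per_trial.append(S / tr)  # trace-normalize each trial
        covs.append(np.mean(per_trial, axis=0))
    return covs[0], covs[1], classes


def csp_fit(epochs: EpochSet, n_pairs: int = 3) -> CSPFilters:
    """Fit CSP filters on a two-class epoch set.

    Solves the generalized eigenproblem ``S1 w = lambda (S1 + S2) w`` on
    the class-average normalized covariances and keeps ``n_pairs``
    eigenvectors from each end of the spectrum.  Eigenvalues lie in [0, 1]
    and the two ends pair up: ``lambda_top + lambda_bottom = 1`` under this
    convention.  A singular composite covariance is ridge-regularized with
    a logged warning.
    """
    S1, S2, classes = _class_covariances(epochs)
    m = S1.shape[0]
    if not 1 <= 2 * n_pairs <= m:
        raise ValueError(f"n_pairs={n_pairs} needs 2*n_pairs <= {m} channels")
    comp = S1 + S2
    cond = np.linalg.cond(comp)
    if not np.isfinite(cond) or cond > 1e12:
        logger.warning(
            "composite covariance ill-conditioned (cond=%.2e); ridge-regularizing",
            cond,
        )
        comp = comp + 1e-10 * np.trace(comp) / m * np.eye(m)
    w, V = linalg.eigh(S1, comp)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    idx = list(range(n_pairs)) + list(range(m - n_pairs, m))
    return CSPFilters(
        W=V[:, idx], eigenvalues=np.clip(w[idx], 0.0, 1.0), n_pairs=n_pairs,
        meta={"classes": classes.tolist()},
    )


def csp_features(epochs: EpochSet, filters: CSPFilters) -> np.ndarray:
    """Log-normalized variance features, one row per trial.

    Per trial: project onto the filters and take
    ``log(var_j / sum_j var_j)`` — scale-invariant by construction, so an
    amplitude rescaling of a trial leaves its features unchanged.
    """
    m = filters.W.shape[0]
    if epochs.n_channels != m:
        raise ValueError(
            f"channel count {epochs.n_channels} does not match filters ({m})"
        )
    Z = np.einsum("ij,tjs->tis", filters.W.T, epochs.data)
    var = Z.var(axis=-1)
    var = np.maximum(var, np.finfo(float).tiny)
    return np.log(var / var.sum(axis=1, keepdims=True))


def cssp_augment(epochs: EpochSet, tau: int) -> EpochSet:
    """Delay-embed every trial: concatenate a ``tau``-sample delayed copy.

    The channel dimension doubles and the sample count shrinks by ``tau``
    (both copies are trimmed to the overlapping window).  CSP fitted on the
    augmented set is the common spatiospectral pattern (CSSP).
    """
    T = epochs.n_samples
    if not 1 <= tau < T:
        raise ValueError(f"delay tau={tau} must satisfy 1 <= tau < {T}")
    now = epochs.data[:, :, tau:]
    delayed = epochs.data[:, :, :-tau]
    return EpochSet(
        data=np.concatenate([now, delayed], axis=1),
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        channel_names=[*epochs.channel_names,
                       *(f"{nm}-d{tau}" for nm in epochs.channel_names)],
        meta={**epochs.meta, "cssp_tau": tau},
    )


@dataclass
class LDAClassifier:
    """Fisher discriminant with pooled covariance and midpoint threshold."""

    model: LinearDiscriminantAnalysis
    classes: np.ndarray

    @property
    def coef(self) -> np.ndarray:
        return self.model.coef_.ravel()


def lda_fit(features: np.ndarray, labels: np.ndarray) -> LDAClassifier:
    """Fit a two-class Fisher LDA.

    The pooled-covariance solver yields a weight vector parallel to
    ``Sigma^-1 (mu_1 - mu_0)``; with equal priors the threshold is the
    discriminant midpoint.  A (near-)singular pooled covariance is
    shrinkage-regularized with a logged warning.
    """
    features = np.atleast_2d(np.asarray(features, float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"LDA requires exactly 2 classes, got {classes}")
    pooled = np.cov(features - _class_means(features, labels), rowvar=False)
    pooled = np.atleast_2d(pooled)
    shrinkage = None
    if features.shape[0] <= features.shape[1] or np.linalg.cond(pooled) > 1e12:
        logger.warning("pooled covariance singular or ill-conditioned; "
                       "applying shrinkage regularization")
        shrinkage = 1e-6
    lda = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage=shrinkage, priors=[0.5, 0.5]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(features, labels)
    return LDAClassifier(model=lda, classes=classes)


def _class_means(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(features)
    for c in np.unique(labels):
        mask = labels == c
        out[mask] = features[mask].mean(axis=0)
    return out


def lda_predict(clf: LDAClassifier, features: np.ndarray) -> np.ndarray:
    """Predicted labels for a feature matrix."""
    return clf.model.predict(np.atleast_2d(np.asarray(features, float)))


def lda_decision(clf: LDAClassifier, features: np.ndarray) -> np.ndarray:
    """Signed discriminant values (positive favors the larger class label)."""
    return clf.model.decision_function(np.atleast_2d(np.asarray(features, float)))
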