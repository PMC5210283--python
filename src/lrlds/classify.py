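"""Distance-based KNN classification and the five-method evaluation harness.

Training and test trials are compared under a chosen dissimilarity (Martin
distance between fitted systems, subspace or Frobenius distance between
low-rank descriptors, Euclidean distance between feature vectors) and each
test trial takes the majority label among its k nearest training trials.
Ties are broken by shrinking the neighbor set one at a time; an exact
residual tie resolves to the smallest label, which makes predictions
invariant to the ordering of the training set.

:func:`evaluate` runs any of the five end-to-end pipelines — ``csp``,
``cssp``, ``lds``, ``lr+csp``, ``lr-lds`` — fitting everything on the
training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from .baselines import (
    bandpass_filter,
    csp_features,
    csp_fit,
    cssp_augment,
    lda_decision,
    lda_fit,
    lda_predict,
)
from .epochs import EpochSet
from .lds import LDSModel, fit_epochs, observability_matrix
from .lowrank import ALMConfig, lrlds_features, three_way_decompose
from .metrics import frobenius_distance, martin_distance, subspace_martin_distance

KNOWN_METHODS = ("csp", "cssp", "lds", "lr+csp", "lr-lds")


@dataclass
class ClassifierResult:
    """Predictions plus summary statistics of one classification run."""

    predicted: np.ndarray
    accuracy: float | None
    confusion: np.ndarray | None
    k: int
    metric_name: str
    classes: np.ndarray | None = None
    params: dict[str, Any] = field(default_factory=dict)


def _confusion(true_labels, predicted, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted):
        M[idx[int(t)], idx[int(p)]] += 1
    return M


def _pair_distance(a, b, metric: str, L: int | None) -> float:
    if metric == "martin":
        if isinstance(a, LDSModel):
            return martin_distance(a, b, L)
        return subspace_martin_distance(a, b)
    if metric == "frobenius":
        return frobenius_distance(np.asarray(a, float), np.asarray(b, float))
    raise ValueError(f"unknown metric {metric!r}")


def cross_distances(
    test_items: Sequence, train_items: Sequence, metric: str, L: int | None = None
) -> np.ndarray:
    """(n_test, n_train) dissimilarity matrix between two item collections."""
    D = np.empty((len(test_items), len(train_items)))
    for i, a in enumerate(test_items):
        for j, b in enumerate(train_items):
            D[i, j] = _pair_distance(a, b, metric, L)
    return D


def knn_vote(distances: np.ndarray, train_labels: np.ndarray, k: int) -> int:
    """Majority label among the k nearest, with the shrink-on-tie rule.

    Neighbors are ordered by (distance, label) so exact distance ties are
    broken toward the smaller label; a voting tie shrinks the neighbor set
    by one until it resolves (at one neighbor it always does).  Non-finite
    distances exclude the corresponding training item.
    """
    finite = np.isfinite(distances)
    distances, labels = distances[finite], np.asarray(train_labels)[finite]
    if distances.size == 0:
        raise ValueError("no finite distances to any training item")
    order = np.lexsort((labels, distances))
    labels = labels[order]
    kk = min(k, labels.size)
    while kk > 1:
        vals, counts = np.unique(labels[:kk], return_counts=True)
        best = counts == counts.max()
        if best.sum() == 1:
            return int(vals[np.argmax(counts)])
        kk -= 1
    return int(labels[0])


def knn_predict(
    train_items: Sequence,
    train_labels: Sequence,
    test_items: Sequence,
    k: int = 1,
    metric: str = "martin",
    *,
    L: int | None = None,
    test_labels: Sequence | None = None,
) -> ClassifierResult:
    """Classify test items by k-nearest-neighbor vote under ``metric``.

    ``metric='martin'`` compares fitted systems (or descriptor column
    spaces); ``metric='frobenius'`` compares equal-shape arrays.  When
    ``test_labels`` is given, accuracy and the confusion matrix are filled
    in (confusion rows are true classes in sorted order).
    """
    train_labels = np.asarray(train_labels)
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= len(train_items)):
        raise ValueError(
            f"k={k} must be an integer in [1, {len(train_items)}]"
        )
    D = cross_distances(test_items, train_items, metric, L)
    predicted = np.array([knn_vote(D[i], train_labels, k) for i in range(len(test_items))])
    accuracy = confusion = classes = None
    if test_labels is not None:
        test_labels = np.asarray(test_labels)
        classes = np.unique(np.concatenate([train_labels, test_labels]))
        confusion = _confusion(test_labels, predicted, classes)
        accuracy = float(np.mean(predicted == test_labels))
    return ClassifierResult(
        predicted=predicted, accuracy=accuracy, confusion=confusion,
        k=int(k), metric_name=metric, classes=classes,
        params={"L": L},
    )


@dataclass
class EvalConfig:
    """Configuration of the end-to-end evaluation pipelines.

    ``n_state`` is the LDS hidden dimension; ``order_L`` the observability
    order (``None`` means equal to ``n_state``).  ``bandpass=None`` applies
    the 8-30 Hz filter for the spatial-pattern methods and leaves the LDS
    methods on raw signals, which need no preprocessing.
    """

    n_state: int = 16
    order_L: int | None = None
    k: int = 1
    metric: str = "martin"          # lr-lds descriptor metric: martin | frobenius
    demean: bool = True
    n_pairs: int = 3
    band: tuple[float, float] = (8.0, 30.0)
    butter_order: int = 4
    bandpass: bool | None = None
    cssp_tau: int | None = None
    cssp_tau_grid: tuple[int, ...] = tuple(range(1, 11))
    alm: ALMConfig = field(default_factory=ALMConfig)
    seed: int = 0


def _maybe_bandpass(epochs: EpochSet, cfg: EvalConfig, default: bool) -> EpochSet:
    apply = cfg.bandpass if cfg.bandpass is not None else default
    if not apply:
        return epochs
    return bandpass_filter(epochs, cfg.band[0], cfg.band[1], cfg.butter_order)


def _csp_lda_predict(
    train: EpochSet, test: EpochSet, cfg: EvalConfig
) -> np.ndarray:
    """CSP(+LDA) prediction; multiclass via one-vs-rest max-margin vote."""
    classes = train.classes
    if len(classes) == 2:
        filters = csp_fit(train, cfg.n_pairs)
        clf = lda_fit(csp_features(train, filters), train.labels)
        return lda_predict(clf, csp_features(test, filters))
    scores = np.empty((test.n_trials, len(classes)))
    for j, c in enumerate(classes):
        bin_train = EpochSet(
            data=train.data, labels=(train.labels == c).astype(int),
            fs=train.fs, channel_names=list(train.channel_names),
        )
        filters = csp_fit(bin_train, cfg.n_pairs)
        clf = lda_fit(csp_features(bin_train, filters), bin_train.labels)
        # decision sign: positive favors label 1, i.e. "class c"
        scores[:, j] = lda_decision(clf, csp_features(test, filters))
    return classes[np.argmax(scores, axis=1)]


def _select_cssp_tau(train: EpochSet, cfg: EvalConfig, n_folds: int = 5) -> int:
    """Pick the CSSP delay by stratified cross-validation on training data."""
    rng = np.random.default_rng(cfg.seed)
    labels = train.labels
    folds = np.zeros(train.n_trials, dtype=int)
    for c in train.classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    best_tau, best_acc = cfg.cssp_tau_grid[0], -1.0
    for tau in cfg.cssp_tau_grid:
        if tau >= train.n_samples:
            continue
        aug = cssp_augment(train, tau)
        accs = []
        for f in range(n_folds):
            tr, te = np.flatnonzero(folds != f), np.flatnonzero(folds == f)
            if len(np.unique(labels[tr])) < 2 or len(te) == 0:
                continue
            pred = _csp_lda_predict(aug.select_trials(tr), aug.select_trials(te), cfg)
            accs.append(np.mean(pred == labels[te]))
        acc = float(np.mean(accs)) if accs else -1.0
        if acc > best_acc:
            best_tau, best_acc = tau, acc
    return best_tau


def _lowrank_clean(epochs: EpochSet, cfg: EvalConfig) -> EpochSet:
    """Replace each trial by the low-rank part of its three-way decomposition."""
    alm = replace(cfg.alm)
    cleaned = np.empty_like(epochs.data)
    for i in range(epochs.n_trials):
        cleaned[i] = three_way_decompose(epochs.data[i], alm).lowrank
    return EpochSet(
        data=cleaned, labels=epochs.labels.copy(), fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        meta={**epochs.meta, "lowrank_cleaned": True},
    )


def _lds_descriptors(epochs: EpochSet, cfg: EvalConfig, denoise: bool):
    models = fit_epochs(epochs, cfg.n_state, demean=cfg.demean)
    if not denoise:
        return models
    L = cfg.order_L or cfg.n_state
    descriptors = []
    for model in models:
        O = observability_matrix(model, L)
        descriptors.append(lrlds_features(O, replace(cfg.alm)).lowrank)
    return descriptors


def evaluate(
    epochs: EpochSet,
    method: str,
    split: tuple[Sequence[int], Sequence[int]],
    config: EvalConfig | None = None,
) -> ClassifierResult:
    """Run one named pipeline end-to-end on an explicit train/test split.

    Everything — filters, decompositions, classifiers — is fitted on the
    training split only.  Overlapping splits are an error (leakage).
    """
    config = config or EvalConfig()
    if method not in KNOWN_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {KNOWN_METHODS}")
    train_idx = np.asarray(split[0], dtype=int)
    test_idx = np.asarray(split[1], dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train/test splits overlap — refusing leaky evaluation")
    for name, idx in (("train", train_idx), ("test", test_idx)):
        if idx.size == 0:
            raise ValueError(f"{name} split is empty")
        if idx.min() < 0 or idx.max() >= epochs.n_trials:
            raise ValueError(f"{name} split indices out of range")

    if method in ("csp", "cssp", "lr+csp"):
        proc = _maybe_bandpass(epochs, config, default=True)
        if method == "lr+csp":
            proc = _lowrank_clean(proc, config)
        if method == "cssp":
            tau = config.cssp_tau
            if tau is None:
                tau = _select_cssp_tau(proc.select_trials(train_idx), config)
            proc = cssp_augment(proc, tau)
        train, test = proc.select_trials(train_idx), proc.select_trials(test_idx)
        predicted = _csp_lda_predict(train, test, config)
        metric_name, k = "csp-lda", 0
    else:
        proc = _maybe_bandpass(epochs, config, default=False)
        items = _lds_descriptors(proc, config, denoise=(method == "lr-lds"))
        train_items = [items[i] for i in train_idx]
        test_items = [items[i] for i in test_idx]
        metric_name = config.metric if method == "lr-lds" else "martin"
        res = knn_predict(
            train_items, epochs.labels[train_idx], test_items,
            k=config.k, metric=metric_name,
            L=config.order_L or config.n_state,
        )
        predicted, k = res.predicted, config.k

    truth = epochs.labels[test_idx]
    classes = epochs.classes
    return ClassifierResult(
        predicted=predicted,
        accuracy=float(np.mean(predicted == truth)),
        confusion=_confusion(truth, predicted, classes),
        k=k, metric_name=metric_name, classes=classes,
        params={"method": method, "n_state": config.n_state,
                "order_L": config.order_L or config.n_state},
    )


def holdout_split(
    labels: Sequence[int], test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split, deterministic in ``seed``."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.array(train)), np.sort(np.array(test))
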