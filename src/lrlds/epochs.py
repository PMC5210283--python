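"""Epoched multichannel time-series container.

An :class:`EpochSet` is the universal input of this package: a stack of
trials, each an ``channels x samples`` matrix, with one integer class label
per trial and a common sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class EpochSet:
    """Labeled trials of multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (trials, channels, samples)
        Signal tensor. All trials share channel count, sample count and
        sampling rate.
    labels : ndarray of int, shape (trials,)
        Class label per trial.
    fs : float
        Sampling rate in Hz; must be positive.
    channel_names : list of str
        One name per channel.
    meta : dict
        Free-form provenance record (generator config, source file, ...).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"trial count {self.data.shape[0]}"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{self.n_channels} channels"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique labels."""
        return np.unique(self.labels)

    def select_trials(self, idx) -> "EpochSet":
        """Subset of trials (copy); ``idx`` is any numpy fancy index."""
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx].copy(),
            labels=self.labels[idx].copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            meta=dict(self.meta),
        )

    def select_channels(self, names: list[str]) -> "EpochSet":
        """Subset of channels by name, in the requested order."""
        missing = [nm for nm in names if nm not in self.channel_names]
        if missing:
            raise KeyError(
                f"channels {missing} not present; available: {self.channel_names}"
            )
        idx = [self.channel_names.index(nm) for nm in names]
        return EpochSet(
            data=self.data[:, idx].copy(),
            labels=self.labels.copy(),
            fs=self.fs,
            channel_names=list(names),
            meta=dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.fs == other.fs
            and self.channel_names == other.channel_names
        )
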