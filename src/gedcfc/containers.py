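"""Core data containers shared across the package.

The universal signal container is :class:`Recording` — a channels × samples
matrix with a sampling rate and channel labels. Event times (low-frequency
troughs/peaks, action potentials) are :class:`EventSeries`. Results of a
generalized eigendecomposition are a :class:`GEDResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """Multichannel continuous recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Channel time series, arbitrary units.
    fs : float
        Sampling rate in Hz.
    labels : list of str, optional
        Channel names; auto-generated ``ch00 …`` when omitted.
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite entries")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.labels:
            self.labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.labels) != self.n_channels:
            raise ValueError("labels length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.labels))


@dataclass
class EventSeries:
    """Sorted sample indices used to time-lock covariance windows."""

    samples: np.ndarray
    kind: str = "custom"  # trough | peak | spike | custom

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64).ravel()
        if self.samples.size and np.any(np.diff(self.samples) <= 0):
            raise ValueError("event samples must be strictly increasing")
        if self.samples.size and self.samples[0] < 0:
            raise ValueError("event samples must be non-negative")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class GEDResult:
    """Solution of S·W = R·W·Λ, sorted by descending eigenvalue.

    ``eigenvectors`` columns are the spatial filters w (unit Euclidean norm);
    ``forward_models`` columns are the activation patterns, i.e. columns of
    W⁻ᵀ, used for topographic interpretation.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    forward_models: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)


@dataclass
class GroundTruth:
    """Simulation ground truth enabling parameter-recovery tests."""

    source_signals: np.ndarray          # sources x samples
    mixing: np.ndarray                  # channels x sources
    driver_freq: float
    modulated_freqs: list[float]
    distractor_freqs: list[float]
    event_times: np.ndarray             # sample indices (possibly empty)
    seed: int
    fs: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.source_signals = np.asarray(self.source_signals, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=np.int64)
        if not np.all(np.isfinite(self.mixing)):
            raise ValueError("mixing matrix has non-finite entries")
        if self.mixing.shape[1] != self.source_signals.shape[0]:
            raise ValueError("mixing columns must align with source rows")
        n = self.source_signals.shape[1]
        if self.event_times.size:
            if np.any(np.diff(self.event_times) <= 0):
                raise ValueError("event_times must be sorted")
            if self.event_times[0] < 0 or self.event_times[-1] >= n:
                raise ValueError("event_times out of range")
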