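"""Methods 4 and 5: GED on time-delay-embedded matrices.

Delay embedding appends time-shifted copies of every channel as extra rows,
so eigenvector weights across the lag axis act as an empirically learned
temporal filter: the covariance contrast then yields a *spatiotemporal*
filter whose forward model, reshaped to channels × lags, is the waveform
the method discovered — without imposing sinusoidality through a
narrowband filter. Method 4 time-locks to low-frequency troughs (channel
data high-passed first so the component cannot simply reflect the
low-frequency waveform); Method 5 time-locks to action potentials,
treating spike-field coherence as event-locked CFC, and screens components
for spike artifacts via the spectral balance of their kernels.

The embedding count E includes the undelayed copy, so an E-embedding of M
channels has M·E rows (64 channels at E = 60 → 3,840 rows). For large M·E
the embedded data are projected onto their top principal components before
the GED (default cap 40 dimensions) and the filters mapped back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import gedcore as _ged
from .containers import EventSeries, Recording
from .filters import highpass
from .lowfreq import LowFreqComponent

__all__ = [
    "EmbeddedRecording", "SpatioTemporalComponent",
    "delay_embed", "embedding_resolution", "method4", "method5",
    "artifact_score", "classify_spikes",
]

DEFAULT_DIM_CAP = 40


@dataclass
class EmbeddedRecording:
    """Delay-embedded matrix with channel/lag bookkeeping.

    Row ``c + M·k`` holds channel ``c`` delayed by ``k·lag_step`` samples;
    all rows share a common support of ``samples − (E−1)·lag_step``
    columns. Column ``i`` spans original samples ``[i, i + (E−1)·lag_step]``
    and is centred on original sample ``i + (E−1)·lag_step//2``.
    """

    data: np.ndarray
    M: int
    E: int
    lag_step: int
    fs: float

    @property
    def n_rows(self) -> int:
        return self.M * self.E

    def event_columns(self, events: EventSeries) -> EventSeries:
        """Map original-time events to embedded columns (center-aligned);
        events whose windows fall outside the support are dropped later by
        the covariance routine."""
        offset = (self.E - 1) * self.lag_step // 2
        cols = events.samples - offset
        cols = cols[(cols >= 0) & (cols < self.data.shape[1])]
        return EventSeries(cols, kind=events.kind)

    def as_recording(self) -> Recording:
        labels = [f"ch{c:02d}@lag{k}" for k in range(self.E)
                  for c in range(self.M)]
        return Recording(self.data, self.fs, labels)


@dataclass
class SpatioTemporalComponent:
    """A spatiotemporal filter and its reshaped forward-model kernel.

    ``kernel`` is the forward model reshaped to channels × lags (lossless;
    ``kernel.ravel(order="F")`` recovers the forward-model vector).
    ``kernel_spectrum`` is the kernel's power spectrum along the lag axis,
    zero-padded to the requested resolution and averaged across channels.
    """

    filter: np.ndarray                  # length M*E
    forward_model: np.ndarray           # length M*E
    kernel: np.ndarray                  # M x E
    kernel_freqs: np.ndarray
    kernel_spectrum: np.ndarray
    eigenvalue: float
    artifact: bool = False
    score: float | None = None
    extras: dict = field(default_factory=dict)


def delay_embed(rec: Recording, E: int, lag_step: int = 1) -> EmbeddedRecording:
    """Stack E time-shifted copies of every channel (E includes the
    undelayed copy). Linear (equal) lag spacing keeps the kernel's Fourier
    spectrum interpretable."""
    if E < 1 or lag_step < 1:
        raise ValueError("E and lag_step must be >= 1")
    span = (E - 1) * lag_step
    if span >= rec.n_samples:
        raise ValueError("(E-1)*lag_step must be smaller than the record")
    M, n = rec.n_channels, rec.n_samples
    out_len = n - span
    data = np.empty((M * E, out_len))
    for k in range(E):
        # row c + M*k = channel c delayed by k*lag_step
        start = span - k * lag_step
        data[k * M: (k + 1) * M] = rec.data[:, start: start + out_len]
    return EmbeddedRecording(data=data, M=M, E=E, lag_step=lag_step, fs=rec.fs)


def embedding_resolution(
    fs: float, E: int, lag_step: int = 1, zero_pad_to: float | None = None
) -> tuple[float, float | None]:
    """Native and zero-padded spectral resolution of the kernel, in Hz.

    Native resolution is fs/(E·lag_step) (e.g. 1,024 Hz with 60 embeddings
    → ≈17 Hz); zero-padding refines the display grid to ``zero_pad_to``.
    """
    if E < 1 or lag_step < 1:
        raise ValueError("E and lag_step must be >= 1")
    native = fs / (E * lag_step)
    if zero_pad_to is not None:
        if zero_pad_to > native:
            raise ValueError("zero_pad_to must be finer than the native "
                             f"resolution ({native:.3f} Hz)")
        return native, float(zero_pad_to)
    return native, None


def _kernel_spectrum(
    kernel: np.ndarray, fs: float, lag_step: int, pad_to_hz: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Channel-averaged power spectrum of the kernel's lag axis, zero-padded
    to ``pad_to_hz`` resolution."""
    fs_lag = fs / lag_step
    n_fft = max(kernel.shape[1], int(round(fs_lag / pad_to_hz)))
    k = kernel - kernel.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(k, n=n_fft, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs_lag)
    return freqs, spec.mean(axis=0)


def artifact_score(comp: SpatioTemporalComponent, split_hz: float = 200.0) -> float:
    """Spectral-balance artifact screen for spike-locked components.

    Score = (mean kernel-spectrum energy above ``split_hz``) / (mean energy
    below). Genuine field-potential effects concentrate below ~200 Hz
    (score ≪ 1); broadband spike artifacts have flat or high-tilted spectra
    (score ≥ 1, flagged).
    """
    freqs, spec = comp.kernel_freqs, comp.kernel_spectrum
    if split_hz >= freqs[-1]:
        raise ValueError("split_hz is at or above the kernel-spectrum Nyquist")
    hi = spec[freqs > split_hz]
    lo = spec[(freqs > 0) & (freqs <= split_hz)]
    return float(hi.mean() / lo.mean())


def _reduced_ged(
    S: np.ndarray, R: np.ndarray, gamma: float, dim_cap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GED with optional PCA reduction; returns (eigenvalues, filters,
    forward models) in the FULL embedded space."""
    d = S.shape[0]
    if d <= dim_cap:
        res = _ged.ged(S, R, gamma)
        return res.eigenvalues, res.eigenvectors, res.forward_models
    evals, evecs = np.linalg.eigh(R)
    P = evecs[:, np.argsort(evals)[::-1][:dim_cap]]
    res = _ged.ged(P.T @ S @ P, P.T @ R @ P, gamma)
    return res.eigenvalues, P @ res.eigenvectors, P @ res.forward_models


def _make_component(
    lam: float, w: np.ndarray, a: np.ndarray, emb: EmbeddedRecording,
    pad_to_hz: float,
) -> SpatioTemporalComponent:
    kernel = a.reshape(emb.E, emb.M).T  # row c + M*k -> kernel[c, k]
    freqs, spec = _kernel_spectrum(kernel, emb.fs, emb.lag_step, pad_to_hz)
    return SpatioTemporalComponent(
        filter=w, forward_model=a, kernel=kernel,
        kernel_freqs=freqs, kernel_spectrum=spec, eigenvalue=float(lam),
    )


def method4(
    rec: Recording,
    lf: LowFreqComponent,
    events: EventSeries,
    E: int = 60,
    lag_step: int = 1,
    window_fraction: float = 0.25,
    gamma: float = 0.01,
    highpass_hz: float = 20.0,
    dim_cap: int = DEFAULT_DIM_CAP,
    pad_to_hz: float = 2.0,
) -> SpatioTemporalComponent:
    """Spatiotemporal filter from trough-locked embedded covariance.

    The channel data are high-passed (default 20 Hz) before embedding so
    the component cannot simply reflect the low-frequency waveform; S is
    the peri-event covariance of the embedded matrix, R the total embedded
    covariance. Returns the top component with its kernel and kernel
    spectrum (zero-padded to ``pad_to_hz`` resolution).
    """
    hp = Recording(highpass(rec.data, rec.fs, highpass_hz), rec.fs, rec.labels)
    emb = delay_embed(hp, E, lag_step)
    erec = emb.as_recording()
    from .methods import event_half_width

    hw = event_half_width(rec.fs, lf.band.peak, window_fraction)
    S = _ged.window_covariance(erec, emb.event_columns(events), hw)
    R = _ged.total_covariance(erec)
    evals, W, A = _reduced_ged(S, R, gamma, dim_cap)
    return _make_component(evals[0], W[:, 0], A[:, 0], emb, pad_to_hz)


def method5(
    rec: Recording,
    spikes: EventSeries,
    E: int = 60,
    lag_step: int = 1,
    window: int | None = None,
    gamma: float = 0.01,
    n_components: int = 5,
    dim_cap: int = DEFAULT_DIM_CAP,
    pad_to_hz: float = 2.0,
    split_hz: float = 200.0,
) -> list[SpatioTemporalComponent]:
    """Spike-locked spatiotemporal components with artifact screening.

    ``window`` is the full peri-spike window in samples (default: the
    embedding span, E·lag_step). Returns the ``n_components`` largest-
    eigenvalue components, each scored by :func:`artifact_score`; a warning
    is raised when every component is flagged as artifact.
    """
    if len(spikes) == 0:
        raise ValueError("spikes must be non-empty")
    emb = delay_embed(rec, E, lag_step)
    erec = emb.as_recording()
    hw = max(1, (window if window is not None else E * lag_step) // 2)
    S = _ged.window_covariance(erec, emb.event_columns(spikes), hw)
    R = _ged.total_covariance(erec)
    evals, W, A = _reduced_ged(S, R, gamma, dim_cap)
    comps = []
    for i in range(min(n_components, evals.size)):
        comp = _make_component(evals[i], W[:, i], A[:, i], emb, pad_to_hz)
        comp.score = artifact_score(comp, split_hz)
        comp.artifact = comp.score >= 1.0
        comps.append(comp)
    if all(c.artifact for c in comps):
        warnings.warn("all spike-locked components flagged as artifact",
                      stacklevel=2)
    return comps


def classify_spikes(
    spikes: EventSeries, fs: float,
    isolation_ms: float = 100.0, train_ms: float = 20.0,
) -> tuple[EventSeries, EventSeries]:
    """Split spikes into 'singlets' and 'train-starters'.

    A singlet has no other spike within ±``isolation_ms``; a train-starter
    has none within ``isolation_ms`` before but at least one within
    ``train_ms`` after. The categories are disjoint; spikes fitting neither
    are unassigned. (Their spike-locked covariances can then be contrasted
    with the Method 2 machinery on embedded data.)
    """
    s = spikes.samples
    iso = isolation_ms * fs / 1000.0
    tr = train_ms * fs / 1000.0
    singlets, starters = [], []
    for i, t in enumerate(s):
        prev_ok = i == 0 or (t - s[i - 1]) > iso
        next_gap = s[i + 1] - t if i + 1 < s.size else np.inf
        if prev_ok and next_gap > iso:
            singlets.append(t)
        elif prev_ok and next_gap <= tr:
            starters.append(t)
    return (EventSeries(np.array(singlets, dtype=np.int64), kind="spike"),
            EventSeries(np.array(starters, dtype=np.int64), kind="spike"))
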