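"""Coupling-strength measures.

* :func:`modulation_spectrum` — per narrowband center frequency, the mean
  envelope at low-frequency peaks minus the mean at troughs: a spectrum of
  phase-to-amplitude modulation.
* :func:`eventlocked_tf_power` — event-locked time-frequency power maps.
* :func:`coupling_fit` — r² and squared phase synchronization between a
  low-frequency series and a power series.
* :func:`phase_bin_power` — mean power per low-frequency phase bin.
* :func:`pacz_baseline` — the traditional single-channel phase-amplitude
  coupling z-score against a circular-shift permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EventSeries
from .filters import FilterSpec, analytic_envelope, gaussian_narrowband

__all__ = [
    "ModulationSpectrum", "PhaseBinProfile", "default_fwhm",
    "modulation_spectrum", "eventlocked_tf_power", "coupling_fit",
    "phase_bin_power", "pacz_baseline",
]


def default_fwhm(center: float) -> float:
    """Proportional narrowband width rule: FWHM = max(2 Hz, 0.15·center)."""
    return max(2.0, 0.15 * center)


@dataclass
class ModulationSpectrum:
    """Average |peak-envelope − trough-envelope| per filter frequency."""

    freqs: np.ndarray
    modulation: np.ndarray

    def argmax_freq(self) -> float:
        return float(self.freqs[int(np.argmax(self.modulation))])

    def flanking_maxima(self) -> tuple[float, float] | None:
        """Frequencies of the secondary local maxima nearest below and above
        the global maximum, or None if either side has no local maximum."""
        m = self.modulation
        i0 = int(np.argmax(m))
        interior = np.where((m[1:-1] > m[:-2]) & (m[1:-1] >= m[2:]))[0] + 1
        lower = [i for i in interior if i < i0]
        upper = [i for i in interior if i > i0]
        if not lower or not upper:
            return None
        # nearest local maxima flanking the main lobe
        lo = max(lower)
        hi = min(upper)
        return float(self.freqs[lo]), float(self.freqs[hi])


@dataclass
class PhaseBinProfile:
    """Mean power per phase bin; bins partition (−π, π]."""

    bin_centers: np.ndarray
    power: np.ndarray
    null_band: tuple[np.ndarray, np.ndarray] | None = None


def modulation_spectrum(
    comp_ts: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    lf_events: tuple[EventSeries, EventSeries] | None = None,
    fwhm: float = 4.0,
    mode: str = "cycle",
) -> ModulationSpectrum:
    """Average peak-minus-trough amplitude difference per narrowband filter.

    Two readings of the peak/trough contrast are available:

    * ``mode="cycle"`` (default): for each center frequency, the filtered
      component's own local peaks and troughs are averaged — the mean
      cycle peak-to-trough swing, ≈ 2 × the mean envelope. Amplitude
      modulation at the driver frequency places sideband lines at
      carrier ± driver frequency, so a coupled carrier shows a global
      maximum flanked by secondary maxima offset by exactly the driver
      frequency. The FWHM must be narrow enough to resolve those
      sidebands (default 4 Hz; keep below the driver frequency).
    * ``mode="lf-events"``: the filtered component's envelope is averaged
      at low-frequency peaks vs troughs (``lf_events = (troughs, peaks)``
      required); a constant-envelope input gives ≈ 0 at all frequencies.

    Invariant to the sign of ``comp_ts`` in both modes.
    """
    comp_ts = np.asarray(comp_ts, dtype=float).ravel()
    freqs = np.asarray(freqs, dtype=float).ravel()
    n = comp_ts.size
    mod = np.empty(freqs.size)
    if mode == "lf-events":
        if lf_events is None:
            raise ValueError("mode='lf-events' requires lf_events")
        troughs, peaks = lf_events
        if len(troughs) == 0 or len(peaks) == 0:
            raise ValueError("empty event set")
        tr = troughs.samples[(troughs.samples >= 0) & (troughs.samples < n)]
        pk = peaks.samples[(peaks.samples >= 0) & (peaks.samples < n)]
    elif mode != "cycle":
        raise ValueError("mode must be 'cycle' or 'lf-events'")
    for i, f in enumerate(freqs):
        filt = gaussian_narrowband(comp_ts, fs, FilterSpec(f, fwhm))
        if mode == "cycle":
            from scipy.signal import find_peaks

            up, _ = find_peaks(filt)
            dn, _ = find_peaks(-filt)
            if up.size == 0 or dn.size == 0:
                mod[i] = 0.0
                continue
            mod[i] = abs(filt[up].mean() - filt[dn].mean())
        else:
            env, _ = analytic_envelope(filt, fs)
            mod[i] = abs(env[pk].mean() - env[tr].mean())
    return ModulationSpectrum(freqs=freqs, modulation=mod)


def eventlocked_tf_power(
    comp_ts: np.ndarray,
    fs: float,
    events: EventSeries,
    freqs: np.ndarray,
    window: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (baseline-free) time-frequency power around events.

    Returns ``(tf, times)`` where ``tf`` is freqs × time, averaged over all
    events whose ±``window``-second windows fit inside the record.
    """
    comp_ts = np.asarray(comp_ts, dtype=float).ravel()
    freqs = np.asarray(freqs, dtype=float).ravel()
    hw = int(round(window * fs))
    ev = events.samples
    ev = ev[(ev - hw >= 0) & (ev + hw < comp_ts.size)]
    if ev.size == 0:
        raise ValueError("no events with full windows inside the record")
    times = np.arange(-hw, hw + 1) / fs
    tf = np.empty((freqs.size, times.size))
    for i, f in enumerate(freqs):
        env, _ = analytic_envelope(
            gaussian_narrowband(comp_ts, fs, FilterSpec(f, default_fwhm(f))), fs)
        pw = env**2
        tf[i] = np.mean([pw[t - hw: t + hw + 1] for t in ev], axis=0)
    return tf, times


def coupling_fit(
    lf_ts: np.ndarray, power_ts: np.ndarray, fs: float
) -> tuple[float, float]:
    """r² and squared phase synchronization between two series.

    r² is the squared Pearson correlation; ps is the squared magnitude of
    the mean unit phase-difference vector between the two series' analytic
    phases (insensitive to amplitude fluctuations). Both lie in [0, 1].
    """
    a = np.asarray(lf_ts, dtype=float).ravel()
    b = np.asarray(power_ts, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input series")
    r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
    _, pa = analytic_envelope(a - a.mean(), fs)
    _, pb = analytic_envelope(b - b.mean(), fs)
    ps = float(np.abs(np.mean(np.exp(1j * (pa - pb)))) ** 2)
    return r2, ps


def phase_bin_power(
    lf_phase: np.ndarray, power_ts: np.ndarray, n_bins: int = 30
) -> PhaseBinProfile:
    """Mean power as a function of low-frequency phase bin."""
    ph = np.asarray(lf_phase, dtype=float).ravel()
    pw = np.asarray(power_ts, dtype=float).ravel()
    if ph.size != pw.size:
        raise ValueError("phase and power must have equal length")
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(ph, edges[1:-1]), 0, n_bins - 1)
    power = np.full(n_bins, np.nan)
    for k in range(n_bins):
        mask = idx == k
        if mask.any():
            power[k] = pw[mask].mean()
    if np.any(np.isnan(power)):
        warnings.warn("empty phase bins recorded as missing (NaN)", stacklevel=2)
    return PhaseBinProfile(bin_centers=centers, power=power)


def pacz_baseline(
    lf_phase: np.ndarray,
    hf_power: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Traditional phase-amplitude coupling z-score (PACz).

    The observed statistic is |mean(power·e^{iφ})|; the null distribution
    is obtained by circularly shifting the power series (preserving its
    autocorrelation) and the z-score is (observed − null mean)/null SD.
    """
    ph = np.asarray(lf_phase, dtype=float).ravel()
    pw = np.asarray(hf_power, dtype=float).ravel()
    if ph.size != pw.size:
        raise ValueError("series must have equal length")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a noisy null", stacklevel=2)
    rng = np.random.default_rng(seed)
    phasor = np.exp(1j * ph)
    observed = np.abs(np.mean(pw * phasor))
    n = pw.size
    null = np.empty(n_perm)
    shifts = rng.integers(1, n, size=n_perm)
    for i, s in enumerate(shifts):
        null[i] = np.abs(np.mean(np.roll(pw, s) * phasor))
    sd = null.std()
    return float((observed - null.mean()) / sd) if sd > 0 else 0.0
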