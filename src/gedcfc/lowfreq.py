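"""Low-frequency component extraction and peak/trough detection.

The low-frequency rhythm used to time-lock every subsequent covariance
contrast is itself extracted with a GED: the signal covariance S comes from
narrowband-filtered data, the reference R either from the broadband data or
from the mean of covariances at two flanking bands (useful when broadband is
dominated by the target rhythm itself). The largest-eigenvalue spatial
filter is sign-fixed against the channel with the largest forward-model
magnitude, so "peak" and "trough" have a consistent meaning downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from . import gedcore as _ged
from .containers import EventSeries, Recording
from .filters import FilterSpec, gaussian_narrowband, narrowband_gain_energy

__all__ = ["LowFreqComponent", "extract_lf_component", "detect_extrema"]


@dataclass
class LowFreqComponent:
    """A narrowband spatial component: weights, forward model, the band-
    limited component time series, the band it was optimized for, and the
    GED eigenvalue (near 1 indicates no narrowband structure)."""

    weights: np.ndarray
    forward_model: np.ndarray
    time_series: np.ndarray
    band: FilterSpec
    eigenvalue: float
    weak: bool = False


def extract_lf_component(
    rec: Recording,
    band: FilterSpec,
    reference: str | tuple[float, float] = "broadband",
    gamma: float = 0.01,
) -> LowFreqComponent:
    """GED-based narrowband component (largest eigenvalue, sign fixed).

    ``reference`` is either ``"broadband"`` (R = total covariance of the
    unfiltered data) or a ``(lo, hi)`` pair of flanking center frequencies
    whose covariances are averaged (each filtered at the same FWHM as the
    target band). The component time series is the spatial filter applied
    to the band-filtered data, so it is band-limited and suitable for
    extremum detection.
    """
    if rec.duration * band.peak < 10:
        raise ValueError("record shorter than 10 cycles of the target band")
    narrow = gaussian_narrowband(rec.data, rec.fs, band)
    # normalize by the filter's white-noise attenuation so that eigenvalue 1
    # means "no more band power than a flat spectrum would give"
    S = _ged.total_covariance(Recording(narrow, rec.fs, rec.labels))
    S = S / narrowband_gain_energy(rec.n_samples, rec.fs, band)
    if reference == "broadband":
        R = _ged.total_covariance(rec)
    else:
        lo, hi = reference
        nyq = rec.fs / 2.0
        if not (0 < lo < nyq and 0 < hi < nyq):
            raise ValueError("flanking frequencies must lie in (0, Nyquist)")
        if lo == hi:
            raise ValueError("degenerate flanking reference (lo == hi)")
        covs = []
        for f in (lo, hi):
            fspec = FilterSpec(peak=f, fwhm=band.fwhm)
            flank = gaussian_narrowband(rec.data, rec.fs, fspec)
            cov = _ged.total_covariance(Recording(flank, rec.fs, rec.labels))
            covs.append(cov / narrowband_gain_energy(rec.n_samples, rec.fs, fspec))
        R = 0.5 * (covs[0] + covs[1])
    res = _ged.ged(S, R, gamma)
    w = res.eigenvectors[:, 0]
    a = res.forward_models[:, 0]
    ts = w @ narrow
    ts, w, a, _ = _ged.fix_sign(ts, rec, w, a, band=band)
    lam = float(res.eigenvalues[0])
    return LowFreqComponent(
        weights=w, forward_model=a, time_series=ts, band=band,
        eigenvalue=lam, weak=lam < 1.5,
    )


def detect_extrema(
    comp: LowFreqComponent,
    fs: float,
    kind: str = "trough",
    min_amplitude_sd: float | None = None,
) -> EventSeries:
    """Local minima (troughs) or maxima (peaks) of the component series.

    A refractory distance of half the nominal period prevents noise-split
    double extrema. With ``min_amplitude_sd`` set, only extrema whose
    magnitude exceeds mean + that many SDs of the extremum magnitudes are
    kept (e.g. restricting the analysis to high-amplitude cycles).
    """
    if kind not in ("trough", "peak"):
        raise ValueError("kind must be 'trough' or 'peak'")
    x = comp.time_series if kind == "peak" else -comp.time_series
    min_dist = max(1, int(round(0.5 * fs / comp.band.peak)))
    locs, props = find_peaks(x, distance=min_dist)
    if locs.size == 0:
        raise ValueError("no extrema found")
    if min_amplitude_sd is not None:
        amps = x[locs]
        thresh = amps.mean() + min_amplitude_sd * amps.std()
        locs = locs[amps > thresh]
        if locs.size == 0:
            raise ValueError("no extrema pass the amplitude screen")
    return EventSeries(locs, kind=kind)
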