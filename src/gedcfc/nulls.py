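"""Permutation null-hypothesis schemes.

Criterion-guided component fitting will find *something* even in pure
noise, so every gedCFC result should be compared against an empirical null
distribution. Three schemes are provided:

* :func:`random_event_null` — refit the method with uniformly random event
  times (count-matched to the real events) and compare a scalar statistic
  (e.g. the top eigenvalue) against the permutation distribution.
* :func:`circular_shift_null` — circularly shift one series relative to the
  other before recomputing a coupling metric; shifts preserve
  autocorrelation, and shifts smaller than one low-frequency period are
  excluded.
* :func:`bin_shuffle_null` — shuffle the phase-bin/power assignment to
  obtain a per-bin confidence band for phase-binned power profiles.

A split-half transfer utility supports the cross-validation approach: fit
the filter on one half of the events, evaluate the statistic on the other.
All schemes are seed-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .containers import EventSeries, Recording
from .lowfreq import LowFreqComponent
from .metrics import coupling_fit, phase_bin_power, PhaseBinProfile

__all__ = [
    "NullDistribution", "random_event_null", "circular_shift_null",
    "bin_shuffle_null", "split_half_transfer",
]


@dataclass
class NullDistribution:
    """Empirical null distribution of a scalar statistic."""

    values: np.ndarray
    observed: float
    alpha: float
    interval: tuple[float, float]
    scheme: str
    seed: int
    n_perm: int

    @property
    def significant(self) -> bool:
        """True when the observed statistic falls outside the interval."""
        return self.observed < self.interval[0] or self.observed > self.interval[1]

    def exceeds_upper(self) -> bool:
        return self.observed > self.interval[1]


def _interval(values: np.ndarray, alpha: float) -> tuple[float, float]:
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def random_event_null(
    rec: Recording,
    lf: LowFreqComponent,
    method_fn: Callable[[Recording, LowFreqComponent, EventSeries], object],
    events: EventSeries,
    n_perm: int = 1000,
    seed: int = 0,
    stat_fn: Callable[[object], float] = lambda c: c.eigenvalue,
    alpha: float = 0.05,
    edge_margin: int = 0,
) -> NullDistribution:
    """Refit the method with random event times and compare a statistic.

    ``method_fn(rec, lf, events)`` fits a component; ``stat_fn`` maps it to
    a scalar (top eigenvalue by default). Random "events" are uniform over
    the record (respecting ``edge_margin`` samples at each edge), with the
    same count as the real events. Permutation refits are allowed to fail
    for at most 1% of draws.
    """
    observed = float(stat_fn(method_fn(rec, lf, events)))
    rng = np.random.default_rng(seed)
    n_events = len(events)
    lo = edge_margin
    hi = rec.n_samples - edge_margin
    values = []
    failures = 0
    for _ in range(n_perm):
        rand = np.unique(rng.integers(lo, hi, size=n_events))
        while rand.size < n_events:
            extra = rng.integers(lo, hi, size=n_events - rand.size)
            rand = np.unique(np.concatenate([rand, extra]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values.append(float(stat_fn(method_fn(
                    rec, lf, EventSeries(rand, kind="custom")))))
        except Exception:
            failures += 1
    if failures > max(1, 0.01 * n_perm):
        raise RuntimeError(
            f"method refit failed in {failures}/{n_perm} permutations")
    values = np.asarray(values)
    return NullDistribution(
        values=values, observed=observed, alpha=alpha,
        interval=_interval(values, alpha), scheme="random-events",
        seed=seed, n_perm=n_perm,
    )


def circular_shift_null(
    series_a: np.ndarray,
    series_b: np.ndarray,
    metric: str = "r2",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    min_shift: int | None = None,
    fs: float = 1.0,
) -> NullDistribution:
    """Null distribution of a coupling metric under circular shifts.

    ``series_a`` is the low-frequency series, ``series_b`` the power
    series. Shifts are drawn uniformly from [min_shift, n − min_shift]
    (zero shift excluded); ``min_shift`` defaults to one period of the
    dominant frequency of ``series_a``. ``metric`` is ``"r2"`` or ``"ps"``.
    """
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if metric not in ("r2", "ps"):
        raise ValueError("metric must be 'r2' or 'ps'")
    n = a.size
    if min_shift is None:
        spec = np.abs(np.fft.rfft(a - a.mean()))
        spec[0] = 0.0
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        f = freqs[int(np.argmax(spec))]
        min_shift = int(round(fs / f)) if f > 0 else n // 10
    min_shift = max(1, min(min_shift, n // 4))
    if n < 10 * min_shift:
        warnings.warn("series shorter than 10 periods: shift space is small",
                      stacklevel=2)
    pick = {"r2": 0, "ps": 1}[metric]
    observed = coupling_fit(a, b, fs)[pick]
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_perm)
    values = np.empty(n_perm)
    for i, s in enumerate(shifts):
        values[i] = coupling_fit(np.roll(a, int(s)), b, fs)[pick]
    return NullDistribution(
        values=values, observed=float(observed), alpha=alpha,
        interval=_interval(values, alpha), scheme="circular-shift",
        seed=seed, n_perm=n_perm,
    )


def bin_shuffle_null(
    lf_phase: np.ndarray,
    power_ts: np.ndarray,
    n_bins: int = 30,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[PhaseBinProfile, np.ndarray]:
    """Per-bin confidence band from shuffling the phase/power assignment.

    Returns the observed :class:`~gedcfc.metrics.PhaseBinProfile` with its
    ``null_band`` filled in, plus a boolean array flagging bins whose
    observed mean power falls outside the band.
    """
    ph = np.asarray(lf_phase, dtype=float).ravel()
    pw = np.asarray(power_ts, dtype=float).ravel()
    profile = phase_bin_power(ph, pw, n_bins)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_bins))
    for i in range(n_perm):
        null[i] = phase_bin_power(ph, rng.permutation(pw), n_bins).power
    lo = np.nanquantile(null, alpha / 2.0, axis=0)
    hi = np.nanquantile(null, 1.0 - alpha / 2.0, axis=0)
    profile.null_band = (lo, hi)
    flagged = (profile.power < lo) | (profile.power > hi)
    return profile, flagged


def split_half_transfer(
    rec: Recording,
    lf: LowFreqComponent,
    events: EventSeries,
    method_fn: Callable[[Recording, LowFreqComponent, EventSeries], object],
    eval_fn: Callable[[object, EventSeries], float],
    seed: int = 0,
    n_folds: int = 2,
) -> list[float]:
    """Cross-validated filter transfer: fit on one event fold, evaluate on
    the rest. Returns one statistic per fold."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(events))
    folds = np.array_split(idx, n_folds)
    stats = []
    for k in range(n_folds):
        train = np.sort(events.samples[np.concatenate(
            [folds[j] for j in range(n_folds) if j != k])])
        test = np.sort(events.samples[folds[k]])
        comp = method_fn(rec, lf, EventSeries(train, kind=events.kind))
        stats.append(float(eval_fn(comp, EventSeries(test, kind=events.kind))))
    return stats
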