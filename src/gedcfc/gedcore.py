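"""Covariance estimation and the generalized eigendecomposition engine.

Every method in the framework contrasts a "signal" covariance S against a
"reference" covariance R by solving S·W = R·W·Λ. The eigenvector with the
largest eigenvalue is a spatial (or spatiotemporal) filter whose weighted
sum of channels maximizes the variance ratio wᵀSw / wᵀRw; the corresponding
column of W⁻ᵀ is the forward model (activation pattern) used for
topographic interpretation. Eigenvectors of a generalized problem are
independent but generally not orthogonal.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import linalg

from .containers import EventSeries, GEDResult, Recording
from .filters import FilterSpec, gaussian_narrowband

__all__ = [
    "window_covariance",
    "total_covariance",
    "ged",
    "apply_filter",
    "fix_sign",
    "regularize",
]

logger = logging.getLogger(__name__)


def _event_windows(
    n_samples: int, events: np.ndarray, half_width: int
) -> tuple[np.ndarray, int]:
    """Events with full windows inside the record; returns (kept, n_dropped)."""
    ok = (events - half_width >= 0) & (events + half_width < n_samples)
    return events[ok], int(np.sum(~ok))


def window_covariance(
    rec: Recording, events: EventSeries, half_width: int
) -> np.ndarray:
    """Average covariance of per-channel-centered windows around events.

    Each window spans ``[event − half_width, event + half_width]``; windows
    clipped by the record edges are discarded (count logged). Each window is
    mean-centered per channel before its covariance is computed, and the
    per-window covariances are averaged.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1 sample")
    kept, dropped = _event_windows(rec.n_samples, events.samples, half_width)
    if dropped:
        logger.info("window_covariance: discarded %d edge-clipped windows", dropped)
    if kept.size == 0:
        raise ValueError("no usable event windows (all clipped by edges)")
    d = rec.n_channels
    cov = np.zeros((d, d))
    wlen = 2 * half_width + 1
    for t in kept:
        seg = rec.data[:, t - half_width : t + half_width + 1]
        seg = seg - seg.mean(axis=1, keepdims=True)
        cov += seg @ seg.T / (wlen - 1)
    cov /= kept.size
    return 0.5 * (cov + cov.T)


def total_covariance(rec: Recording) -> np.ndarray:
    """Channel-mean-centered covariance of the full record."""
    if rec.n_samples < rec.n_channels:
        warnings.warn(
            "fewer samples than channels: covariance will be rank-deficient",
            stacklevel=2,
        )
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    cov = x @ x.T / (rec.n_samples - 1)
    return 0.5 * (cov + cov.T)


def condition_number(cov: np.ndarray) -> float:
    """Ratio of largest to smallest singular value — a covariance-quality
    diagnostic (singular matrices have condition number infinity)."""
    sv = linalg.svdvals(cov)
    smallest = sv[-1]
    return float(np.inf) if smallest == 0 else float(sv[0] / smallest)


def regularize(R: np.ndarray, gamma: float) -> np.ndarray:
    """Diagonal loading: R ← (1−γ)·R + γ·mean(eig(R))·I."""
    if gamma == 0:
        return R
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0, 1)")
    scale = np.trace(R) / R.shape[0]
    return (1.0 - gamma) * R + gamma * scale * np.eye(R.shape[0])


def ged(S: np.ndarray, R: np.ndarray, gamma: float = 0.01) -> GEDResult:
    """Solve S·W = R·W·Λ for symmetric covariance matrices S and R.

    ``gamma`` applies diagonal loading to the reference (denominator) matrix
    only. Eigenvalues are returned descending; eigenvectors are normalized
    to unit Euclidean norm and the forward models are the columns of W⁻ᵀ
    (so that Wᵀ·A = I).
    """
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    if S.shape != R.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and R must be square matrices of equal size")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ValueError("S is not symmetric")
    if not np.allclose(R, R.T, atol=1e-8 * max(1.0, np.abs(R).max())):
        raise ValueError("R is not symmetric")
    Rr = regularize(R, gamma)
    try:
        evals, evecs = linalg.eigh(S, Rr)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "generalized eigendecomposition failed — the reference matrix is "
            "(near-)singular; increase gamma (diagonal loading) or reduce "
            "dimensionality before calling ged"
        ) from err
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evecs = evecs / np.linalg.norm(evecs, axis=0, keepdims=True)
    forward = linalg.inv(evecs.T)
    return GEDResult(evals, evecs, forward)


def apply_filter(rec: Recording, w: np.ndarray) -> np.ndarray:
    """Component time series wᵀ·X over the whole record.

    Although the filter may be fit from covariances of discrete event
    windows, the component is a continuous signal covering the full record.
    ``w`` must match the row count of the data (channels, or channels×lags
    for delay-embedded recordings).
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size != rec.data.shape[0]:
        raise ValueError(
            f"filter length {w.size} != data row count {rec.data.shape[0]}"
        )
    return w @ rec.data


def fix_sign(
    component: np.ndarray,
    rec: Recording,
    weights: np.ndarray,
    forward_model: np.ndarray,
    band: FilterSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Resolve the sign indeterminacy of an eigenvector-based component.

    The forward model's largest-magnitude entry is forced positive; then the
    component is correlated with the (optionally band-filtered) data at that
    reference channel and the component + weights are flipped if the
    correlation is negative. Returns
    ``(component, weights, forward_model, flipped)``.
    """
    forward_model = np.asarray(forward_model, dtype=float).copy()
    weights = np.asarray(weights, dtype=float).copy()
    component = np.asarray(component, dtype=float).copy()
    ref = int(np.argmax(np.abs(forward_model)))
    if forward_model[ref] < 0:
        forward_model = -forward_model
    ref_ts = rec.data[ref]
    if band is not None:
        ref_ts = gaussian_narrowband(ref_ts, rec.fs, band)
    flipped = False
    if np.std(ref_ts) == 0 or np.std(component) == 0:
        warnings.warn("zero-variance reference channel; sign not fixed",
                      stacklevel=2)
        return component, weights, forward_model, flipped
    r = np.corrcoef(component, ref_ts)[0, 1]
    if r < 0:
        component = -component
        weights = -weights
        flipped = True
    return component, weights, forward_model, flipped
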