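"""Method 3: the low-frequency waveform as a bias filter on sphered data.

This is a joint-decorrelation-style procedure. Per analysis frequency, the
multichannel amplitude envelopes are extracted (filter-Hilbert) and
mean-centered, then sphered: with V, D the eigenvectors/eigenvalues of the
envelope covariance, Y = Xᵀ·V·D^−½ has identity covariance on the kept
dimensions. The low-frequency bias series b is expanded (conceptually) into
a Toeplitz matrix B whose rows are time-shifted copies of b; the
eigenvectors W of the covariance of B·Y rotate the eigenspace as
F = V·D^−½·W, and the largest-eigenvalue column of F — applied to the
NON-sphered envelopes — is the component whose power fluctuations best
match the bias waveform.

B is never materialized: cov(B·Y) = Yᵀ·(BᵀB)·Y, and BᵀB is a symmetric
Toeplitz matrix built from the autocorrelation of b, truncated at
±``max_lag`` (shifts bounded by about one bias period). Applying it is a
short FFT convolution per sphered dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .containers import Recording
from .filters import FilterSpec, analytic_envelope, gaussian_narrowband
from .metrics import coupling_fit

__all__ = ["SpheredData", "JDResult", "sphere", "method3_single_freq",
           "method3_sweep"]

_RANK_TOL = 1e-10


@dataclass
class SpheredData:
    """Sphered (whitened) power envelopes and the transform that made them."""

    Y: np.ndarray            # samples x kept_dims
    V: np.ndarray            # channels x channels eigenvectors
    D: np.ndarray            # eigenvalues (descending)
    kept_dims: int

    def unsphere_filter(self, w: np.ndarray) -> np.ndarray:
        """Map a filter from sphered space back to channel space:
        f = V·D^−½·w (defined on the kept dimensions)."""
        Vk = self.V[:, : self.kept_dims]
        Dk = self.D[: self.kept_dims]
        return Vk @ (np.asarray(w).ravel() / np.sqrt(Dk))


@dataclass
class JDResult:
    """Per-frequency joint-decorrelation result."""

    frequency: float
    filter: np.ndarray               # channel-space filter (V·D^−½·w₁)
    rotated_filters: np.ndarray      # full F = V·D^−½·W (channels x kept)
    eigenvalues: np.ndarray
    component_power: np.ndarray      # filter applied to non-sphered envelopes
    coupling_r2: float
    coupling_ps: float
    extras: dict = field(default_factory=dict)


def sphere(power_env: np.ndarray) -> SpheredData:
    """Whiten mean-centered channel envelopes by scaling their eigenvalues.

    Rank-deficient input is handled by dropping dimensions whose eigenvalue
    falls below ``1e-10`` of the largest; the covariance of the output is
    the identity on the kept dimensions.
    """
    X = np.asarray(power_env, dtype=float)
    if X.ndim != 2:
        raise ValueError("power_env must be channels x samples")
    if not np.any(X):
        raise ValueError("all-zero envelope input")
    X = X - X.mean(axis=1, keepdims=True)
    n = X.shape[1]
    cov = X @ X.T / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    kept = int(np.sum(evals > _RANK_TOL * evals[0]))
    # YᵀY/(n−1) = I on the kept dimensions by construction
    Y = X.T @ evecs[:, :kept] / np.sqrt(evals[:kept])
    return SpheredData(Y=Y, V=evecs, D=evals, kept_dims=kept)


def _dominant_period_samples(b: np.ndarray, fs: float) -> int:
    """Period of the bias series' dominant spectral component, in samples."""
    n = b.size
    spec = np.abs(np.fft.rfft(b - b.mean()))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[0] = 0.0
    f = freqs[int(np.argmax(spec))]
    if f <= 0:
        return n // 4
    return min(n // 2, int(round(fs / f)))


def _bias_gram_apply(Y: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Compute G·Y where G = BᵀB is the banded autocorrelation Toeplitz of
    the bias segment b (lags −max_lag…max_lag)."""
    b = b - b.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    acf = np.array([np.dot(b[max(0, -d): b.size - max(0, d)],
                           b[max(0, d): b.size - max(0, -d)]) for d in lags])
    # (G·Y)[j] = sum_d acf[d] Y[j+d]  -> convolution with reversed kernel
    return fftconvolve(Y, acf[::-1, None], mode="same", axes=0)


def method3_single_freq(
    rec: Recording,
    bias: np.ndarray,
    freq: float,
    fwhm: float | None = None,
    epochs: int | None = 50,
    epoch_len: float = 4.0,
    max_lag: int | None = None,
) -> JDResult:
    """Bias-filtered component at one analysis frequency.

    The record is cut into ``epochs`` epochs of ``epoch_len`` seconds
    (``epochs=None`` fits as many as the record holds); the covariance of
    B·Y is computed separately per epoch and averaged. The top eigenvector,
    rotated back to channel space, is applied to the non-sphered narrowband
    power time series; coupling of that power series with the bias is
    returned as r² (squared Pearson correlation) and ps (squared phase
    synchronization).

    The default ``fwhm`` is 2.2 × the bias's dominant frequency (at least
    4 Hz): amplitude modulation at the bias rate puts sidebands at
    carrier ± bias frequency, and the envelope can only follow the
    modulation if those sidebands pass the filter.
    """
    bias = np.asarray(bias, dtype=float).ravel()
    if bias.size != rec.n_samples:
        raise ValueError("bias length must equal the record length")
    if not 0 < freq < rec.fs / 2:
        raise ValueError("freq must lie in (0, Nyquist)")
    ep_samp = int(round(epoch_len * rec.fs))
    if epochs is None:
        epochs = rec.n_samples // ep_samp
    if epochs * ep_samp > rec.n_samples:
        raise ValueError("epochs x epoch_len exceeds the record length")
    if max_lag is None:
        max_lag = _dominant_period_samples(bias, rec.fs)
    if fwhm is None:
        fwhm = max(4.0, 2.2 * rec.fs / max_lag)

    filt = gaussian_narrowband(rec.data, rec.fs, FilterSpec(freq, fwhm))
    env, _ = analytic_envelope(filt, rec.fs)
    env = env - env.mean(axis=1, keepdims=True)
    sph = sphere(env)

    k = sph.kept_dims
    C = np.zeros((k, k))
    for e in range(epochs):
        sl = slice(e * ep_samp, (e + 1) * ep_samp)
        Ye = sph.Y[sl]
        be = bias[sl]
        Ze = _bias_gram_apply(Ye, be, min(max_lag, ep_samp // 2))
        C += Ye.T @ Ze / ep_samp
    C /= epochs
    C = 0.5 * (C + C.T)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    F = sph.V[:, :k] @ (evecs / np.sqrt(sph.D[:k])[:, None])
    f1 = F[:, 0]
    comp_power = f1 @ env
    r2, ps = coupling_fit(bias, comp_power, rec.fs)
    return JDResult(
        frequency=freq, filter=f1, rotated_filters=F, eigenvalues=evals,
        component_power=comp_power, coupling_r2=r2, coupling_ps=ps,
        extras={"max_lag": max_lag, "fwhm": fwhm},
    )


def method3_sweep(
    rec: Recording,
    bias: np.ndarray,
    freqs: np.ndarray,
    fwhm: float | None = None,
    epochs: int | None = 50,
    epoch_len: float = 4.0,
    max_lag: int | None = None,
) -> list[JDResult]:
    """Apply the bias-filter procedure over a frequency sweep.

    The bias (and hence the implicit Toeplitz structure) is the same for
    every frequency; only the narrowband envelopes change.
    """
    freqs = np.asarray(freqs, dtype=float).ravel()
    if freqs.size > 1 and np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    if max_lag is None:
        max_lag = _dominant_period_samples(np.asarray(bias).ravel(), rec.fs)
    return [
        method3_single_freq(rec, bias, float(f), fwhm=fwhm, epochs=epochs,
                            epoch_len=epoch_len, max_lag=max_lag)
        for f in freqs
    ]
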