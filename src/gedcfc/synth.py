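"""Synthetic multichannel electrophysiology with full ground truth.

Scenes emulate the standard simulation setup for validating covariance-based
CFC analyses: a handful of "signal" dipoles (a nonstationary ~6 Hz driver,
gamma sources whose amplitude follows driver phase, a phase-independent
distractor gamma) plus many correlated 1/f noise sources, all projected to
the channels through a linear mixing matrix. The recording is exactly
``mixing @ source_signals`` — no hidden nonlinearity — so parameter-recovery
tests can regenerate channels from the stored ground truth.

Four scene generators are provided:

* :func:`gen_pac_scene` — one phase-modulated gamma + a stronger
  phase-independent distractor (single-network phase-amplitude coupling).
* :func:`gen_two_network_scene` — two gamma sources modulated at opposite
  driver phases with distinct topographies.
* :func:`gen_burst_scene` — non-phase-locked gamma bursts at driver troughs.
* :func:`gen_spikefield_scene` — a 16-channel laminar probe with
  spike-locked, non-phase-locked gamma bursts and a distractor rhythm.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert

from .containers import EventSeries, GroundTruth, Recording

__all__ = [
    "NoiseSpec",
    "SceneConfig",
    "gen_pink_noise",
    "impose_correlations",
    "gen_pac_scene",
    "gen_two_network_scene",
    "gen_burst_scene",
    "gen_spikefield_scene",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of the correlated 1/f background.

    The amplitude spectrum of each source is tapered by a sigmoid that
    decays with frequency (center ``sigmoid_center`` Hz, steepness
    ``sigmoid_slope`` 1/Hz), normalized to gain 1 at 0 Hz. ``max_corr``
    bounds the magnitudes of the randomly drawn source-to-source
    correlations.
    """

    n_sources: int = 200
    max_corr: float = 0.8
    sigmoid_center: float = 10.0
    sigmoid_slope: float = 0.08
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if not 0.0 <= self.max_corr < 1.0:
            raise ValueError("max_corr must be in [0, 1)")

    def taper(self, freqs: np.ndarray) -> np.ndarray:
        """Amplitude taper at ``freqs`` (Hz); equals 1 at 0 Hz."""
        num = 1.0 + np.exp(-self.sigmoid_center * self.sigmoid_slope)
        return num / (1.0 + np.exp((freqs - self.sigmoid_center) * self.sigmoid_slope))


def gen_pink_noise(
    n_sources: int,
    n_samples: int,
    fs: float,
    spec: NoiseSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Mutually uncorrelated 1/f-like noise sources.

    Each source is the inverse Fourier transform of random complex
    coefficients (uniform real and imaginary parts), with the amplitude
    spectrum tapered by the sigmoid of ``spec`` and mirrored onto negative
    frequencies so the output is real.
    """
    if n_samples < 2 or n_sources < 1:
        raise ValueError("n_sources and n_samples must be positive (n_samples >= 2)")
    if fs <= 0:
        raise ValueError("fs must be positive")
    spec = spec or NoiseSpec(n_sources=n_sources)
    rng = np.random.default_rng(seed)
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    taper = spec.taper(freqs)
    coeffs = (
        rng.uniform(-1.0, 1.0, size=(n_sources, n_freq))
        + 1j * rng.uniform(-1.0, 1.0, size=(n_sources, n_freq))
    ) * taper
    coeffs[:, 0] = 0.0  # zero mean
    x = np.fft.irfft(coeffs, n=n_samples, axis=1)
    # normalize each source to unit variance, then apply requested amplitude
    x /= x.std(axis=1, keepdims=True)
    return spec.amplitude * x


def _random_correlation_target(
    n: int, max_corr: float, rng: np.random.Generator
) -> np.ndarray:
    """Random correlation matrix with off-diagonals bounded by ``max_corr``,
    repaired to positive semidefiniteness by eigenvalue clipping."""
    C = rng.uniform(0.0, max_corr, size=(n, n))
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    evals, evecs = np.linalg.eigh(C)
    if evals[0] < 1e-10:
        evals = np.clip(evals, 1e-10, None)
        C = evecs @ np.diag(evals) @ evecs.T
        # renormalize to unit diagonal
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        C = 0.5 * (C + C.T)
    if np.linalg.eigvalsh(C)[0] < -1e-8:
        raise RuntimeError("correlation target not PSD after repair")
    return C


def impose_correlations(
    noise: np.ndarray, max_corr: float, seed: int = 0
) -> np.ndarray:
    """Mix uncorrelated sources so their correlations match a random target.

    A random positive-semidefinite correlation matrix with off-diagonal
    magnitudes at most ``max_corr`` is drawn and imposed through its
    symmetric square root V·D^½ (V, D its eigenvectors/eigenvalues).
    """
    noise = np.asarray(noise, dtype=float)
    if noise.ndim != 2 or noise.shape[0] < 2:
        raise ValueError("noise must be 2-D with at least two sources")
    if not 0.0 <= max_corr < 1.0:
        raise ValueError("max_corr must be in [0, 1)")
    if max_corr == 0.0:
        return noise.copy()
    rng = np.random.default_rng(seed)
    n = noise.shape[0]
    C = _random_correlation_target(n, max_corr, rng)
    evals, evecs = np.linalg.eigh(C)
    evals = np.clip(evals, 0.0, None)
    # whiten the input (ZCA on its empirical covariance) before applying the
    # target's symmetric square root: the imposed correlations then match
    # the target exactly and re-applying the transform is idempotent
    x = noise - noise.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    ce, cv = np.linalg.eigh(cov)
    ce = np.clip(ce, 1e-12 * ce.max(), None)
    white = (cv / np.sqrt(ce)) @ (cv.T @ x)
    return (evecs * np.sqrt(evals)) @ (evecs.T @ white)


# --------------------------------------------------------------------------
# scene configuration and building blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Parameters shared by the scene generators.

    ``snr`` is the ratio of summed signal-source variance to summed noise
    variance at the channels; the noise mixing gain is scaled so the
    requested value is met exactly. The driver's instantaneous frequency
    follows a slow random walk within ±``freq_jitter`` of nominal and its
    amplitude within ±``amp_jitter``. The gamma envelope is
    ``baseline + depth·(1 + cos(φ − φ_pref))/2`` of the driver phase φ,
    with the trough (φ_pref = π) preferred by default.
    """

    fs: float = 1024.0
    duration: float = 120.0
    n_channels: int = 64
    driver_freq: float = 6.0
    driver_waveform: str = "nonstationary-sine"  # | gaussian-train | van-der-pol
    modulated_freqs: tuple[float, ...] = (40.0,)
    distractor_freqs: tuple[float, ...] = (50.0,)
    mod_depth: float = 1.0
    mod_baseline: float = 0.3
    preferred_phase: float = np.pi  # trough
    snr: float = 0.05
    n_noise: int = 200
    max_corr: float = 0.8
    freq_jitter: float = 0.2
    amp_jitter: float = 0.5
    # burst / spike-field parameters
    burst_freq: float = 75.0
    burst_sigma: float = 0.012  # seconds (Gaussian envelope SD)
    random_burst_phase: bool = True
    n_spikes: int = 40

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _slow_walk(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slow random fluctuation, unit SD, clipped to [-1, 1]."""
    w = gaussian_filter1d(rng.standard_normal(n), sigma=0.5 * fs, mode="wrap")
    sd = w.std()
    if sd > 0:
        w = w / (1.5 * sd)
    return np.clip(w, -1.0, 1.0)


def _driver_phase_amp(
    cfg: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated nonstationary phase and amplitude envelope of the driver."""
    n = cfg.n_samples
    f_inst = cfg.driver_freq * (1.0 + cfg.freq_jitter * _slow_walk(n, cfg.fs, rng))
    if np.any(f_inst >= cfg.fs / 2):
        raise ValueError("driver frequency violates Nyquist")
    phase = 2.0 * np.pi * np.cumsum(f_inst) / cfg.fs
    amp = 1.0 + cfg.amp_jitter * _slow_walk(n, cfg.fs, rng)
    return phase, np.clip(amp, 0.1, None)


def _van_der_pol(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Van der Pol oscillator rescaled so its fundamental matches the
    nominal driver frequency (μ = 5: strongly non-sinusoidal limit cycle).

    One limit-cycle period is integrated accurately (after discarding the
    transient) and tiled; the limit cycle is strictly periodic, so tiling
    is exact and cheap for long records.
    """
    mu = 5.0
    sol = solve_ivp(
        lambda t, y: [y[1], mu * (1 - y[0] ** 2) * y[1] - y[0]],
        (0.0, 200.0),
        [2.0, 0.0],
        max_step=0.02,
        dense_output=True,
    )
    tau = np.linspace(100.0, 200.0, 50_000)  # past the transient
    x = sol.sol(tau)[0]
    up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
    # one full period between the last two upward zero crossings
    t0, t1 = tau[up[-2]], tau[up[-1]]
    samples_per_cycle = cfg.fs / cfg.driver_freq
    n_cycle = int(round(samples_per_cycle))
    cycle = sol.sol(np.linspace(t0, t1, n_cycle, endpoint=False))[0]
    reps = int(np.ceil(cfg.n_samples / n_cycle))
    out = np.tile(cycle, reps)[: cfg.n_samples]
    return out / out.std()


def _driver_signal(
    cfg: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Driver source time series and its phase (radians, peak at 0)."""
    if cfg.driver_waveform == "nonstationary-sine":
        phase, amp = _driver_phase_amp(cfg, rng)
        return amp * np.cos(phase), np.mod(phase + np.pi, 2 * np.pi) - np.pi
    if cfg.driver_waveform == "gaussian-train":
        phase, amp = _driver_phase_amp(cfg, rng)
        kappa = 8.0  # pulse concentration: rich harmonic content
        pulses = np.exp(kappa * (np.cos(phase) - 1.0))
        pulses = pulses - pulses.mean()
        return amp * pulses, np.mod(phase + np.pi, 2 * np.pi) - np.pi
    if cfg.driver_waveform == "van-der-pol":
        x = _van_der_pol(cfg, rng)
        phase = np.angle(hilbert(x))
        return x, phase
    raise ValueError(f"unknown driver waveform {cfg.driver_waveform!r}")


def _gamma_source(
    cfg: SceneConfig,
    freq: float,
    phase: np.ndarray,
    preferred: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-modulated gamma oscillation; returns (signal, envelope)."""
    if freq >= cfg.fs / 2:
        raise ValueError("gamma frequency violates Nyquist")
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    env = cfg.mod_baseline + cfg.mod_depth * (1.0 + np.cos(phase - preferred)) / 2.0
    carrier = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return env * carrier, env


def _distractor_source(
    cfg: SceneConfig, freq: float, target_var: float, rng: np.random.Generator
) -> np.ndarray:
    """Phase-independent gamma with a slowly wandering envelope, scaled to
    ``target_var`` total variance."""
    if freq >= cfg.fs / 2:
        raise ValueError("distractor frequency violates Nyquist")
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    env = 1.0 + 0.5 * _slow_walk(n, cfg.fs, rng)
    x = np.clip(env, 0.05, None) * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return x * np.sqrt(target_var / x.var())


def _grid_positions(n_channels: int) -> np.ndarray:
    """Channel coordinates on a square grid over the unit square."""
    side = int(np.ceil(np.sqrt(n_channels)))
    gx, gy = np.meshgrid(np.linspace(0, 1, side), np.linspace(0, 1, side))
    return np.column_stack([gx.ravel(), gy.ravel()])[:n_channels]


def _gaussian_topography(
    pos: np.ndarray, center: tuple[float, float], width: float,
    floor: float = 0.0,
) -> np.ndarray:
    """Smooth 2-D Gaussian gain profile over the channel grid; ``floor``
    adds a uniform far-field term (volume conduction does not decay to
    zero within a recording array)."""
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2)) + floor


def _noise_mixing(
    n_channels: int, n_noise: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random topographies (random center/width/sign) for noise."""
    pos = _grid_positions(n_channels)
    cols = np.empty((n_channels, n_noise))
    for j in range(n_noise):
        c = rng.uniform(-0.2, 1.2, size=2)
        w = rng.uniform(0.1, 0.4)
        cols[:, j] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5) * \
            _gaussian_topography(pos, tuple(c), w)
    return cols


def _calibrate_snr(
    sig_mix: np.ndarray,
    sig_src: np.ndarray,
    noise_mix: np.ndarray,
    noise_src: np.ndarray,
    snr: float,
) -> np.ndarray:
    """Scale the noise mixing so channel-summed signal/noise variance = snr."""
    sig_var = (sig_mix @ sig_src).var(axis=1).sum()
    noise_var = (noise_mix @ noise_src).var(axis=1).sum()
    return noise_mix * np.sqrt(sig_var / (snr * noise_var))


def _detect_troughs(driver_phase: np.ndarray) -> np.ndarray:
    """Samples where the driver phase crosses π (the waveform trough)."""
    wrapped = np.mod(driver_phase, 2 * np.pi)  # trough at π
    cross = np.where((wrapped[:-1] < np.pi) & (wrapped[1:] >= np.pi))[0]
    return cross.astype(np.int64)


def _assemble(
    cfg: SceneConfig,
    sig_src: np.ndarray,
    sig_mix: np.ndarray,
    seed: int,
    *,
    event_times: np.ndarray | None = None,
    modulated: list[float] | None = None,
    distractors: list[float] | None = None,
    extras: dict | None = None,
    noise_seed_offset: int = 1,
) -> tuple[Recording, GroundTruth]:
    """Add correlated 1/f noise, calibrate SNR, mix, and package."""
    noise = gen_pink_noise(
        cfg.n_noise, cfg.n_samples, cfg.fs,
        NoiseSpec(n_sources=cfg.n_noise, max_corr=cfg.max_corr),
        seed=seed + noise_seed_offset,
    )
    noise = impose_correlations(noise, cfg.max_corr, seed=seed + noise_seed_offset)
    rng = np.random.default_rng(seed + 2 * noise_seed_offset + 7)
    noise_mix = _noise_mixing(cfg.n_channels, cfg.n_noise, rng)
    noise_mix = _calibrate_snr(sig_mix, sig_src, noise_mix, noise, cfg.snr)

    sources = np.vstack([sig_src, noise])
    mixing = np.hstack([sig_mix, noise_mix])
    rec = Recording(mixing @ sources, cfg.fs)
    gt = GroundTruth(
        source_signals=sources,
        mixing=mixing,
        driver_freq=cfg.driver_freq,
        modulated_freqs=list(modulated or []),
        distractor_freqs=list(distractors or []),
        event_times=event_times if event_times is not None else np.array([], dtype=np.int64),
        seed=seed,
        fs=cfg.fs,
        extras={"n_signal_sources": sig_src.shape[0], **(extras or {})},
    )
    return rec, gt


# --------------------------------------------------------------------------
# scenes
# --------------------------------------------------------------------------

def gen_pac_scene(
    config: SceneConfig | None = None, seed: int = 0
) -> tuple[Recording, GroundTruth]:
    """Single-network phase-amplitude coupling scene.

    Three signal dipoles with overlapping (but distinct) scalp topographies:
    a nonstationary driver, one gamma source whose amplitude follows driver
    phase, and one phase-independent distractor gamma carrying twice the
    modulated source's power. Correlated 1/f noise is added at the channel
    SNR stated in the config.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    driver, phase = _driver_signal(cfg, rng)
    mod_f = cfg.modulated_freqs[0]
    gamma, env = _gamma_source(cfg, mod_f, phase, cfg.preferred_phase, rng)

    pos = _grid_positions(cfg.n_channels)
    cols = [
        _gaussian_topography(pos, (0.50, 0.62), 0.24, floor=0.05),  # driver
        _gaussian_topography(pos, (0.38, 0.78), 0.18, floor=0.05),  # mod gamma
    ]
    srcs = [driver, gamma]
    extras = {"driver_phase": phase, "gamma_envelope": env,
              "driver_index": 0, "modulated_index": 1}
    distractors: list[float] = []
    if cfg.distractor_freqs:
        dis_f = cfg.distractor_freqs[0]
        srcs.append(_distractor_source(cfg, dis_f, 2.0 * gamma.var(), rng))
        cols.append(_gaussian_topography(pos, (0.62, 0.78), 0.18, floor=0.05))
        extras["distractor_index"] = 2
        distractors = [dis_f]
    sig_mix = np.column_stack(cols)
    sig_src = np.vstack(srcs)
    troughs = _detect_troughs(phase)
    return _assemble(
        cfg, sig_src, sig_mix, seed,
        event_times=troughs,
        modulated=[mod_f], distractors=distractors,
        extras=extras,
    )


def gen_two_network_scene(
    config: SceneConfig | None = None, seed: int = 0
) -> tuple[Recording, GroundTruth]:
    """Two gamma networks modulated at opposite driver phases.

    Source 1 (default 40 Hz) peaks at the driver trough, source 2 (default
    45 Hz) at the driver peak; their topographies are distinct — the
    separability the trough-vs-peak covariance contrast relies on.
    """
    cfg = config or SceneConfig(modulated_freqs=(40.0, 45.0), distractor_freqs=())
    if len(cfg.modulated_freqs) != 2:
        cfg = replace(cfg, modulated_freqs=(40.0, 45.0))
    rng = np.random.default_rng(seed)
    driver, phase = _driver_signal(cfg, rng)
    f1, f2 = cfg.modulated_freqs
    g1, env1 = _gamma_source(cfg, f1, phase, cfg.preferred_phase, rng)
    g2, env2 = _gamma_source(cfg, f2, phase, cfg.preferred_phase + np.pi, rng)

    pos = _grid_positions(cfg.n_channels)
    cols = [
        _gaussian_topography(pos, (0.50, 0.60), 0.24, floor=0.05),
        _gaussian_topography(pos, (0.40, 0.80), 0.20, floor=0.05),
        _gaussian_topography(pos, (0.60, 0.80), 0.20, floor=0.05),
    ]
    if np.allclose(cols[1], cols[2]):
        import warnings

        warnings.warn("identical mixing columns for the two gamma sources "
                      "violate the peri-peak/peri-trough separability "
                      "assumption", stacklevel=2)
    sig_mix = np.column_stack(cols)
    sig_src = np.vstack([driver, g1, g2])
    troughs = _detect_troughs(phase)
    return _assemble(
        cfg, sig_src, sig_mix, seed,
        event_times=troughs,
        modulated=[f1, f2], distractors=[],
        extras={"driver_phase": phase, "envelope_1": env1, "envelope_2": env2,
                "driver_index": 0},
    )


def _burst_train(
    cfg: SceneConfig,
    centers: np.ndarray,
    freq: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of Gaussian-windowed oscillatory bursts at the given samples,
    each with an independently random carrier phase (unless disabled)."""
    n = cfg.n_samples
    out = np.zeros(n)
    half = int(round(4 * cfg.burst_sigma * cfg.fs))
    t_loc = np.arange(-half, half + 1) / cfg.fs
    envelope = np.exp(-0.5 * (t_loc / cfg.burst_sigma) ** 2)
    for c in centers:
        ph = rng.uniform(0, 2 * np.pi) if cfg.random_burst_phase else 0.0
        burst = envelope * np.cos(2 * np.pi * freq * t_loc + ph)
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > n:
            continue
        out[lo:hi] += burst
    return out


def gen_burst_scene(
    config: SceneConfig | None = None, seed: int = 0
) -> tuple[Recording, GroundTruth]:
    """Bursts of high-frequency activity time-locked to driver troughs.

    Each burst's carrier phase is drawn independently (an "induced", non-
    phase-locked response) unless ``config.random_burst_phase`` is False.
    A phase-independent 50 Hz distractor and correlated 1/f noise are added.
    """
    cfg = config or SceneConfig(burst_freq=75.0, distractor_freqs=(50.0,))
    if 2.0 * 4 * cfg.burst_sigma > 1.0 / cfg.driver_freq:
        raise ValueError("burst duration exceeds one driver period")
    rng = np.random.default_rng(seed)
    driver, phase = _driver_signal(cfg, rng)
    troughs = _detect_troughs(phase)
    bursts = _burst_train(cfg, troughs, cfg.burst_freq, rng)
    dis_f = cfg.distractor_freqs[0] if cfg.distractor_freqs else 50.0
    distractor = _distractor_source(cfg, dis_f, 2.0 * max(bursts.var(), 1e-12), rng)

    pos = _grid_positions(cfg.n_channels)
    sig_mix = np.column_stack([
        _gaussian_topography(pos, (0.50, 0.60), 0.22, floor=0.05),
        _gaussian_topography(pos, (0.38, 0.82), 0.17, floor=0.05),
        _gaussian_topography(pos, (0.62, 0.82), 0.17, floor=0.05),
    ])
    sig_src = np.vstack([driver, bursts, distractor])
    return _assemble(
        cfg, sig_src, sig_mix, seed,
        event_times=troughs,
        modulated=[cfg.burst_freq], distractors=[dis_f],
        extras={"driver_phase": phase, "burst_source_index": 1,
                "driver_index": 0},
    )


def _rugged_gains(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Laminar gain vector with sign flips between adjacent channels —
    deliberately non-smooth across depth."""
    g = rng.uniform(0.3, 1.0, size=n_channels)
    signs = rng.choice([-1.0, 1.0], size=n_channels)
    # guarantee at least one adjacent sign flip
    if np.all(signs[:-1] == signs[1:]):
        signs[n_channels // 2] *= -1.0
    return g * signs


def gen_spikefield_scene(
    config: SceneConfig | None = None, seed: int = 0
) -> tuple[Recording, EventSeries, GroundTruth]:
    """Laminar-probe spike-field scene.

    Sixteen channels by default; ``n_spikes`` (default 40) spikes at random
    times, each centered on a 70 Hz gamma burst with per-spike random
    carrier phase projected through a "rugged" (non-smooth, sign-flipping)
    laminar gain vector; a 75 Hz distractor uncorrelated with the spikes;
    correlated 1/f noise.
    """
    cfg = config or SceneConfig(
        n_channels=16, duration=40.0, burst_freq=70.0,
        distractor_freqs=(75.0,), n_noise=48, snr=0.2,
    )
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    half = int(round(4 * cfg.burst_sigma * cfg.fs))
    margin = half + 1
    min_gap = 2 * half + 1
    # rejection-sample spike times with a minimum separation
    spikes: list[int] = []
    for _ in range(10_000):
        if len(spikes) == cfg.n_spikes:
            break
        cand = int(rng.integers(margin, n - margin))
        if all(abs(cand - s) >= min_gap for s in spikes):
            spikes.append(cand)
    else:
        logger.warning("spike placement: overlapping bursts will be summed")
    spike_arr = np.array(sorted(spikes), dtype=np.int64)

    bursts = _burst_train(cfg, spike_arr, cfg.burst_freq, rng)
    dis_f = cfg.distractor_freqs[0] if cfg.distractor_freqs else 75.0
    distractor = _distractor_source(cfg, dis_f, 2.0 * max(bursts.var(), 1e-12), rng)

    rugged = _rugged_gains(cfg.n_channels, rng)
    depth = np.linspace(0, 1, cfg.n_channels)
    smooth = np.exp(-0.5 * ((depth - 0.4) / 0.35) ** 2)  # distractor: smooth profile
    sig_mix = np.column_stack([rugged, smooth])
    sig_src = np.vstack([bursts, distractor])
    rec, gt = _assemble(
        cfg, sig_src, sig_mix, seed,
        event_times=spike_arr,
        modulated=[cfg.burst_freq], distractors=[dis_f],
        extras={"rugged_gains": rugged, "burst_source_index": 0},
    )
    return rec, EventSeries(spike_arr, kind="spike"), gt
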