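"""Synthetic-scene generators: determinism, calibration, and construction
properties (the physics each scene is supposed to embody)."""

import numpy as np
import pytest
from scipy.signal import find_peaks, welch

import gedcfc as g
from gedcfc.synth import (NoiseSpec, SceneConfig, _driver_signal,
                          gen_pink_noise, impose_correlations)


def circular_linear_corr(phase, x):
    """Multiple correlation of x on (cos φ, sin φ)."""
    rc = np.corrcoef(x, np.cos(phase))[0, 1]
    rs = np.corrcoef(x, np.sin(phase))[0, 1]
    rcs = np.corrcoef(np.cos(phase), np.sin(phase))[0, 1]
    return np.sqrt((rc**2 + rs**2 - 2 * rc * rs * rcs) / (1 - rcs**2))


class TestPinkNoise:
    def test_flat_taper_gives_flat_spectrum(self):
        spec = NoiseSpec(n_sources=4, sigmoid_slope=1e-9)
        x = gen_pink_noise(4, 2**14, 1024.0, spec, seed=0)
        f, P = welch(x, fs=1024.0, nperseg=2048)
        mean_p = P.mean(axis=0)
        lo = mean_p[(f > 5) & (f < 50)].mean()
        hi = mean_p[(f > 300) & (f < 500)].mean()
        assert lo / hi == pytest.approx(1.0, rel=0.2)

    def test_seed_determinism(self):
        a = gen_pink_noise(3, 4096, 1024.0, seed=42)
        b = gen_pink_noise(3, 4096, 1024.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_band_power_ratio_matches_taper(self):
        """Power below 5 Hz vs above 50 Hz follows the squared sigmoid taper
        integrated over each band (analytic oracle), within 20%."""
        fs, n = 1024.0, 2**14
        spec = NoiseSpec(n_sources=200)
        x = gen_pink_noise(200, n, fs, spec, seed=1)
        f, P = welch(x, fs=fs, nperseg=4096)
        mean_p = P.mean(axis=0)
        lo_band = (f > 0.5) & (f < 5)
        hi_band = (f > 50) & (f < 500)
        measured = mean_p[lo_band].mean() / mean_p[hi_band].mean()
        # analytic: mean squared taper over the same bands
        expect = np.mean(spec.taper(f[lo_band]) ** 2) / \
            np.mean(spec.taper(f[hi_band]) ** 2)
        assert measured > 1.0
        assert measured == pytest.approx(expect, rel=0.2)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            gen_pink_noise(0, 100, 1024.0)
        with pytest.raises(ValueError):
            gen_pink_noise(2, 1, 1024.0)


class TestImposeCorrelations:
    def test_zero_maxcorr_identity(self, rng):
        x = rng.standard_normal((5, 20000))
        y = impose_correlations(x, 0.0, seed=0)
        corr = np.corrcoef(y)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_two_sources_target_08(self):
        """Closed-form check: with a 2x2 target of correlation 0.8, the
        empirical correlation is 0.8 ± 0.02 at n = 1e5."""
        x = gen_pink_noise(2, 100_000, 1024.0, NoiseSpec(n_sources=2), seed=3)
        target = np.array([[1.0, 0.8], [0.8, 1.0]])
        evals, evecs = np.linalg.eigh(target)
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        y = (evecs * np.sqrt(evals)) @ (evecs.T @ z)   # oracle transform
        got = np.corrcoef(y)[0, 1]
        assert got == pytest.approx(0.8, abs=0.02)
        # the library call with max_corr=0.8 draws a random target whose
        # off-diagonal is <= 0.8 + sampling error
        y2 = impose_correlations(x, 0.8, seed=3)
        assert abs(np.corrcoef(y2)[0, 1]) <= 0.82

    def test_correlations_bounded_after_repeated_application(self, rng):
        x = rng.standard_normal((20, 50_000))
        y = impose_correlations(x, 0.6, seed=1)
        y = impose_correlations(y, 0.6, seed=1)  # same target twice
        corr = np.corrcoef(y)
        off = np.abs(corr[~np.eye(20, dtype=bool)])
        assert off.max() <= 0.6 + 0.05  # bound + sampling error


class TestSceneContracts:
    def test_determinism(self):
        cfg = SceneConfig(duration=6.0, n_channels=16, n_noise=20)
        r1, g1_ = g.gen_pac_scene(cfg, seed=7)
        r2, g2_ = g.gen_pac_scene(cfg, seed=7)
        np.testing.assert_array_equal(r1.data, r2.data)
        np.testing.assert_array_equal(g1_.source_signals, g2_.source_signals)

    def test_mixing_linearity_exact(self):
        cfg = SceneConfig(duration=6.0, n_channels=16, n_noise=20)
        rec, gt = g.gen_pac_scene(cfg, seed=5)
        np.testing.assert_allclose(rec.data, gt.mixing @ gt.source_signals,
                                   rtol=0, atol=1e-12)

    def test_snr_calibration_within_5pct(self):
        cfg = SceneConfig(duration=10.0, n_channels=32, n_noise=40, snr=0.1)
        rec, gt = g.gen_pac_scene(cfg, seed=6)
        k = gt.extras["n_signal_sources"]
        sig = gt.mixing[:, :k] @ gt.source_signals[:k]
        noi = gt.mixing[:, k:] @ gt.source_signals[k:]
        achieved = sig.var(axis=1).sum() / noi.var(axis=1).sum()
        assert achieved == pytest.approx(0.1, rel=0.05)

    def test_nyquist_guard(self):
        cfg = SceneConfig(duration=4.0, n_channels=8, n_noise=10,
                          modulated_freqs=(600.0,))
        with pytest.raises(ValueError, match="Nyquist"):
            g.gen_pac_scene(cfg, seed=0)


class TestPacScene:
    def test_zero_depth_no_coupling(self):
        cfg = SceneConfig(duration=20.0, n_channels=16, n_noise=20,
                          mod_depth=0.0)
        rec, gt = g.gen_pac_scene(cfg, seed=8)
        env = gt.extras["gamma_envelope"]
        phase = gt.extras["driver_phase"]
        assert np.std(env) < 1e-12 or \
            circular_linear_corr(phase, env) < 0.05

    def test_default_depth_strong_phase_envelope_link(self):
        cfg = SceneConfig(duration=20.0, n_channels=16, n_noise=20)
        rec, gt = g.gen_pac_scene(cfg, seed=8)
        r = circular_linear_corr(gt.extras["driver_phase"],
                                 gt.extras["gamma_envelope"])
        assert r > 0.8

    def test_distractor_has_twice_modulated_power_at_channels(self):
        """Channel-level 50 Hz power exceeds 40 Hz power (the distractor is
        simulated at twice the modulated gamma's power)."""
        cfg = SceneConfig(duration=20.0)
        rec, gt = g.gen_pac_scene(cfg, seed=1)
        i40 = gt.extras["modulated_index"]
        i50 = gt.extras["distractor_index"]
        s40 = gt.source_signals[i40]
        s50 = gt.source_signals[i50]
        assert s50.var() == pytest.approx(2.0 * s40.var(), rel=0.01)
        f, P = welch(rec.data, fs=rec.fs, nperseg=2048)
        tot = P.sum(axis=0)
        assert tot[np.argmin(abs(f - 50))] > tot[np.argmin(abs(f - 40))]


class TestTwoNetworkScene:
    def test_antiphase_envelopes(self, two_network_scene):
        gt = two_network_scene["gt"]
        e1, e2 = gt.extras["envelope_1"], gt.extras["envelope_2"]
        assert np.corrcoef(e1, e2)[0, 1] < -0.8

    def test_envelope_peaks_align_with_driver_extrema(self, two_network_scene):
        gt = two_network_scene["gt"]
        fs = gt.fs
        phase = gt.extras["driver_phase"]
        wrapped = np.mod(phase, 2 * np.pi)
        period = fs / gt.driver_freq
        for env, target in ((gt.extras["envelope_1"], np.pi),
                            (gt.extras["envelope_2"], 0.0)):
            locs, _ = find_peaks(env, distance=int(period * 0.6))
            ph = wrapped[locs]
            # circular distance to the target phase < 1/8 cycle
            d = np.angle(np.exp(1j * (ph - target)))
            assert np.median(np.abs(d)) < 2 * np.pi / 8


class TestBurstScene:
    def test_locked_vs_random_phase_trough_average(self, burst_scene_pair):
        """Averaging oracle: the trough-triggered average of the burst
        source retains the carrier when phase-locked and cancels when the
        carrier phase is randomized per burst."""
        out = {}
        for name in ("locked", "random"):
            rec, gt = burst_scene_pair[name]
            src = gt.source_signals[gt.extras["burst_source_index"]]
            hw = 50
            evs = gt.event_times[(gt.event_times >= hw)
                                 & (gt.event_times < src.size - hw)]
            assert evs.size >= 100
            avg = np.mean([src[t - hw: t + hw + 1] for t in evs], axis=0)
            out[name] = np.abs(avg).max()
        assert out["locked"] > 10 * out["random"]

    def test_burst_envelope_max_at_troughs(self, burst_scene_pair):
        rec, gt = burst_scene_pair["random"]
        src = gt.source_signals[gt.extras["burst_source_index"]]
        env = np.abs(src)
        for t in gt.event_times[5:50]:
            seg = env[t - 80: t + 81]
            assert np.argmax(seg) == pytest.approx(80, abs=25)

    def test_carrier_phases_uniform(self, burst_scene_pair):
        """Rayleigh test on per-burst carrier phases (random-phase scene):
        no significant clustering."""
        rec, gt = burst_scene_pair["random"]
        src = gt.source_signals[gt.extras["burst_source_index"]]
        fs = gt.fs
        t = np.arange(src.size) / fs
        ref = np.exp(-1j * 2 * np.pi * 75.0 * t)
        phases = []
        for ev in gt.event_times:
            if ev < 40 or ev > src.size - 40:
                continue
            seg = slice(ev - 12, ev + 13)
            phases.append(np.angle(np.sum(src[seg] * ref[seg])))
        phases = np.array(phases)
        n = phases.size
        rbar = np.abs(np.mean(np.exp(1j * phases)))
        z = n * rbar**2                    # Rayleigh statistic
        p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n))
        assert p > 0.01

    def test_burst_longer_than_period_rejected(self):
        cfg = SceneConfig(duration=6.0, n_channels=8, n_noise=10,
                          burst_sigma=0.05)
        with pytest.raises(ValueError, match="period"):
            g.gen_burst_scene(cfg, seed=0)


class TestSpikefieldScene:
    def test_default_size_and_events(self, spikefield_scene):
        rec = spikefield_scene["rec"]
        spikes = spikefield_scene["spikes"]
        assert rec.n_channels == 16
        assert len(spikes) == 40

    def test_rugged_gain_has_sign_flip(self, spikefield_scene):
        gains = spikefield_scene["gt"].extras["rugged_gains"]
        assert np.any(np.sign(gains[:-1]) != np.sign(gains[1:]))

    def test_sta_fails_but_per_spike_envelope_high(self):
        """With per-spike random carrier phase and no noise, the
        spike-triggered average cancels the burst while the per-spike
        envelope at burst channels stays high."""
        cfg = SceneConfig(n_channels=16, duration=40.0, burst_freq=70.0,
                          distractor_freqs=(), n_noise=4, snr=1e6,
                          n_spikes=40)
        rec, spikes, gt = g.gen_spikefield_scene(cfg, seed=9)
        ch = int(np.argmax(np.abs(gt.extras["rugged_gains"])))
        hw = 40
        segs = np.array([rec.data[ch, t - hw: t + hw + 1]
                         for t in spikes.samples])
        sta_amp = np.abs(segs.mean(axis=0)).max()
        per_spike = np.median(np.abs(segs).max(axis=1))
        assert sta_amp < 0.4 * per_spike


class TestConfoundDrivers:
    @pytest.mark.parametrize("waveform,harmonics", [
        # the Gaussian train has all harmonics (2f resolvable despite the
        # ±20% frequency jitter); the van der Pol limit cycle is
        # odd-symmetric, so its harmonics sit at odd multiples only
        ("gaussian-train", (2,)),
        ("van-der-pol", (3, 5)),
    ])
    def test_harmonic_content(self, waveform, harmonics):
        """Non-sinusoidal drivers carry energy at integer multiples of the
        fundamental — the property that confounds traditional CFC."""
        cfg = SceneConfig(duration=30.0, n_channels=8, n_noise=10,
                          driver_waveform=waveform)
        rng = np.random.default_rng(11)
        drv, phase = _driver_signal(cfg, rng)
        f, P = welch(drv, fs=cfg.fs, nperseg=8192)

        def band(center, half=2.0):
            return P[(f > center - half) & (f < center + half)].mean()

        baseline = band(47.0, half=2.0)  # far from any retained harmonic
        for harmonic in harmonics:
            assert band(harmonic * cfg.driver_freq) > 3 * baseline
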