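"""Delay embedding, spatiotemporal components (Methods 4–5), artifact
screening, and spike-pattern classification."""

import numpy as np
import pytest

import gedcfc as g
from gedcfc.embed import SpatioTemporalComponent, _kernel_spectrum
from gedcfc.filters import highpass


def ramp_rec(n=500, channels=2, fs=1000.0):
    data = np.vstack([np.arange(n, dtype=float) * (c + 1)
                      for c in range(channels)])
    return g.Recording(data, fs)


class TestDelayEmbed:
    def test_row_count_64x60_is_3840(self, rng):
        rec = g.Recording(rng.standard_normal((64, 4000)), 1024.0)
        emb = g.delay_embed(rec, E=60)
        assert emb.data.shape[0] == 3840
        assert emb.data.shape[1] == 4000 - 59

    def test_first_order_identity(self, rng):
        rec = g.Recording(rng.standard_normal((3, 100)), 1000.0)
        emb = g.delay_embed(rec, E=1)
        np.testing.assert_array_equal(emb.data, rec.data)

    def test_rows_are_exact_shifts(self):
        rec = ramp_rec()
        emb = g.delay_embed(rec, E=3, lag_step=1)
        M = rec.n_channels
        for k in range(1, 3):
            # row c + M*k is channel c delayed by k samples
            np.testing.assert_array_equal(
                emb.data[M * k, k:], emb.data[0, :-k])

    def test_unit_cell_filter_reproduces_shifted_channel(self, rng):
        rec = g.Recording(rng.standard_normal((4, 300)), 1000.0)
        emb = g.delay_embed(rec, E=5, lag_step=2)
        w = np.zeros(emb.n_rows)
        idx = 2 + 4 * 3  # channel 2, lag 3
        w[idx] = 1.0
        out = w @ emb.data
        np.testing.assert_array_equal(out, emb.data[idx])
        # and that row is the original channel shifted by 3*2 samples
        span = (5 - 1) * 2
        np.testing.assert_array_equal(
            out, rec.data[2, span - 6: rec.n_samples - 6])

    def test_embedding_too_deep_rejected(self, rng):
        rec = g.Recording(rng.standard_normal((2, 50)), 1000.0)
        with pytest.raises(ValueError):
            g.delay_embed(rec, E=60)

    def test_derivative_filter_on_ramp(self):
        """Weights (+1, −1) across one delay implement a temporal
        derivative: applied to a ramp they produce a constant."""
        rec = ramp_rec(channels=1)
        emb = g.delay_embed(rec, E=2, lag_step=1)
        w = np.array([1.0, -1.0])  # undelayed minus delayed
        out = w @ emb.data
        np.testing.assert_allclose(out, out[0])
        assert out[0] == pytest.approx(1.0)


class TestEmbeddingResolution:
    def test_native_17hz(self):
        native, padded = g.embedding_resolution(1024.0, 60, 1, 2.0)
        assert round(native) == 17
        assert padded == 2.0

    def test_doubling_E_halves_resolution(self):
        n1, _ = g.embedding_resolution(1024.0, 30, 1)
        n2, _ = g.embedding_resolution(1024.0, 60, 1)
        assert n1 == pytest.approx(2 * n2)

    def test_coarser_padding_rejected(self):
        with pytest.raises(ValueError):
            g.embedding_resolution(1024.0, 60, 1, zero_pad_to=50.0)


class TestKernelReshape:
    def test_roundtrip(self, rng):
        rec = g.Recording(rng.standard_normal((6, 3000)), 1024.0)
        emb = g.delay_embed(rec, E=10)
        a = rng.standard_normal(60)
        from gedcfc.embed import _make_component
        comp = _make_component(1.0, a.copy(), a, emb, 2.0)
        np.testing.assert_array_equal(comp.kernel.ravel(order="F"), a)
        assert comp.kernel.shape == (6, 10)


class TestArtifactScore:
    def _comp(self, kernel, fs=1024.0, lag=1):
        freqs, spec = _kernel_spectrum(kernel, fs, lag, 2.0)
        return SpatioTemporalComponent(
            filter=kernel.ravel(order="F"), forward_model=kernel.ravel(order="F"),
            kernel=kernel, kernel_freqs=freqs, kernel_spectrum=spec,
            eigenvalue=1.0)

    def test_white_noise_kernel_flagged(self, rng):
        score = g.artifact_score(self._comp(rng.standard_normal((4, 256))))
        assert score == pytest.approx(1.0, abs=0.35)

    def test_pure_70hz_kernel_not_flagged(self):
        t = np.arange(256) / 1024.0
        kernel = np.tile(np.cos(2 * np.pi * 70.0 * t), (4, 1))
        score = g.artifact_score(self._comp(kernel))
        assert score < 0.1

    def test_impulse_kernel_flagged(self):
        kernel = np.zeros((4, 256))
        kernel[:, 128] = 1.0
        assert g.artifact_score(self._comp(kernel)) >= 0.9

    def test_split_above_nyquist_rejected(self, rng):
        comp = self._comp(rng.standard_normal((4, 256)))
        with pytest.raises(ValueError):
            g.artifact_score(comp, split_hz=600.0)


class TestMethod4:
    def test_burst_recovery_vs_trough_average(self, burst_scene_pair):
        """Kernel spectrum peaks at the burst frequency although the
        trough-triggered average cancels (random carrier phase)."""
        rec, gt = burst_scene_pair["random"]
        lf = g.extract_lf_component(rec, g.FilterSpec(6.0, 2.0))
        troughs = g.detect_extrema(lf, rec.fs, "trough")
        comp = g.method4(rec, lf, troughs, E=48, lag_step=1)
        sel = (comp.kernel_freqs >= 30) & (comp.kernel_freqs <= 120)
        peak = comp.kernel_freqs[sel][np.argmax(comp.kernel_spectrum[sel])]
        assert abs(peak - 75.0) <= 2.0
        # the trough-locked average has no 75 Hz concentration
        hp = highpass(rec.data, rec.fs, 20.0)
        hw = 48
        evs = gt.event_times[(gt.event_times >= hw)
                             & (gt.event_times < rec.n_samples - hw)]
        tla = np.mean([hp[:, t - hw: t + hw + 1] for t in evs], axis=0)
        spec = np.abs(np.fft.rfft(tla, n=512, axis=1)) ** 2
        fr = np.fft.rfftfreq(512, 1 / rec.fs)
        band = spec.mean(axis=0)
        rel75 = band[np.argmin(abs(fr - 75))] / \
            band[(fr >= 30) & (fr <= 120)].mean()
        assert rel75 < 1.5

    def test_phase_locked_variant_matches_average(self, burst_scene_pair):
        """When bursts are phase-locked, the method's kernel and the
        trough-triggered average agree (correlation > 0.7 at the best
        channel)."""
        rec, gt = burst_scene_pair["locked"]
        lf = g.extract_lf_component(rec, g.FilterSpec(6.0, 2.0))
        troughs = g.detect_extrema(lf, rec.fs, "trough")
        E = 48
        comp = g.method4(rec, lf, troughs, E=E, lag_step=1)
        hp = highpass(rec.data, rec.fs, 20.0)
        hw = E // 2
        evs = troughs.samples[(troughs.samples >= hw)
                              & (troughs.samples < rec.n_samples - hw)]
        tla = np.mean([hp[:, t - hw: t + hw] for t in evs], axis=0)
        ch = int(np.argmax(np.abs(comp.kernel).max(axis=1)))
        k = comp.kernel[ch][::-1]  # kernel lag axis runs backwards in time
        r = max(abs(np.corrcoef(k, tla[ch])[0, 1]),
                abs(np.corrcoef(k[::-1], tla[ch])[0, 1]))
        assert r > 0.7

    def test_no_burst_scene_within_null(self):
        cfg = g.SceneConfig(duration=30.0, n_channels=16, n_noise=40,
                            burst_freq=75.0, distractor_freqs=(50.0,),
                            snr=0.1)
        rec, gt = g.gen_burst_scene(cfg, seed=61)
        # destroy the coupling: use random events instead of troughs
        lf = g.extract_lf_component(rec, g.FilterSpec(6.0, 2.0))
        rng = np.random.default_rng(0)
        n_ev = len(gt.event_times)
        fake = np.unique(rng.integers(200, rec.n_samples - 200, n_ev))
        null = g.random_event_null(
            rec, lf,
            lambda r, l, e: g.method4(r, l, e, E=24, lag_step=2),
            g.EventSeries(fake), n_perm=30, seed=7, edge_margin=200)
        lo, hi = np.quantile(null.values, [0.005, 0.995])
        assert lo <= null.observed <= hi


class TestMethod5:
    def test_laminar_recovery(self, spikefield_scene):
        rec, spikes, gt = (spikefield_scene["rec"], spikefield_scene["spikes"],
                           spikefield_scene["gt"])
        comps = g.method5(rec, spikes, E=60, lag_step=1)
        lead = next(c for c in comps if not c.artifact)
        sel = (lead.kernel_freqs >= 30) & (lead.kernel_freqs <= 120)
        peak = lead.kernel_freqs[sel][np.argmax(lead.kernel_spectrum[sel])]
        assert abs(peak - 70.0) <= 2.0
        profile = np.sqrt((lead.kernel ** 2).sum(axis=1))
        r = np.corrcoef(profile, np.abs(gt.extras["rugged_gains"]))[0, 1]
        assert r > 0.8

    def test_injected_transient_flagged_as_artifact(self, spikefield_scene):
        """Spike-shaped impulses injected at spike times dominate a
        component that the spectral screen flags."""
        rec = spikefield_scene["rec"].copy()
        spikes = spikefield_scene["spikes"]
        art = np.zeros(rec.n_samples)
        art[spikes.samples] = 60.0 * rec.data.std()
        art[spikes.samples + 1] = -45.0 * rec.data.std()
        rec.data[:] += np.outer(np.linspace(0.5, 1.5, rec.n_channels), art)
        comps = g.method5(rec, spikes, E=60, lag_step=1)
        assert comps[0].artifact

    def test_shuffled_spikes_within_null(self, spikefield_scene):
        rec = spikefield_scene["rec"]
        rng = np.random.default_rng(1)
        fake = np.unique(rng.integers(200, rec.n_samples - 200, 40))
        null = g.random_event_null(
            rec, None,
            lambda r, l, e: g.method5(r, e, E=30, lag_step=2,
                                      n_components=1)[0],
            g.EventSeries(fake), n_perm=30, seed=8, edge_margin=200)
        lo, hi = np.quantile(null.values, [0.005, 0.995])
        assert lo <= null.observed <= hi

    def test_empty_spikes_rejected(self, spikefield_scene):
        with pytest.raises(ValueError):
            g.method5(spikefield_scene["rec"], g.EventSeries([]), E=10)


class TestClassifySpikes:
    FS = 1000.0  # 1 sample = 1 ms

    def classify(self, times_ms):
        ev = g.EventSeries(np.asarray(times_ms, dtype=int))
        return g.classify_spikes(ev, self.FS)

    def test_isolated_spike_is_singlet(self):
        singlets, starters = self.classify([500])
        assert list(singlets.samples) == [500]
        assert len(starters) == 0

    def test_pair_at_10ms(self):
        singlets, starters = self.classify([0, 10])
        assert list(starters.samples) == [0]
        assert len(singlets) == 0  # the second has a spike 10 ms before

    def test_spaced_spikes_all_singlets(self):
        singlets, starters = self.classify([0, 150, 300])
        assert list(singlets.samples) == [0, 150, 300]
        assert len(starters) == 0

    def test_categories_disjoint_random_trains(self, rng):
        times = np.unique(rng.integers(0, 100_000, 300))
        singlets, starters = g.classify_spikes(g.EventSeries(times), self.FS)
        assert not set(singlets.samples) & set(starters.samples)

    def test_intermediate_gap_unassigned(self):
        # 50 ms gap: not isolated (within 100 ms), not a train (> 20 ms)
        singlets, starters = self.classify([0, 50])
        assert len(singlets) == 0 and len(starters) == 0
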