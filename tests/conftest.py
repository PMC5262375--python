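"""Shared fixtures: small synthetic scenes reused across test modules.

Scenes are generated once per session at desk scale (shorter records and,
where possible, fewer channels than the full-size simulations) — enough for
the qualitative physics while keeping the suite fast.
"""

import numpy as np
import pytest

import gedcfc as g


@pytest.fixture(scope="session")
def pac_scene():
    """Single-network PAC scene (6 Hz driver, 40 Hz modulated, 50 Hz
    distractor) with its low-frequency component and events."""
    rec, gt = g.gen_pac_scene(g.SceneConfig(), seed=1)  # default 120 s
    lf = g.extract_lf_component(rec, g.FilterSpec(6.0, 2.0))
    troughs = g.detect_extrema(lf, rec.fs, "trough")
    peaks = g.detect_extrema(lf, rec.fs, "peak")
    return {"rec": rec, "gt": gt, "lf": lf, "troughs": troughs, "peaks": peaks}


@pytest.fixture(scope="session")
def pac_method1(pac_scene):
    comp = g.method1(pac_scene["rec"], pac_scene["lf"], pac_scene["troughs"])
    return comp


@pytest.fixture(scope="session")
def two_network_scene():
    cfg = g.SceneConfig(duration=60.0, modulated_freqs=(40.0, 45.0),
                        distractor_freqs=())
    rec, gt = g.gen_two_network_scene(cfg, seed=2)
    lf = g.extract_lf_component(rec, g.FilterSpec(6.0, 2.0))
    troughs = g.detect_extrema(lf, rec.fs, "trough")
    peaks = g.detect_extrema(lf, rec.fs, "peak")
    return {"rec": rec, "gt": gt, "lf": lf, "troughs": troughs, "peaks": peaks}


@pytest.fixture(scope="session")
def burst_scene_pair():
    """Random-phase and phase-locked variants of the 75 Hz burst scene
    (reduced channel count for speed)."""
    out = {}
    for name, rand in (("random", True), ("locked", False)):
        cfg = g.SceneConfig(duration=40.0, n_channels=32, n_noise=100,
                            burst_freq=75.0, distractor_freqs=(50.0,),
                            random_burst_phase=rand, snr=0.1)
        out[name] = g.gen_burst_scene(cfg, seed=3)
    return out


@pytest.fixture(scope="session")
def spikefield_scene():
    rec, spikes, gt = g.gen_spikefield_scene(seed=4)
    return {"rec": rec, "spikes": spikes, "gt": gt}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
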