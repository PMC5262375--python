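"""Two networks alternating with low-frequency phase (Method 2).

Two gamma sources (40 and 45 Hz) with distinct topographies are amplitude
modulated at opposite phases of a 6 Hz driver. Contrasting peri-trough
against peri-peak covariance separates them: the largest-eigenvalue filter
gives the trough network, the swapped contrast the peak network.
"""

import numpy as np
from scipy.signal import welch

import gedcfc as g

cfg = g.SceneConfig(duration=60.0, modulated_freqs=(40.0, 45.0),
                    distractor_freqs=())
rec, gt = g.gen_two_network_scene(cfg, seed=2)

lf = g.extract_lf_component(rec, g.FilterSpec(6.0, 2.0))
troughs = g.detect_extrema(lf, rec.fs, "trough")
peaks = g.detect_extrema(lf, rec.fs, "peak")
trough_comp, peak_comp = g.method2(rec, lf, troughs, peaks)


def peak_freq(ts):
    f, P = welch(ts, fs=rec.fs, nperseg=int(rec.fs))
    sel = (f >= 20) & (f <= 100)
    return f[sel][np.argmax(P[sel])]


for name, comp, col in (("trough", trough_comp, 1), ("peak", peak_comp, 2)):
    r = np.corrcoef(comp.forward_model, gt.mixing[:, col])[0, 1]
    print(f"{name}-component: spectral peak {peak_freq(comp.time_series):.0f} Hz, "
          f"eigenvalue {comp.eigenvalue:.2f}, forward-model match r = {r:.2f}")
# Each component's spectrum peaks at its own simulated gamma frequency and
# its forward model reproduces that dipole's scalp projection — although no
# channel spectrum shows a prominent gamma peak.
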