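"""Low-frequency waveform as a bias filter on sphered envelopes (Method 3).

Instead of time-locking to discrete phase landmarks, the low-frequency
waveform itself selects — via joint decorrelation of sphered multichannel
power envelopes — the combination of channels whose high-frequency power
best follows it. Applied over a frequency sweep, the coupling profile
identifies the modulated band; a circular-shift null gives significance.
"""

import numpy as np

import gedcfc as g

cfg = g.SceneConfig(duration=60.0, modulated_freqs=(45.0,),
                    distractor_freqs=(50.0,))
rec, gt = g.gen_pac_scene(cfg, seed=3)
lf = g.extract_lf_component(rec, g.FilterSpec(6.0, 2.0))

freqs = np.arange(25.0, 76.0, 5.0)
sweep = g.method3_sweep(rec, lf.time_series, freqs, epochs=None, epoch_len=4.0)

print(" freq   r^2     ps")
for res in sweep:
    print(f"{res.frequency:5.0f}  {res.coupling_r2:.3f}  {res.coupling_ps:.3f}")

best = max(sweep, key=lambda r: r.coupling_r2)
null = g.circular_shift_null(lf.time_series, best.component_power,
                             metric="r2", n_perm=500, seed=3, fs=rec.fs)
print(f"\nstrongest coupling at {best.frequency:.0f} Hz "
      f"(r^2 = {best.coupling_r2:.3f}; 99% null bound "
      f"{null.interval[1]:.4f}; significant: {null.exceeds_upper()})")
# The sweep peaks at the simulated 45 Hz band; the squared correlation far
# exceeds the circular-shift null, while single-channel fits stay near zero.
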