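"""Spike-field coherence as event-locked CFC (Method 5).

A 16-channel laminar probe records 70 Hz bursts centered on each of 40
spikes with a "rugged" depth profile and random carrier phase, plus a 75 Hz
distractor and 1/f noise. Time-locking delay-embedded covariance to the
spikes recovers the spatiotemporal pattern that spike-triggered averaging
misses; a spectral screen separates genuine field patterns from
spike-artifact components, and spikes can be split into singlets vs
train-starters for pattern contrasts.
"""

import numpy as np

import gedcfc as g

rec, spikes, gt = g.gen_spikefield_scene(seed=5)
comps = g.method5(rec, spikes, E=60, lag_step=1)

print("component  eigenvalue  artifact-score  flagged")
for i, c in enumerate(comps):
    print(f"  {i}        {c.eigenvalue:8.2f}      {c.score:6.3f}      "
          f"{c.artifact}")

lead = next(c for c in comps if not c.artifact)
sel = (lead.kernel_freqs >= 30) & (lead.kernel_freqs <= 120)
kpeak = lead.kernel_freqs[sel][np.argmax(lead.kernel_spectrum[sel])]
profile = np.sqrt((lead.kernel ** 2).sum(axis=1))
r = np.corrcoef(profile, np.abs(gt.extras["rugged_gains"]))[0, 1]

print(f"\nleading non-artifact kernel peak  : {kpeak:.0f} Hz")
print(f"laminar profile vs true gains     : r = {r:.2f}")

singlets, starters = g.classify_spikes(spikes, rec.fs)
print(f"singlets / train-starters         : {len(singlets)} / {len(starters)}")
# The kernel spectrum peaks at the spike-locked 70 Hz burst (not the 75 Hz
# distractor), and the kernel's channel profile reproduces the non-smooth
# laminar gain pattern from only 40 spikes.
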