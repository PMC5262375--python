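"""Single-network phase-amplitude coupling (Method 1).

Simulates 64-channel EEG in which a nonstationary ~6 Hz rhythm modulates
the amplitude of a 40 Hz source while a stronger 50 Hz distractor runs
independently, then recovers the coupled network by contrasting
trough-locked covariance against the whole-record covariance.
"""

import numpy as np

import gedcfc as g

rec, gt = g.gen_pac_scene(g.SceneConfig(duration=60.0), seed=1)

lf = g.extract_lf_component(rec, g.FilterSpec(peak=6.0, fwhm=2.0))
troughs = g.detect_extrema(lf, rec.fs, "trough")
peaks = g.detect_extrema(lf, rec.fs, "peak")
comp = g.method1(rec, lf, troughs)

ms = g.modulation_spectrum(comp.time_series, rec.fs, np.arange(20, 81, 2.0))
fm_corr = np.corrcoef(comp.forward_model, gt.mixing[:, 1])[0, 1]

print(f"low-frequency component eigenvalue : {lf.eigenvalue:8.1f}")
print(f"trough events detected             : {len(troughs):8d}")
print(f"CFC component eigenvalue           : {comp.eigenvalue:8.2f}")
print(f"forward model vs true 40 Hz dipole : r = {fm_corr:5.2f}")
print(f"modulation spectrum global maximum : {ms.argmax_freq():.0f} Hz")
print(f"flanking secondary maxima          : {ms.flanking_maxima()} Hz")
# The global maximum at 40 Hz is the coupled gamma network; the secondary
# maxima offset by the 6 Hz driver frequency are the amplitude-modulation
# sidebands. The 50 Hz distractor — twice as strong at the channels — does
# not appear, because it loads troughs and reference covariance equally.
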