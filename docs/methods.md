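# Methods

## The model

All five analysis methods in this package are instances of one idea:
contrast a "signal" covariance matrix **S** against a "reference"
covariance matrix **R** by solving the generalized eigenvalue problem

    S W = R W Λ.

Each column **w** of **W** is a spatial filter over channels; the
eigenvalue λ is the variance ratio **wᵀSw / wᵀRw** that the filter
attains, and the filter with the largest eigenvalue maximally
differentiates the two matrices. Because **R⁻¹S** is not symmetric, the
eigenvectors are linearly independent but not orthogonal — unlike PCA,
which is what makes GED usable as a source-separation method. The
component time series is **wᵀX** over the whole record (covariances may
come from discrete event windows; the component does not). For
interpretation, the forward model (activation pattern) is the
corresponding column of **W⁻ᵀ**: the component's projection back onto the
channels.

The methods differ only in how **S** and **R** are built:

| method | S | R | yields |
|---|---|---|---|
| low-frequency extraction | narrowband-filtered total covariance | broadband (or mean of two flanking-band) total covariance | the slow rhythm used for time-locking |
| 1 | broadband covariance of ¼-cycle windows at troughs | total covariance | one phase-coupled high-frequency network |
| 2 | peri-trough windows | peri-peak windows | two networks active at opposite phases |
| 3 | covariance of bias-filtered sphered envelopes | (sphering makes R the identity) | the envelope combination matching the low-frequency waveform |
| 4 | trough-locked windows of the delay-embedded matrix | total embedded covariance | a spatiotemporal (waveform-learning) filter |
| 5 | spike-locked windows of the embedded matrix | total embedded covariance | spike-field patterns, artifact-screened |

Key robustness property: the low-frequency waveform only supplies *time
points* (Methods 1, 2, 4, 5) or a *regressor* (Method 3); no sinusoidality
is assumed, so non-sinusoidal drivers (pulse trains, relaxation
oscillators) that confound phase-amplitude coupling indices based on
Euler's formula do not produce spurious coupling here.

### Assumptions

- Fields mix linearly and instantaneously onto channels.
- The high-frequency network's spatial (Methods 1–3) or spatiotemporal
  (4–5) signature is consistent across event windows.
- Method 2 additionally requires the two networks' channel projections to
  be separable; fed a single network it returns near-identical covariances
  (a warning fires when neither contrast direction reaches a ~1.7× power
  ratio).
- Method 3 requires a well-specified bias waveform; it is the only method
  that uses the low-frequency waveform *shape*.

## Temporal filtering

All filtering is frequency-domain: multiply the FFT by a Gaussian
`exp(−0.5 (x/s)²)` centered on the peak frequency, with
`s = fwhm·(2π−1)/(4π)` and the taper mirrored onto negative frequencies;
inverse-transform back. The constant `(2π−1)/(4π)` is implemented verbatim;
it makes the empirical half-gain width ≈ 0.99 × the nominal FWHM, and the
FWHM contract is therefore tested at 5% tolerance. Filtering is a circular
convolution — the first/last half-window wrap around the record edge, so
event windows near the edges are discarded by the covariance routines.

The high-pass (used by Method 4 to keep the component from reflecting the
low-frequency waveform itself) is an integrated-Gaussian (erf) spectral
edge rising across [cutoff/2, cutoff]. A plain "1 − Gaussian-lowpass"
complement cannot simultaneously give ≥ 20 dB attenuation one octave below
the cutoff and a flat passband (it would need a stop/pass frequency ratio
of ≈ 5); the erf edge achieves both with the same circular-FFT machinery.

### Filter-width rules (they matter)

Amplitude modulation at driver rate f_d puts spectral sidebands at
carrier ± f_d. Consequences, each verified empirically in the test suite:

- **Envelope tracking** (Method 3, coupling fits): the narrowband filter
  must pass both sidebands, or the extracted envelope is flat regardless
  of true modulation. Method 3's default FWHM is therefore
  `max(4 Hz, 2.2 × f_bias)`, with f_bias estimated from the bias series'
  dominant spectral peak.
- **Modulation spectra** (Method 1 quantification): the default metric is
  the mean cycle peak-to-trough swing of the narrowband-filtered component
  (≈ 2 × mean envelope). On this metric a coupled carrier shows a global
  maximum at the carrier and secondary maxima at exactly carrier ± f_d —
  the AM sidebands. Resolving them requires a FWHM *below* f_d (default
  4 Hz). An alternative mode (`mode="lf-events"`) contrasts the envelope
  at low-frequency peaks vs troughs; it is zero for unmodulated input but
  its frequency profile dips at the carrier and its side maxima are pulled
  inward under driver-frequency jitter, so it is not the default.
- Single-frequency power extraction and time-frequency maps use the
  proportional rule `FWHM = max(2 Hz, 0.15·center)`.

## Method 3 mechanics

Per analysis frequency: filter-Hilbert envelopes per channel,
mean-centered → **X**; sphere with the eigendecomposition of cov(**X**)
(**Y** = **Xᵀ V D**^−½ on dimensions with eigenvalue > 10⁻¹⁰ of the
largest); form the covariance of **B·Y**, where **B** is (conceptually) a
Toeplitz matrix of time-shifted copies of the bias series. **B** is never
materialized: cov(**BY**) = **Yᵀ(BᵀB)Y** and **BᵀB** is the bias
autocorrelation Toeplitz, truncated at ± one bias period and applied as a
short FFT convolution. The truncation is essential for selectivity as well
as cost: shorter lags degrade the Gram kernel into a lowpass hump and the
procedure then prefers the slowest envelope rather than the matching one.
Covariance is computed per epoch (default 4 s, as many epochs as fit) and
averaged; the top eigenvector **w** is rotated back to channel space as
**V D**^−½**w** and applied to the *non-sphered* envelopes. Coupling is
reported as r² (squared Pearson correlation with the bias) and ps (squared
magnitude of the mean unit phase-difference phasor; amplitude-blind).

## Delay embedding (Methods 4–5)

An E-fold embedding of M channels stacks E copies of each channel at lags
0, lag_step, …, (E−1)·lag_step; the embedding count includes the undelayed
copy, so the matrix has M·E rows (64 channels × 60 embeddings = 3,840).
The eigenvector weights along the lag axis form an empirically learned
temporal filter; the forward model reshaped to M × E is the discovered
waveform, and its lag-axis spectrum (zero-padded from the native
fs/(E·lag_step) ≈ 17 Hz at fs = 1,024 to a 2 Hz display grid) gives the
component's frequency content without imposing a sinusoidal basis. For
M·E above a cap (default 40) the embedded data are projected onto the top
principal components of the reference covariance before the GED and the
filters/patterns mapped back — numerically necessary and statistically
harmless at these scales.

Spike-locked components are screened for spike artifacts by spectral
balance: score = mean kernel-spectrum energy above 200 Hz / mean below;
genuine field patterns score ≪ 1, broadband transients ≥ 1 (flagged).

## Numerical choices

- **Covariances**: per-window channel-mean-centering, per-window
  covariance, then averaging (robust to window-to-window offsets; matches
  the per-epoch averaging used by Method 3). Whether to center per window
  or globally is genuinely open; per-window was chosen.
- **Regularization**: diagonal loading R ← (1−γ)R + γ·mean(eig R)·I with
  γ = 0.01 by default, applied to the denominator matrix only. A singular
  R with γ = 0 raises an error suggesting loading or dimensionality
  reduction.
- **Method 2's "smallest eigenvalue"**: with denominator-only loading the
  minimum eigenvalue is captured by globally low-variance noise directions
  rather than the peak network. The peak component is therefore computed
  as the *largest* eigenvector of the swapped pair (identical at γ = 0,
  robust with loading).
- **Eigenvalue normalization for low-frequency extraction**: the
  narrowband covariance is divided by the filter's white-noise attenuation
  (mean squared gain), so eigenvalue 1 means "no more band power than a
  flat spectrum gives"; a structureless record scores ≈ 1 and is flagged
  weak, a real rhythm scores in the tens to hundreds.
- **Sign fixing**: eigenvector signs are arbitrary; the forward model's
  largest-magnitude channel is forced positive, and the component is
  flipped if it anticorrelates with the (band-filtered) data at that
  channel. Idempotent; peak/trough identity is only as reliable as this
  step, so analyses where it is crucial should be run separately for peaks
  and troughs.
- **Extremum detection**: local extrema of the band-limited component with
  a refractory distance of half the nominal period; an optional screen
  keeps extrema above mean + k·SD of extremum amplitudes. Near-zero
  amplitude cycles can drop one extremum, so peak/trough interleaving is
  near-strict rather than strict.

## The synthetic world

The generators mimic scalp EEG / laminar LFP simulation practice: a few
"signal" dipoles plus many correlated 1/f noise sources, all projected
through a fixed mixing matrix; the recording is exactly
`mixing @ sources`, so ground-truth recovery is well-defined.

- **Noise**: each source is the inverse FFT of uniform random complex
  coefficients with the amplitude spectrum tapered by a sigmoid
  (center 10 Hz, slope 0.08/Hz, normalized to 1 at DC). The slope leaves a
  small but non-zero gamma-band floor; a steeper taper makes the gamma
  band noise-free, which is unrealistic and lets single channels act as
  noiseless gamma sensors. Source-to-source correlations follow a random
  PSD-repaired target with off-diagonals ≤ 0.8, imposed by ZCA-whitening
  then multiplying by the target's symmetric square root (exact and
  idempotent). 200 noise sources by default (a desk-scale stand-in for a
  dense whole-brain dipole grid).
- **Mixing**: 2-D Gaussian topographies over an 8×8 grid for "scalp"
  scenes (driver at (0.50, 0.62), width 0.24; gamma dipoles at
  (0.38/0.62, 0.78), width 0.18 — overlapping but distinct), plus a
  uniform far-field floor of 0.05 because physical volume conduction does
  not decay to zero across an array. Laminar scenes use per-channel gain
  vectors, with a deliberately sign-flipping "rugged" profile for the
  spike-locked burst.
- **Driver**: instantaneous frequency follows a slow random walk within
  ±20% of nominal and amplitude within ±50% (nonstationary by
  construction); alternatives are a periodic Gaussian pulse train
  (von-Mises-shaped, κ = 8) and a van der Pol oscillator (μ = 5, one limit
  cycle integrated and tiled, rescaled to the nominal fundamental) — both
  harmonic-rich confound drivers.
- **Phase→amplitude link**: gamma envelope =
  baseline + depth·(1 + cos(φ − φ_pref))/2 with baseline 0.3, depth 1.0,
  trough-preferring by default. The distractor gamma carries twice the
  modulated source's power with a slowly wandering, phase-independent
  envelope.
- **SNR** is defined as summed signal-source variance over summed noise
  variance at the channels and is met exactly by scaling the noise mixing.
  The default 0.05 was calibrated once and frozen so that the
  single-channel PACz baseline fails (z within ±2 at the power-maximum
  channel) while the GED component succeeds (z ≈ 10) — the regime the
  framework is designed for. The spike-field scene uses SNR 0.2 (40 spikes
  must carry a measurable burst).
- **Bursts**: Gaussian-windowed (σ = 12 ms) carriers at 75 Hz (trough-
  locked scenes) or 70 Hz (spike scenes, 75 Hz distractor), with an
  independently random carrier phase per burst unless disabled.

What a green test does *not* establish: the generators have no volume-
conduction physics (no realistic leadfield geometry), no measurement-noise
model distinct from brain noise, no spike waveforms in the recording
(spikes are event times only, except the constructed artifact test), and
stationary network topographies. Results on real recordings depend on all
of these.

## Permutation statistics

Three seed-deterministic schemes: random-events (refit with count-matched
uniform event times; compare a scalar such as the top eigenvalue against
empirical quantiles), circular-shift (shift one series against the other,
excluding shifts below one low-frequency period; preserves
autocorrelation; default α = 0.01), and bin-shuffle (per-phase-bin
confidence bands from shuffled phase/power assignment). A split-half
utility supports cross-validated filter transfer, and fitting filters on
condition-pooled data leaves between-condition comparisons unbiased (the
filter is defined orthogonally to the condition labels) — verified on
equal-coupling two-condition data. Since random events can pick up the
low-frequency component itself, Method-4-style nulls high-pass the data
first, and coupling claims within one filter-width of the extraction band
should be ignored.

## Known limitations

- No rising/falling-slope phase landmarks and no empirical-mode
  decomposition input for the low-frequency rhythm (extension points).
- No >2-network iterated contrast; no multi-bias (matrix-valued)
  filtering; no automatic embedding-order selection; no Ledoit–Wolf or
  cross-validated shrinkage.
- The delimited-text reader holds the whole file in memory; HDF5 is the
  container for anything sizable. EDF input is not implemented.
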