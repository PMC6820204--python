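# Methods

## Overview

`hgalpha` implements, end to end, an intracranial-EEG analysis of alpha
(7–10 Hz) oscillations across primary (pmHG) and non-primary (alHG) auditory
cortex, together with a synthetic-LFP generator that realizes the effects the
analysis is designed to detect. The pipeline is
simulate → preprocess → localize → time–frequency/spectral analysis → exact
group inference; all randomness descends from one run seed and every region
label used by statistics comes from the functional localization stage, never
from simulator ground truth.

## The synthetic LFP model

Each hemisphere contributes two epoched experiments sampled at 2000 Hz.

**Geometry.** Contacts live in a simplified 3-D frame: an alHG cluster
(default 4 contacts, ±3 mm along the gyrus axis, 1 mm jitter), a pmHG
cluster 12–25 mm down the axis (5 contacts), and 8 scattered superior
temporal contacts 8–40 mm away. Only inter-contact distances enter any
analysis, so no real anatomy is modeled.

**Sentence experiment.** Trials span −1.5 to 6.3 s around sentence onset
with per-trial durations uniform on [1.223, 4.703] s and balanced
clear/vocoded labels. Each contact's voltage is the sum of:

- a Gaussian **1/f^χ background** (χ = 2 by default) built in the frequency
  domain with gain `(max(f, 1 Hz)/8 Hz)^(−χ/2)`; the clamp below 1 Hz mimics
  amplifier high-pass roll-off and keeps the variance finite. The gain is
  anchored at 8 Hz so that changing χ rotates the spectrum about the alpha
  frequency: this makes "exponent change" and "oscillator-gain change"
  orthogonal by construction, which is the ground truth the spectral
  dissociation analysis needs. During the stimulus the exponent can flatten
  by a per-zone Δχ (default 0.3 in alHG, 0 elsewhere), realized as a
  power-preserving cos/sin crossfade between two independent backgrounds;
- an **ongoing alpha oscillation** `A_z · g_i · sin(2πf_α t + φ)` with
  zone amplitudes A = 4.0 (alHG), 2.0 (other), 0.8 (pmHG) relative to the
  unit-SD background, per-trial lognormal amplitude jitter (σ = 0.2) and a
  random phase per trial/contact. Its amplitude is multiplied by
  `1 − s_c · e^(−d/λ) · w(t)`, where s_c is the condition suppression
  (0.75 clear, 0.5 vocoded), d the contact's distance to the alHG centroid,
  λ = 10 mm, and w(t) ramps 0→1 over the first 0.5 s, holds until sentence
  offset and releases over 0.15 s. Amplitudes were chosen so that pmHG's
  post-suppression alpha roughly matches alHG's (4.0 × 0.25 ≈ 0.8), which
  reproduces the characteristic null of a region difference in *raw*
  post-stimulus alpha despite a large prestimulus difference;
- **induced high gamma**: 70–150 Hz band-limited noise gated by the stimulus
  (50 ms ramps), gain 0.25 on pmHG and 10–20% of that elsewhere;
- white **sensor noise** (SD 0.05).

**Click experiment.** 160 ms click trains at 25–200 Hz (20 trials per rate
by default), epoched −0.3 to 0.5 s. The response is the click train
convolved with a damped biphasic kernel (~2 ms dominant deflection).
pmHG responds at 12 ms latency with the sharp kernel; alHG (and weaker,
other contacts) responds at 40 ms through a Gaussian-smoothed kernel
(σ = 0.2 / max_locking_rate, i.e. 4 ms) **with per-trial latency jitter
(SD 4 ms)**. The jitter is what destroys phase locking above ~50 Hz — at
100 Hz the phase scatter is 2π·100·0.004 ≈ 2.5 rad — mirroring the
physiological picture that non-primary responses are temporally sloppy
rather than merely low-pass.

**What the generator does not emulate.** Real anatomy and volume conduction,
shared noise across contacts, non-sinusoidal alpha waveshape, evoked
low-frequency transients at sentence onset, artifacts, or mains interference
(the notch stage is still exercised on constructed tones). Passing tests
therefore show the analysis chain is correct and calibrated on signals with
the designed statistical structure, not that the biological effects exist.

## Problem sizes

Defaults are scaled for a few-minute single-CPU run while keeping the design
fully powered: 8 hemispheres, 17 contacts each (5 pmHG + 4 alHG + 8 other),
20 trials per speech condition, 20 click trains per rate. The epoch grid,
analysis windows, frequency grids and statistical machinery are full-size.
Because the designed effects are large relative to measurement noise (the
per-hemisphere region contrast is ~5 dB against sub-dB estimation error),
the group tests land on the same signed-rank configurations at these sizes
as they would at the full recording sizes.

## Preprocessing

Line noise is removed by spectrum interpolation: rFFT amplitudes within
±1 Hz of 60/120/180 Hz are replaced by the mean amplitude of the ±1–2 Hz
flanks, phases kept. Resampling to 1000 Hz is polyphase with a rational
approximation of the ratio (2034.5 → 1000 uses 2000/4069). Epoching is
half-open [start, stop) on the sample grid with the onset sample at t = 0
and copies samples verbatim.

## Functional localization

ITPC is computed on the 0–0.2 s window with a Hann taper, zero-padded to
1 s so that 1 Hz bins put every click rate on an exact bin. The chance level
is the mean ITPC of 100 phase-randomized copies (phases i.i.d. uniform, DC
and Nyquist kept real, amplitude spectra preserved exactly); "significant"
means exceeding the surrogate mean by 3 surrogate SDs at the stimulus-rate
bin. The evoked criterion detects |evoked| > 3 × baseline SD sustained for
two consecutive samples within 0–20 ms, after a causal 15 Hz high-pass.
Three numerical choices matter here and were made deliberately:

- the high-pass is **causal** (not zero-phase) so filter transients cannot
  precede a late component and fake an early latency;
- the two-consecutive-sample requirement suppresses the multiple-comparison
  false alarms a pointwise 3 SD rule commits across a 20-sample window
  (~7% per contact on 1/f noise, incompatible with reliable localization);
- a contact is pmHG iff *both* criteria hold, so the two ~independent false
  alarm channels multiply.

## Time–frequency analysis

Complex Morlet wavelets with unit energy on the sample grid, truncated at
±3.5 temporal SDs; cycles rise linearly 3→12 across 2–30 Hz (0.2 Hz steps)
and stay at 12 for 40–180 Hz (1 Hz steps). Coefficients are evaluated on a
10 ms grid aligned to t = 0, windows inclusive of both endpoints; an error
naming the offending frequency is raised if the epoch cannot cover the
longest wavelet. Power is trial-averaged first, then converted to dB against
the −0.6 to −0.1 s baseline; the conversion is exactly invertible. The
offset-locked variant re-epochs each trial to its sentence offset (nearest
sample), excludes sentences shorter than the 1.2 s pre-offset window, and
baselines against 0.1–0.6 s post-offset. Unit-energy normalization makes
white-noise power flat across frequency, which the tests exploit.

## Spectral decomposition

Window spectra are trial-averaged Hann periodograms (windows ≥ 0.5 s).
The aperiodic component is fit by OLS of log₁₀ P on log₁₀ f over 2–30 Hz;
whitening divides by the fitted power law (an exact power law maps to 1), and
narrowband alpha is the mean whitened 7–10 Hz value. Division rather than
log-subtraction is the default convention; both are exposed and identical up
to the same fit. The alpha peak is **included** in the fit by default, with
an `exclude_band=(6, 12)` flag for sensitivity analysis. The dissociation
demonstration (exponent-only change leaves whitened alpha fixed; gain-only
change leaves the slope fixed) uses that flag plus 2 s windows, because two
biases otherwise couple the readouts: the peak itself tilts the OLS line
when its gain changes, and 0.5 s windows leak steep sub-2 Hz power into the
lowest fit bins by an exponent-dependent amount.

## Inference

The exact signed-rank test ranks |dᵢ| (average ranks on ties, zeros dropped
with a warning), takes W as the smaller signed rank sum and computes
`p = min(1, 2·P(W_null ≤ W))` from the full null distribution via a
subset-sum dynamic program — an exact equivalent of enumerating all 2^N sign
assignments, cross-checked in tests against brute-force enumeration and
scipy. Effect size r_e maps the one-tailed p to a Student-t quantile at
df = N−1 and returns √(t²/(t²+df)); the df convention is the one that best
reproduces conventional reported values, which pin it down only to ±0.04.
FDR is Benjamini–Hochberg step-up (note p₍ₘ₎ equal to q rejects everything).
Hemisphere-level contrasts shuffle pooled trial labels 1000 times with
`p = (1+k)/(n_perm+1)`. The distance-decay analysis fits alpha dB on
distance to the *localized* alHG centroid per hemisphere (≥3 contacts,
exactly-zero slopes snapped for degenerate constant input) and tests the
slopes against zero with the exact test; the stimulus-by-region interaction
tests the per-hemisphere double difference the same way.

## Known limitations

- The simulator's alpha is a pure sinusoid, so spectral peaks are sharper
  than physiological ones; whitened-alpha magnitudes are not calibrated to
  real data.
- The suppression law is exactly exponential in distance; real spatial decay
  need not be, so distance-decay slopes validate the estimator, not biology.
- Left/right hemispheres are treated identically and pooled by distance only.
- EDF input is a thin reader; no montage/re-referencing logic is provided.
- The permutation test uses unpaired label shuffling of pooled trials; a
  paired within-trial swap variant is not implemented.
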