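"""Conditioning of raw multi-channel recordings.

Line-noise removal uses spectrum interpolation: the Fourier amplitudes in a
narrow band around the mains frequency and its harmonics are replaced by the
mean amplitude of the flanking bands (phases preserved), which notches the
interference by well over 20 dB while leaving the passband untouched.
Resampling is anti-aliased polyphase with a rational approximation of the
rate ratio, so acquisition rates like 2034.5 Hz map cleanly onto 1000 Hz.
Epoching uses a half-open [start, stop) window on the sample grid with the
onset sample defined as t = 0; it copies samples verbatim (no filtering), so
epoch-then-concatenate is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochedRecording

__all__ = ["PreprocessConfig", "remove_line_noise", "resample", "epoch"]


@dataclass(frozen=True)
class PreprocessConfig:
    line_freq: float = 60.0
    n_harmonics: int = 3
    target_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-1.5, 6.3)


def remove_line_noise(data: np.ndarray, sample_rate: float,
                      line_freq: float = 60.0, n_harmonics: int = 3,
                      bandwidth: float = 1.0) -> np.ndarray:
    """Suppress mains interference at ``line_freq`` and its harmonics.

    Operates along the last axis of ``data`` (any leading shape). For each
    harmonic, FFT amplitudes within ``+/-bandwidth`` Hz are replaced by the
    mean amplitude of the two flanking bands of equal width; phases are kept.
    """
    data = np.asarray(data, float)
    n = data.shape[-1]
    harmonics = [line_freq * (k + 1) for k in range(n_harmonics)]
    if sample_rate <= 2 * max(harmonics):
        raise ValueError("sample rate too low for requested harmonics")
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    spec = np.fft.rfft(data, axis=-1)
    for f0 in harmonics:
        notch = np.abs(freqs - f0) <= bandwidth
        if not notch.any():
            continue
        flank = ((np.abs(freqs - f0) > bandwidth)
                 & (np.abs(freqs - f0) <= 2 * bandwidth))
        if not flank.any():
            continue
        target_amp = np.abs(spec[..., flank]).mean(axis=-1, keepdims=True)
        amp = np.abs(spec[..., notch])
        phase = spec[..., notch] / np.where(amp == 0, 1.0, amp)
        phase = np.where(amp == 0, 1.0, phase)
        spec[..., notch] = target_amp * phase
    return np.fft.irfft(spec, n, axis=-1)


def resample(data: np.ndarray, sample_rate: float,
             target_rate: float) -> tuple[np.ndarray, float]:
    """Anti-aliased polyphase resampling along the last axis.

    Returns the resampled array and the exact achieved rate. Non-integer
    ratios (e.g. 2034.5 -> 1000) use a rational approximation of the ratio.
    """
    if target_rate > sample_rate:
        raise ValueError("target rate must not exceed the current rate")
    if target_rate == sample_rate:
        return np.asarray(data, float), sample_rate
    frac = Fraction(target_rate / sample_rate).limit_denominator(10000)
    out = signal.resample_poly(np.asarray(data, float), frac.numerator,
                               frac.denominator, axis=-1)
    achieved = sample_rate * frac.numerator / frac.denominator
    return out, achieved


def epoch(data: np.ndarray, sample_rate: float, onsets_s: np.ndarray,
          window: tuple[float, float],
          conditions: np.ndarray | None = None,
          contact_ids: np.ndarray | None = None) -> EpochedRecording:
    """Cut a continuous (channels, samples) recording into trials.

    The epoch covers the half-open interval [window[0], window[1]) on the
    sample grid, with the onset sample at t = 0. Trials that would run past
    either end of the recording are rejected with a warning.
    """
    data = np.atleast_2d(np.asarray(data, float))
    n_ch, n_samp = data.shape
    start = int(round(window[0] * sample_rate))
    stop = int(round(window[1] * sample_rate))
    if stop <= start:
        raise ValueError("empty epoch window")
    n_epoch = stop - start
    times = (start + np.arange(n_epoch)) / sample_rate

    kept, trials = [], []
    onsets_s = np.atleast_1d(np.asarray(onsets_s, float))
    for i, onset in enumerate(onsets_s):
        o = int(round(onset * sample_rate))
        if o + start < 0 or o + stop > n_samp:
            warnings.warn(f"trial {i} at onset {onset:.3f}s does not fit the "
                          "recording; rejected")
            continue
        kept.append(i)
        trials.append(data[:, o + start:o + stop])
    arr = (np.stack(trials) if trials
           else np.empty((0, n_ch, n_epoch)))
    if conditions is None:
        conditions = np.array([""] * len(onsets_s))
    if contact_ids is None:
        contact_ids = np.array([f"ch{c}" for c in range(n_ch)])
    return EpochedRecording(arr, sample_rate, times,
                            np.asarray(conditions)[kept] if kept
                            else np.asarray(conditions)[:0],
                            contact_ids)
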