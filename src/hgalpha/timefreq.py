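"""Morlet-wavelet time-frequency power with decibel baseline correction.

Low frequencies (2-30 Hz, 0.2 Hz steps) are analyzed with wavelets whose
length grows linearly from 3 cycles at 2 Hz to 12 cycles at 30 Hz; high
frequencies (40-180 Hz, 1 Hz steps) use 12 cycles throughout. Power is the
squared magnitude of the complex coefficients, averaged across trials, on a
10 ms output grid aligned so that t = 0 is a grid point (windows include both
endpoints on the grid). Baseline correction divides by the mean prestimulus
power per frequency and converts to decibels: dB(t,f) = 10 log10(P/P_base).

Wavelets are normalized to unit energy on the sample grid, so white noise
yields flat mean power across frequency; power comparisons are always
within-frequency and the normalization cancels under baselining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .containers import EpochedRecording

__all__ = [
    "WaveletConfig",
    "TFPower",
    "morlet_power",
    "baseline_db",
    "band_window_power",
    "offset_locked_power",
    "wavelet_cycles",
]

#: kernels are truncated at this many Gaussian SDs from the center
_TRUNC_SD = 3.5


@dataclass(frozen=True)
class WaveletConfig:
    low_range: tuple[float, float] = (2.0, 30.0)
    low_step: float = 0.2
    low_cycles: tuple[float, float] = (3.0, 12.0)
    high_range: tuple[float, float] = (40.0, 180.0)
    high_step: float = 1.0
    high_cycles: float = 12.0
    time_step: float = 0.010
    analysis_window: tuple[float, float] = (-0.6, 1.2)
    baseline_window: tuple[float, float] = (-0.6, -0.1)

    def low_freqs(self) -> np.ndarray:
        lo, hi = self.low_range
        n = int(round((hi - lo) / self.low_step))
        return lo + self.low_step * np.arange(n + 1)

    def high_freqs(self) -> np.ndarray:
        lo, hi = self.high_range
        n = int(round((hi - lo) / self.high_step))
        return lo + self.high_step * np.arange(n + 1)


def wavelet_cycles(freqs: np.ndarray, config: WaveletConfig) -> np.ndarray:
    """Cycles per wavelet: linear 3 -> 12 across the low band, 12 above."""
    freqs = np.asarray(freqs, float)
    lo, hi = config.low_range
    c_lo, c_hi = config.low_cycles
    frac = np.clip((freqs - lo) / (hi - lo), 0.0, 1.0)
    cycles = c_lo + frac * (c_hi - c_lo)
    return np.where(freqs >= config.high_range[0], config.high_cycles, cycles)


@dataclass
class TFPower:
    """Trial-aggregated (or per-trial) time-frequency power.

    ``power`` has shape (contacts, freqs, times), or (trials, contacts,
    freqs, times) when trials are kept; ``units`` is "raw" or "dB".
    """

    power: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    contact_ids: np.ndarray
    units: str = "raw"

    def mean_over_trials(self) -> "TFPower":
        if self.power.ndim == 3:
            return self
        return TFPower(self.power.mean(axis=0), self.frequencies, self.times,
                       self.contact_ids, self.units)


def _kernel(freq: float, cycles: float, sample_rate: float) -> np.ndarray:
    """Unit-energy complex Morlet kernel, odd length, truncated at 3.5 SD."""
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(_TRUNC_SD * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    k = np.exp(-0.5 * (t / sigma_t) ** 2) * np.exp(2j * np.pi * freq * t)
    return k / np.sqrt(np.sum(np.abs(k) ** 2))


def _out_times(window: tuple[float, float], step: float) -> np.ndarray:
    """Output grid over ``window``, inclusive of both endpoints, t=0 aligned."""
    k0 = int(round(window[0] / step))
    k1 = int(round(window[1] / step))
    return step * np.arange(k0, k1 + 1)


def morlet_power(epochs: EpochedRecording, config: WaveletConfig | None = None,
                 freqs: np.ndarray | None = None,
                 window: tuple[float, float] | None = None,
                 keep_trials: bool = False) -> TFPower:
    """Morlet-wavelet power over the analysis window.

    By default the full low+high frequency grid is analyzed; pass ``freqs``
    (a subset, e.g. just the alpha band on the 0.2 Hz grid) to restrict.
    Raises if the epoch does not extend far enough past the analysis window
    for the longest wavelet, naming the offending frequency.
    """
    if config is None:
        config = WaveletConfig()
    if freqs is None:
        freqs = np.concatenate([config.low_freqs(), config.high_freqs()])
    freqs = np.asarray(freqs, float)
    cycles = wavelet_cycles(freqs, config)
    if window is None:
        window = config.analysis_window
    out_t = _out_times(window, config.time_step)
    fs = epochs.sample_rate

    sigma = cycles / (2.0 * np.pi * freqs)
    half_s = np.ceil(_TRUNC_SD * sigma * fs) / fs
    for f, h in zip(freqs, half_s):
        if out_t[0] - h < epochs.times[0] - 0.5 / fs or \
           out_t[-1] + h > epochs.times[-1] + 0.5 / fs:
            raise ValueError(
                f"analysis window too close to the epoch edge for {f:g} Hz "
                f"(needs +/-{h:.3f} s of margin)")

    max_half = int(np.ceil(_TRUNC_SD * sigma.max() * fs))
    i_lo = max(0, epochs.time_index(out_t[0]) - max_half)
    i_hi = min(epochs.times.size, epochs.time_index(out_t[-1]) + max_half + 1)
    seg = epochs.data[:, :, i_lo:i_hi]
    m = seg.shape[-1]
    nfft = next_fast_len(m + 2 * max_half + 1)
    spec = fft(seg, nfft, axis=-1)

    # sample indices of the output grid within the cropped segment
    out_idx = np.round((out_t - epochs.times[i_lo]) * fs).astype(int)

    n_tr, n_c = seg.shape[0], seg.shape[1]
    shape = ((n_tr, n_c, freqs.size, out_t.size) if keep_trials
             else (n_c, freqs.size, out_t.size))
    power = np.zeros(shape)
    for fi, (f, cyc) in enumerate(zip(freqs, cycles)):
        k = _kernel(f, cyc, fs)
        center = k.size // 2
        kf = fft(k, nfft)
        coef = ifft(spec * kf, axis=-1)[..., out_idx + center]
        p = np.abs(coef) ** 2
        if keep_trials:
            power[:, :, fi, :] = p
        else:
            power[:, fi, :] = p.mean(axis=0)
    return TFPower(power, freqs, out_t, epochs.contact_ids, "raw")


def baseline_db(tf: TFPower,
                baseline_window: tuple[float, float] = (-0.6, -0.1)) -> TFPower:
    """Convert raw power to dB re. the mean power in the baseline window.

    The baseline mean is taken over the trial-aggregated power per frequency,
    matching the convention of averaging power across trials first.
    """
    if tf.units != "raw":
        raise ValueError("baseline correction must be applied to raw power")
    sel = (tf.times >= baseline_window[0] - 1e-9) & \
          (tf.times <= baseline_window[1] + 1e-9)
    if not sel.any():
        raise ValueError("baseline window selects no time points")
    mean_power = tf.power if tf.power.ndim == 3 else tf.power.mean(axis=0)
    base = mean_power[..., sel].mean(axis=-1, keepdims=True)  # (contacts, f, 1)
    if np.any(base <= 0):
        raise ValueError("zero baseline power; dB correction undefined")
    db = 10.0 * np.log10(tf.power / base)
    return TFPower(db, tf.frequencies, tf.times, tf.contact_ids, "dB")


def band_window_power(tf: TFPower, band: tuple[float, float],
                      window: tuple[float, float]) -> np.ndarray:
    """Mean power over a frequency band and time window (inclusive bins).

    Returns one scalar per contact (per trial and contact if trials kept).
    """
    fsel = (tf.frequencies >= band[0] - 1e-9) & (tf.frequencies <= band[1] + 1e-9)
    tsel = (tf.times >= window[0] - 1e-9) & (tf.times <= window[1] + 1e-9)
    if not fsel.any() or not tsel.any():
        raise ValueError("band/window selects no bins")
    sub = tf.power[..., fsel, :][..., tsel]
    return sub.mean(axis=(-2, -1))


def reepoch_to_offsets(epochs: EpochedRecording,
                       window: tuple[float, float]) -> EpochedRecording:
    """Re-epoch trials so t = 0 is the sentence offset.

    Trials whose sentence is too short for the requested window are excluded
    with a warning.
    """
    if epochs.sentence_durations is None:
        raise ValueError("per-trial sentence durations are required")
    fs = epochs.sample_rate
    n_out = int(round((window[1] - window[0]) * fs))
    times = window[0] + np.arange(n_out) / fs
    keep, rows = [], []
    for i, d in enumerate(epochs.sentence_durations):
        start = int(round((d + window[0] - epochs.times[0]) * fs))
        stop = start + n_out
        if start < 0 or stop > epochs.times.size:
            warnings.warn(f"trial {i} (duration {d:.3f}s) too short for the "
                          "offset-locked window; excluded")
            continue
        keep.append(i)
        rows.append(epochs.data[i, :, start:stop])
    if not rows:
        raise ValueError("no trials long enough for the offset-locked analysis")
    return EpochedRecording(np.stack(rows), fs, times,
                            epochs.conditions[keep], epochs.contact_ids,
                            sentence_durations=epochs.sentence_durations[keep])


def offset_locked_power(epochs: EpochedRecording,
                        config: WaveletConfig | None = None,
                        band: tuple[float, float] = (7.0, 10.0),
                        analysis_window: tuple[float, float] = (-1.2, -0.5),
                        baseline_window: tuple[float, float] = (0.1, 0.6)
                        ) -> np.ndarray:
    """Alpha power time-locked to sentence offset, in dB re. post-offset baseline.

    Trials shorter than the pre-offset window are excluded with a warning.
    Returns one dB value per contact.
    """
    if config is None:
        config = WaveletConfig()
    lo = config.low_freqs()
    freqs = lo[(lo >= band[0] - 1e-9) & (lo <= band[1] + 1e-9)]
    if epochs.sentence_durations is None:
        raise ValueError("per-trial sentence durations are required")
    cycles_min = wavelet_cycles(freqs[:1], config)[0]
    sigma = cycles_min / (2 * np.pi * freqs[0])
    fs = epochs.sample_rate
    pad = (np.ceil(_TRUNC_SD * sigma * fs) + 2) / fs
    span = (analysis_window[0] - pad, baseline_window[1] + pad)
    min_dur = -analysis_window[0]
    long_enough = epochs.sentence_durations >= min_dur
    if not long_enough.all():
        warnings.warn(f"excluding {int((~long_enough).sum())} trial(s) with "
                      f"sentences shorter than {min_dur:g} s from the "
                      "offset-locked analysis")
    if not long_enough.any():
        raise ValueError("no trials long enough for the offset-locked analysis")
    re = reepoch_to_offsets(epochs.select_trials(long_enough), span)
    tf = morlet_power(re, config, freqs=freqs,
                      window=(analysis_window[0], baseline_window[1]))
    db = baseline_db(tf, baseline_window)
    return band_window_power(db, band, analysis_window)
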