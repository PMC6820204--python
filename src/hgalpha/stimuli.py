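"""Acoustic stimulus synthesis: click trains and noise-vocoded sentence surrogates.

Two stimulus families are produced. Click trains (160 ms, rates between 25 and
200 clicks/s) probe phase locking in auditory cortex and drive the functional
split into primary and non-primary fields. Sentence-like stimuli come in a
"clear" version (speech-shaped modulated noise standing in for recorded
sentences; no speech audio is shipped) and a degraded version produced by a
three-band noise vocoder: the signal is split into three contiguous bands
(50-558, 558-2264, 2264-8000 Hz) with FIR Hann band-pass filters, each band's
amplitude envelope (full-wave rectification followed by a 30 Hz fourth-order
Butterworth low-pass) is imposed on band-limited noise, and the three modulated
noises are summed. A stimulus set is equalised for RMS intensity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "ALLOWED_CLICK_RATES",
    "SENTENCE_DURATION_RANGE",
    "AudioStimulus",
    "ClickTrainSpec",
    "VocoderSpec",
    "InvalidSpecification",
    "generate_click_train",
    "click_onset_schedule",
    "vocode",
    "make_sentence_surrogate",
    "rms_normalize",
    "write_wav",
    "read_wav",
    "write_schedule_csv",
]

#: Click-train repetition rates used for functional localization (clicks/s).
ALLOWED_CLICK_RATES = (25, 50, 100, 125, 150, 200)

#: Range of sentence durations in the speech experiment (s).
SENTENCE_DURATION_RANGE = (1.223, 4.703)


class InvalidSpecification(ValueError):
    """Raised when a stimulus specification violates its contract."""


@dataclass(frozen=True)
class ClickTrainSpec:
    """Parameters of one click-train condition.

    ``rate`` must be one of :data:`ALLOWED_CLICK_RATES`; ``rate * duration``
    is an integer click count for all of them. Successive train onsets are
    drawn from a normal distribution (mean ``onset_interval_mean``, SD
    ``onset_interval_sd``).
    """

    rate: float
    duration: float = 0.160
    n_trials: int = 50
    onset_interval_mean: float = 2.0
    onset_interval_sd: float = 0.010
    sample_rate: float = 44100.0

    def validate(self) -> None:
        if self.rate not in ALLOWED_CLICK_RATES:
            raise InvalidSpecification(
                f"click rate {self.rate} not in supported set {ALLOWED_CLICK_RATES}"
            )
        if self.sample_rate < 2 * self.rate:
            raise InvalidSpecification("sample rate below Nyquist for click rate")
        if min(self.duration, self.n_trials, self.onset_interval_mean,
               self.onset_interval_sd, self.sample_rate) <= 0:
            raise InvalidSpecification("all click-train parameters must be positive")


@dataclass(frozen=True)
class VocoderSpec:
    """Three-band noise vocoder settings.

    ``band_filter_window_len`` is the FIR Hann window length at 44.1 kHz;
    for other sample rates it is scaled proportionally (rounded to odd) so the
    transition bandwidth in Hz is preserved.
    """

    band_edges: tuple[float, ...] = (50.0, 558.0, 2264.0, 8000.0)
    envelope_cutoff: float = 30.0
    envelope_filter_order: int = 4
    band_filter_window_len: int = 801
    sample_rate: float = 44100.0

    def validate(self) -> None:
        edges = np.asarray(self.band_edges, float)
        if not np.all(np.diff(edges) > 0):
            raise InvalidSpecification("band edges must be strictly increasing")
        if self.sample_rate <= 2 * edges[-1]:
            raise InvalidSpecification(
                f"sample rate {self.sample_rate} too low for top band edge {edges[-1]}"
            )
        if self.band_filter_window_len % 2 == 0:
            raise InvalidSpecification("FIR window length must be odd")
        if self.envelope_cutoff >= edges[0] * self.sample_rate:
            raise InvalidSpecification("envelope cutoff too high")

    def numtaps(self, sample_rate: float) -> int:
        """FIR length at ``sample_rate``, scaled from the 44.1 kHz reference."""
        n = int(round(self.band_filter_window_len * sample_rate / 44100.0))
        return n if n % 2 == 1 else n + 1


@dataclass
class AudioStimulus:
    """A pressure waveform with its sample rate and condition label."""

    samples: np.ndarray
    sample_rate: float
    condition: str  # one of {"clear", "vocoded", "click"}
    onsets_s: np.ndarray | None = field(default=None, repr=False)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def click_onset_schedule(spec: ClickTrainSpec, seed: int) -> np.ndarray:
    """Trial onset times (s) for ``spec.n_trials`` presentations.

    Inter-onset intervals are i.i.d. normal with the spec's mean and SD;
    the schedule is a deterministic function of ``seed``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    intervals = rng.normal(spec.onset_interval_mean, spec.onset_interval_sd,
                           size=spec.n_trials)
    onsets = np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    return onsets


def generate_click_train(spec: ClickTrainSpec, seed: int) -> AudioStimulus:
    """One click train: unit impulses at ``spec.rate`` spanning ``spec.duration``.

    Clicks are single-sample unit impulses (maximally flat spectrum). The
    returned stimulus also carries the seeded trial onset schedule.
    """
    spec.validate()
    n = int(round(spec.duration * spec.sample_rate))
    wave = np.zeros(n)
    n_clicks = int(round(spec.rate * spec.duration))
    click_times = np.arange(n_clicks) / spec.rate
    idx = np.round(click_times * spec.sample_rate).astype(int)
    wave[idx[idx < n]] = 1.0
    return AudioStimulus(wave, spec.sample_rate, "click",
                         onsets_s=click_onset_schedule(spec, seed))


def _band_filter(x: np.ndarray, lo: float, hi: float, numtaps: int,
                 sample_rate: float) -> np.ndarray:
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hann",
                         fs=sample_rate)
    # zero-phase FIR: shift out the (numtaps-1)/2 group delay
    y = signal.lfilter(taps, 1.0, np.concatenate([x, np.zeros(numtaps // 2)]))
    return y[numtaps // 2:]


def vocode(stimulus: AudioStimulus, spec: VocoderSpec | None = None, *,
           seed: int = 0) -> AudioStimulus:
    """Three-band noise vocoding of a clear stimulus.

    Each band's full-wave-rectified, 30 Hz low-passed envelope is applied to
    noise band-limited to the same range; bands are summed and the result is
    RMS-matched to the input.
    """
    if spec is None:
        spec = VocoderSpec(sample_rate=stimulus.sample_rate)
    spec.validate()
    if stimulus.condition != "clear":
        raise InvalidSpecification("vocoder input must be a clear stimulus")
    sr = stimulus.sample_rate
    if sr < 16000:
        raise InvalidSpecification("sample rate must be at least 16 kHz")
    if sr <= 2 * spec.band_edges[-1]:
        raise InvalidSpecification("sample rate too low for top band edge")

    numtaps = spec.numtaps(sr)
    b_lp, a_lp = signal.butter(spec.envelope_filter_order,
                               spec.envelope_cutoff, btype="low", fs=sr)
    rng = np.random.default_rng(seed)
    x = np.asarray(stimulus.samples, float)
    out = np.zeros_like(x)
    for lo, hi in zip(spec.band_edges[:-1], spec.band_edges[1:]):
        band = _band_filter(x, lo, hi, numtaps, sr)
        env = signal.lfilter(b_lp, a_lp, np.abs(band))
        env = np.clip(env, 0.0, None)
        carrier = _band_filter(rng.standard_normal(x.size), lo, hi, numtaps, sr)
        out += env * carrier
    in_rms = stimulus.rms()
    out_rms = np.sqrt(np.mean(out ** 2))
    if out_rms > 0 and in_rms > 0:
        out *= in_rms / out_rms
    return AudioStimulus(out, sr, "vocoded")


def make_sentence_surrogate(duration: float, seed: int,
                            sample_rate: float = 44100.0) -> AudioStimulus:
    """Speech-shaped noise with syllable-rate (2-8 Hz) envelope modulation.

    A stand-in for recorded sentences: broadband noise with a gentle spectral
    tilt above ~500 Hz, amplitude-modulated by a 2-8 Hz band-limited envelope,
    deterministic in ``seed``. Durations outside the sentence range raise.
    """
    lo, hi = SENTENCE_DURATION_RANGE
    if not (lo <= duration <= hi):
        raise InvalidSpecification(
            f"sentence duration {duration} outside [{lo}, {hi}] s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    noise = rng.standard_normal(n)
    # speech-like tilt: first-order low-pass shoulder at 500 Hz
    spec_f = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    spec_f *= 1.0 / np.sqrt(1.0 + (freqs / 500.0) ** 2)
    carrier = np.fft.irfft(spec_f, n)
    # 2-8 Hz modulator
    b, a = signal.butter(2, [2.0, 8.0], btype="band", fs=sample_rate)
    mod = signal.lfilter(b, a, rng.standard_normal(n))
    mod = mod / (3.0 * np.std(mod))
    env = np.clip(1.0 + 0.9 * mod, 0.05, None)
    wave = carrier * env
    wave /= np.sqrt(np.mean(wave ** 2))
    return AudioStimulus(wave, sample_rate, "clear")


def rms_normalize(stimuli: Sequence[AudioStimulus],
                  target_rms: float = 0.05) -> list[AudioStimulus]:
    """Scale every stimulus in a set to the same RMS intensity."""
    out = []
    for s in stimuli:
        r = s.rms()
        if r == 0:
            raise InvalidSpecification("cannot RMS-normalize an all-zero stimulus")
        out.append(AudioStimulus(s.samples * (target_rms / r), s.sample_rate,
                                 s.condition, onsets_s=s.onsets_s))
    return out


def write_wav(path: str | Path, stimulus: AudioStimulus) -> None:
    wavfile.write(str(path), int(stimulus.sample_rate),
                  stimulus.samples.astype(np.float32))


def read_wav(path: str | Path, condition: str = "clear") -> AudioStimulus:
    sr, data = wavfile.read(str(path))
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return AudioStimulus(np.asarray(data, float), float(sr), condition)


def write_schedule_csv(path: str | Path,
                       rows: Iterable[tuple[int, str, float, float]]) -> None:
    """Write a presentation schedule: (trial, condition, onset_s, duration_s)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "condition", "onset_s", "duration_s"])
        for row in rows:
            w.writerow(list(row))
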