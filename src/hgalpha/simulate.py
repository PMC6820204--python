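"""Synthetic multi-contact LFP generator.

Emulates the statistical structure of intracranial recordings from superior
temporal cortex in two experiments per hemisphere:

* a **click-train experiment** (160 ms trains at 25-200 clicks/s) in which
  posteromedial Heschl's gyrus (pmHG) contacts respond with short-latency
  (<20 ms) components that phase-lock up to 200 Hz, while anterolateral (alHG)
  contacts respond late (>20 ms) through a temporally smoothed kernel that
  cannot follow rates above ~50 Hz;

* a **sentence experiment** (epochs -1.5 to 6.3 s around onset) in which an
  ongoing ~8 Hz alpha oscillation — strong on alHG contacts, weak on pmHG —
  is multiplicatively suppressed from stimulus onset (reaching a plateau by
  0.5 s) until sentence offset, more for clear than for degraded ("vocoded")
  trials, with the suppression decaying exponentially with distance from the
  alHG centroid; pmHG contacts instead gain induced high-gamma (70-150 Hz)
  power during the sentence.

All contacts ride on a scale-free 1/f^chi background. The background's
spectral density is anchored at the alpha frequency, so changing the exponent
rotates the spectrum about 8 Hz: a pure exponent ("slope") change leaves the
whitened narrowband alpha peak unchanged, which is exactly the dissociation
the spectral module must be able to demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ContactSet, EpochedRecording

__all__ = [
    "SimulationParams",
    "SimulatedDataset",
    "simulate_dataset",
    "spectral_background",
]


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of the synthetic dataset.

    Amplitudes are in arbitrary voltage units relative to the unit-variance
    background; distances in mm; times in s. ``suppression_*`` are fractional
    amplitude reductions of the alpha oscillator at the alHG centroid
    (0.75 means the oscillation drops to 25% of its baseline amplitude, i.e.
    20*log10(0.25) ~ -12 dB of band power).
    """

    chi: float = 2.0
    alpha_freq: float = 8.0
    alpha_amp_alHG: float = 4.0
    alpha_amp_pmHG: float = 0.8
    alpha_amp_other: float = 2.0
    alpha_trial_cv: float = 0.2          # lognormal sigma of per-trial alpha amp
    suppression_clear: float = 0.75
    suppression_vocoded: float = 0.5
    suppression_ramp_time: float = 0.5
    suppression_release_time: float = 0.15
    spatial_decay_lambda: float = 10.0
    hg_response_amp: float = 0.25        # pmHG high-gamma gain; alHG gets 10%
    hg_band: tuple[float, float] = (70.0, 150.0)
    hg_ramp_time: float = 0.05
    click_response_amp: float = 6.0
    click_latency_pmHG: float = 0.012
    click_latency_alHG: float = 0.040
    click_locking_max_rate_alHG: float = 50.0
    click_jitter_sd_alHG: float = 0.004  # trial latency jitter kills locking >50 Hz
    sensor_noise_sd: float = 0.05        # white measurement-noise floor
    chi_stim_delta_alHG: float = 0.3     # exponent flattening during stimulus
    chi_stim_delta_pmHG: float = 0.0
    chi_stim_delta_other: float = 0.0
    noise_sd: float = 1.0
    n_hemispheres: int = 8
    n_trials_per_condition: int = 20
    n_click_trials_per_rate: int = 20
    click_rates: tuple[float, ...] = (25.0, 50.0, 100.0, 125.0, 150.0, 200.0)
    n_pmhg: int = 5
    n_alhg: int = 4
    n_other: int = 8
    sample_rate: float = 2000.0
    sentence_epoch: tuple[float, float] = (-1.5, 6.3)
    click_epoch: tuple[float, float] = (-0.3, 0.5)
    sentence_duration_range: tuple[float, float] = (1.223, 4.703)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.suppression_vocoded < 1.0
                and 0.0 <= self.suppression_clear < 1.0):
            raise ValueError("suppression fractions must lie in [0, 1)")
        if self.suppression_clear < self.suppression_vocoded:
            raise ValueError("suppression_clear must be >= suppression_vocoded")
        if self.click_latency_pmHG >= 0.020:
            raise ValueError("pmHG click latency must be below 20 ms")
        if self.click_latency_alHG <= 0.020:
            raise ValueError("alHG click latency must exceed 20 ms")
        if min(self.alpha_amp_alHG, self.alpha_amp_pmHG, self.alpha_amp_other,
               self.hg_response_amp, self.click_response_amp) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_trials_per_condition <= 0 or self.n_click_trials_per_rate <= 0:
            raise ValueError("trial counts must be positive")
        if self.chi < 0:
            raise ValueError("chi must be non-negative")


@dataclass
class SimulatedDataset:
    """Per-hemisphere epoched recordings plus the global contact table."""

    contacts: ContactSet
    sentence_epochs: list[EpochedRecording]
    click_epochs: list[EpochedRecording]
    params: SimulationParams

    def hemisphere_contacts(self, hemi: int) -> ContactSet:
        return self.contacts.hemisphere(hemi)


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, ...],
                  chi: np.ndarray | float, sample_rate: float,
                  amplitude: float = 1.0, f_ref: float = 8.0,
                  f_min: float = 1.0) -> np.ndarray:
    """Gaussian noise with PSD proportional to f^-chi along the last axis.

    The gain is anchored at ``f_ref`` (unity there regardless of chi) and
    clamped below ``f_min`` to keep the variance finite. ``chi`` may be a
    scalar or broadcastable against ``shape[:-1]`` (per-channel exponents).
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    f_eff = np.maximum(freqs, f_min)
    chi_arr = np.asarray(chi, float)
    gain = (f_eff / f_ref) ** (-chi_arr[..., None] / 2.0)
    gain[..., 0] = 0.0  # zero-mean
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1) * gain
    return amplitude * np.fft.irfft(spec, n, axis=-1)


def spectral_background(chi: float, n_samples: int, sample_rate: float,
                        seed: int | np.random.Generator,
                        amplitude: float = 1.0) -> np.ndarray:
    """A single 1/f^chi background trace.

    Log-log spectral slope equals ``-chi`` over the analysis range (2-180 Hz);
    standard deviation scales linearly with ``amplitude``.
    """
    if chi < 0:
        raise ValueError("chi must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _shaped_noise(rng, (int(n_samples),), float(chi), sample_rate,
                         amplitude=amplitude)


_ZONE_FIELDS = {
    "pmHG": ("alpha_amp_pmHG", "chi_stim_delta_pmHG"),
    "alHG": ("alpha_amp_alHG", "chi_stim_delta_alHG"),
    "STP_STG_other": ("alpha_amp_other", "chi_stim_delta_other"),
}


def _place_contacts(params: SimulationParams,
                    rng: np.random.Generator) -> ContactSet:
    """Simplified 3-D geometry: an alHG cluster at the local origin, a pmHG
    cluster 12-25 mm down the gyrus axis, and lateral contacts scattered
    8-40 mm away. Only inter-contact distances enter the analysis."""
    ids, hemis, coords, zones = [], [], [], []
    axis = np.array([1.0, 0.6, 0.25])
    axis /= np.linalg.norm(axis)
    for h in range(params.n_hemispheres):
        origin = np.array([0.0, 100.0 * h, 0.0])  # keep hemispheres apart
        for k in range(params.n_alhg):
            pos = origin + axis * rng.uniform(-3, 3) + rng.normal(0, 1.0, 3)
            ids.append(f"H{h}_al{k}"); hemis.append(h)
            coords.append(pos); zones.append("alHG")
        for k in range(params.n_pmhg):
            pos = origin + axis * rng.uniform(12, 25) + rng.normal(0, 1.5, 3)
            ids.append(f"H{h}_pm{k}"); hemis.append(h)
            coords.append(pos); zones.append("pmHG")
        for k in range(params.n_other):
            direction = rng.normal(0, 1, 3)
            direction /= np.linalg.norm(direction)
            pos = origin + direction * rng.uniform(8, 40)
            ids.append(f"H{h}_st{k}"); hemis.append(h)
            coords.append(pos); zones.append("STP_STG_other")
    return ContactSet(np.array(ids), np.array(hemis), np.array(coords),
                      np.array(zones))


def _stim_profile(times: np.ndarray, onset: float, offset: float,
                  ramp: float, release: float) -> np.ndarray:
    """0 before onset, linear ramp to 1 over ``ramp`` s, hold until ``offset``,
    linear release back to 0 over ``release`` s."""
    w = np.clip((times - onset) / max(ramp, 1e-9), 0.0, 1.0)
    down = np.clip((times - offset) / max(release, 1e-9), 0.0, 1.0)
    return w * (1.0 - down)


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...],
                band: tuple[float, float], sample_rate: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (FFT masking)."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    spec[..., ~mask] = 0.0
    x = np.fft.irfft(spec, n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _click_kernel(sample_rate: float, smooth_sigma: float = 0.0) -> np.ndarray:
    """Damped biphasic impulse response (~2 ms dominant deflection).

    ``smooth_sigma`` > 0 convolves with a Gaussian, low-passing the response
    so phase locking fails above roughly 0.2/sigma Hz."""
    t = np.arange(0.0, 0.015, 1.0 / sample_rate)
    k = np.sin(2 * np.pi * 350.0 * t) * np.exp(-t / 0.003)
    if smooth_sigma > 0:
        half = int(round(4 * smooth_sigma * sample_rate))
        tg = np.arange(-half, half + 1) / sample_rate
        g = np.exp(-0.5 * (tg / smooth_sigma) ** 2)
        g /= g.sum()
        k = np.convolve(k, g)
    return k


def _sentence_hemisphere(params: SimulationParams, contacts: ContactSet,
                         rng: np.random.Generator) -> EpochedRecording:
    fs = params.sample_rate
    t0, t1 = params.sentence_epoch
    n = int(round((t1 - t0) * fs))
    times = t0 + np.arange(n) / fs
    n_c = len(contacts)
    n_tr = 2 * params.n_trials_per_condition

    conditions = np.array(["clear"] * params.n_trials_per_condition
                          + ["vocoded"] * params.n_trials_per_condition)
    rng.shuffle(conditions)
    durations = rng.uniform(*params.sentence_duration_range, size=n_tr)

    dist = contacts.distance_to_alhg_centroid()
    decay = np.exp(-dist / params.spatial_decay_lambda)
    alpha_amp = np.empty(n_c)
    chi_delta = np.empty(n_c)
    hg_amp = np.empty(n_c)
    for z, (amp_field, delta_field) in _ZONE_FIELDS.items():
        m = contacts.zone == z
        alpha_amp[m] = getattr(params, amp_field)
        chi_delta[m] = getattr(params, delta_field)
    hg_amp[:] = 0.0
    hg_amp[contacts.zone == "pmHG"] = params.hg_response_amp
    hg_amp[contacts.zone == "alHG"] = 0.1 * params.hg_response_amp
    hg_amp[contacts.zone == "STP_STG_other"] = 0.2 * params.hg_response_amp

    supp_frac = {"clear": params.suppression_clear,
                 "vocoded": params.suppression_vocoded}

    data = np.empty((n_tr, n_c, n))
    for i in range(n_tr):
        w = _stim_profile(times, 0.0, durations[i],
                          params.suppression_ramp_time,
                          params.suppression_release_time)
        w_hg = _stim_profile(times, 0.0, durations[i], params.hg_ramp_time,
                             params.hg_ramp_time)
        # background: power-preserving crossfade between the baseline
        # exponent and the (possibly flattened) during-stimulus exponent
        b_base = _shaped_noise(rng, (n_c, n), np.full(n_c, params.chi), fs,
                               amplitude=params.noise_sd)
        if np.any(chi_delta != 0.0):
            b_stim = _shaped_noise(rng, (n_c, n), params.chi - chi_delta, fs,
                                   amplitude=params.noise_sd)
            cw = np.cos(0.5 * np.pi * w)
            sw = np.sin(0.5 * np.pi * w)
            bg = cw * b_base + sw * b_stim
        else:
            bg = b_base
        # ongoing alpha oscillation with multiplicative suppression
        phase = rng.uniform(0, 2 * np.pi, size=(n_c, 1))
        trial_gain = np.exp(rng.normal(0.0, params.alpha_trial_cv, size=(n_c, 1)))
        s = supp_frac[str(conditions[i])]
        envelope = 1.0 - s * decay[:, None] * w[None, :]
        osc = np.sin(2 * np.pi * params.alpha_freq * times[None, :] + phase)
        alpha = alpha_amp[:, None] * trial_gain * envelope * osc
        # induced high gamma during the sentence
        hg = hg_amp[:, None] * w_hg[None, :] * _band_noise(
            rng, (n_c, n), params.hg_band, fs)
        sensor = params.sensor_noise_sd * rng.standard_normal((n_c, n))
        data[i] = bg + alpha + hg + sensor
    return EpochedRecording(data, fs, times, conditions, contacts.contact_id,
                            sentence_durations=durations)


def _click_hemisphere(params: SimulationParams, contacts: ContactSet,
                      rng: np.random.Generator) -> EpochedRecording:
    fs = params.sample_rate
    t0, t1 = params.click_epoch
    n = int(round((t1 - t0) * fs))
    times = t0 + np.arange(n) / fs
    n_c = len(contacts)

    smooth = 0.2 / params.click_locking_max_rate_alHG
    # (kernel, latency, gain, per-trial latency jitter SD)
    kernels = {"pmHG": (_click_kernel(fs), params.click_latency_pmHG, 1.0, 0.0),
               "alHG": (_click_kernel(fs, smooth), params.click_latency_alHG,
                        1.0, params.click_jitter_sd_alHG),
               "STP_STG_other": (_click_kernel(fs, smooth),
                                 params.click_latency_alHG, 0.3,
                                 params.click_jitter_sd_alHG)}

    # per-zone template response for each click rate
    templates: dict[tuple[str, float], np.ndarray] = {}
    for rate in params.click_rates:
        n_clicks = int(round(rate * 0.160))
        for z, (kern, lat, gain, _) in kernels.items():
            resp = np.zeros(n)
            for k in range(n_clicks):
                idx = int(round((k / rate + lat - t0) * fs))
                if idx < n:
                    resp[idx] += 1.0
            resp = np.convolve(resp, kern)[:n]
            templates[(z, rate)] = gain * params.click_response_amp * resp

    rates = np.repeat(params.click_rates, params.n_click_trials_per_rate)
    n_tr = rates.size
    data = np.empty((n_tr, n_c, n))
    zone_rows = {z: contacts.zone == z for z in kernels}
    for i, rate in enumerate(rates):
        bg = _shaped_noise(rng, (n_c, n), np.full(n_c, params.chi), fs,
                           amplitude=params.noise_sd)
        trial = bg + params.sensor_noise_sd * rng.standard_normal((n_c, n))
        for z, (_, _, _, jitter_sd) in kernels.items():
            rows = np.flatnonzero(zone_rows[z])
            template = templates[(z, float(rate))]
            if jitter_sd == 0:
                trial[rows] += template
            else:
                # non-primary latencies jitter trial to trial, so phase
                # locking decays above ~1/(2*pi*jitter) Hz
                shifts = np.round(rng.normal(0, jitter_sd, rows.size)
                                  * fs).astype(int)
                for r_idx, sh in zip(rows, shifts):
                    trial[r_idx] += np.roll(template, sh)
        data[i] = trial
    return EpochedRecording(data, fs, times, rates.astype(float),
                            contacts.contact_id)


def simulate_dataset(params: SimulationParams | None = None) -> SimulatedDataset:
    """Generate the full synthetic study: contact table plus one click-train
    and one sentence experiment per hemisphere, reproducible from
    ``params.seed``."""
    if params is None:
        params = SimulationParams()
    params.validate()
    root = np.random.SeedSequence(params.seed)
    geom_ss, *hemi_ss = root.spawn(1 + 2 * params.n_hemispheres)
    contacts = _place_contacts(params, np.random.default_rng(geom_ss))
    sentence, clicks = [], []
    for h in range(params.n_hemispheres):
        sub = contacts.hemisphere(h)
        sentence.append(_sentence_hemisphere(
            params, sub, np.random.default_rng(hemi_ss[2 * h])))
        clicks.append(_click_hemisphere(
            params, sub, np.random.default_rng(hemi_ss[2 * h + 1])))
    return SimulatedDataset(contacts, sentence, clicks, params)
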