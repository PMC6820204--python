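"""Functional assignment of Heschl's-gyrus contacts to primary / non-primary fields.

A contact is assigned to the primary field (pmHG) iff it satisfies BOTH
criteria: significant phase locking to 100 Hz click trains (empirical ITPC
above the surrogate chance level), and a short-latency (<20 ms) component in
the averaged click-evoked potential. Gyrus contacts failing either criterion
are assigned to the non-primary field (alHG). Contacts outside the gyrus are
never classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochedRecording
from .phaselock import ITPCResult, is_significant_at_rate

__all__ = [
    "LocalizationConfig",
    "averaged_evoked_potential",
    "detect_short_latency",
    "classify_contacts",
]


@dataclass(frozen=True)
class LocalizationConfig:
    itpc_rate: float = 100.0        # criterion click rate (Hz)
    extra_rates: tuple[float, ...] = ()  # optionally accept any of {100,125,150}
    itpc_n_sd: float = 3.0
    threshold_sd: float = 3.0       # evoked amplitude criterion
    latency_window: tuple[float, float] = (0.0, 0.020)
    baseline_window: tuple[float, float] = (-0.1, 0.0)


def averaged_evoked_potential(epochs: EpochedRecording,
                              baseline: tuple[float, float] = (-0.1, 0.0),
                              min_trials: int = 10
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Trial-mean voltage per contact, baseline-subtracted.

    Returns ``(evoked, times)`` with ``evoked`` of shape (contacts, samples).
    """
    if epochs.n_trials < min_trials:
        raise ValueError(f"need at least {min_trials} trials for an evoked "
                         f"potential, got {epochs.n_trials}")
    evoked = epochs.data.mean(axis=0)
    i0 = epochs.time_index(baseline[0])
    i1 = epochs.time_index(baseline[1])
    if i1 <= i0 or i0 < 0:
        raise ValueError("baseline window outside the epoch")
    evoked = evoked - evoked[:, i0:i1].mean(axis=1, keepdims=True)
    return evoked, epochs.times.copy()


def detect_short_latency(evoked: np.ndarray, times: np.ndarray,
                         threshold_sd: float = 3.0,
                         window: tuple[float, float] = (0.0, 0.020),
                         baseline: tuple[float, float] = (-0.1, 0.0),
                         highpass_hz: float | None = 15.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Detect early evoked components per contact.

    A component is present iff |evoked| exceeds ``threshold_sd`` times the
    prestimulus baseline SD at any sample strictly inside ``window``; the
    latency is the first crossing. Returns ``(present, latency_s)`` with
    latency NaN where absent. Short-latency components are fast deflections,
    so slow drift (the dominant part of 1/f activity) is removed first with
    a causal high-pass at ``highpass_hz`` (causal so that filter transients
    cannot precede the component and bias the latency; None disables it), and the
    crossing must be sustained for two consecutive samples, since a genuine
    evoked deflection is at least ~2 ms wide while single-sample noise
    excursions are not.
    """
    evoked = np.atleast_2d(np.asarray(evoked, float))
    if highpass_hz is not None:
        fs = 1.0 / float(np.median(np.diff(times)))
        sos = signal.butter(2, highpass_hz, btype="high", fs=fs, output="sos")
        evoked = signal.sosfilt(sos, evoked, axis=-1)
    base = (times >= baseline[0]) & (times < baseline[1])
    if base.sum() < 10:
        raise ValueError("baseline too short for SD estimation (need >=100 ms)")
    sd = evoked[:, base].std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero baseline variance; cannot set a threshold")
    win = (times > window[0]) & (times < window[1])
    present = np.zeros(evoked.shape[0], bool)
    latency = np.full(evoked.shape[0], np.nan)
    above = np.abs(evoked[:, win]) > (threshold_sd * sd)[:, None]
    sustained = above[:, :-1] & above[:, 1:]
    t_win = times[win]
    for c in range(evoked.shape[0]):
        hits = np.flatnonzero(sustained[c])
        if hits.size:
            present[c] = True
            latency[c] = t_win[hits[0]]
    return present, latency


def classify_contacts(itpc: ITPCResult, chance: ITPCResult,
                      evoked: np.ndarray, times: np.ndarray,
                      on_heschl: np.ndarray,
                      config: LocalizationConfig | None = None) -> pd.DataFrame:
    """Per-contact field assignment for gyrus contacts.

    Returns a DataFrame with columns ``contact_id``, ``on_heschl``,
    ``itpc_significant``, ``short_latency_component``, ``evoked_latency`` and
    ``assigned_field`` ("pmHG"/"alHG" on the gyrus, empty otherwise).
    """
    if config is None:
        config = LocalizationConfig()
    if itpc.values.shape[0] != evoked.shape[0]:
        raise ValueError("ITPC and evoked cover different contact sets")
    if not np.array_equal(itpc.contact_ids, chance.contact_ids):
        raise ValueError("empirical and chance ITPC cover different contacts")
    on_heschl = np.asarray(on_heschl, bool)
    if on_heschl.size != evoked.shape[0]:
        raise ValueError("gyrus mask does not match contact count")

    sig = is_significant_at_rate(itpc, chance, config.itpc_rate,
                                 config.itpc_n_sd)
    for rate in config.extra_rates:
        sig = sig | is_significant_at_rate(itpc, chance, rate, config.itpc_n_sd)
    present, latency = detect_short_latency(
        evoked, times, config.threshold_sd, config.latency_window,
        config.baseline_window)

    field = np.where(sig & present, "pmHG", "alHG")
    field = np.where(on_heschl, field, "")
    return pd.DataFrame({
        "contact_id": itpc.contact_ids,
        "on_heschl": on_heschl,
        "itpc_significant": sig,
        "short_latency_component": present,
        "evoked_latency": latency,
        "assigned_field": field,
    })
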