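"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ContactSet", "EpochedRecording"]


@dataclass
class ContactSet:
    """Recording contacts with coordinates and anatomical annotations.

    ``zone`` is the simulator's ground-truth field label ({"pmHG", "alHG",
    "STP_STG_other"}); the analysis pipeline never consumes it directly —
    it only uses ``on_heschl`` (anatomical gyrus membership, which in real
    data comes from imaging) and re-derives the pm/al split functionally.
    """

    contact_id: np.ndarray          # str array, unique
    hemisphere_id: np.ndarray       # int array
    coordinates: np.ndarray         # (n, 3) mm
    zone: np.ndarray                # str array

    def __post_init__(self) -> None:
        self.contact_id = np.asarray(self.contact_id)
        self.hemisphere_id = np.asarray(self.hemisphere_id, int)
        self.coordinates = np.asarray(self.coordinates, float)
        self.zone = np.asarray(self.zone)
        n = self.contact_id.size
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (n_contacts, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if len(set(self.contact_id.tolist())) != n:
            raise ValueError("contact ids must be unique")

    def __len__(self) -> int:
        return int(self.contact_id.size)

    @property
    def on_heschl(self) -> np.ndarray:
        """Anatomical Heschl's-gyrus membership (pmHG or alHG zones)."""
        return np.isin(self.zone, ("pmHG", "alHG"))

    def subset(self, mask: np.ndarray) -> "ContactSet":
        return ContactSet(self.contact_id[mask], self.hemisphere_id[mask],
                          self.coordinates[mask], self.zone[mask])

    def hemisphere(self, hemi: int) -> "ContactSet":
        return self.subset(self.hemisphere_id == hemi)

    def distances_to_centroid(self, centroid_mask: np.ndarray) -> np.ndarray:
        """Per-contact Euclidean distance (mm) to the mean coordinate of the
        masked contacts within the same hemisphere."""
        centroid_mask = np.asarray(centroid_mask, bool)
        d = np.full(len(self), np.nan)
        for hemi in np.unique(self.hemisphere_id):
            in_h = self.hemisphere_id == hemi
            sel = in_h & centroid_mask
            if not sel.any():
                continue
            centroid = self.coordinates[sel].mean(axis=0)
            d[in_h] = np.linalg.norm(self.coordinates[in_h] - centroid, axis=1)
        return d

    def distance_to_alhg_centroid(self) -> np.ndarray:
        """Distance to the ground-truth alHG centroid (simulator bookkeeping)."""
        return self.distances_to_centroid(self.zone == "alHG")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "contact_id": self.contact_id,
            "hemisphere_id": self.hemisphere_id,
            "x": self.coordinates[:, 0],
            "y": self.coordinates[:, 1],
            "z": self.coordinates[:, 2],
            "zone": self.zone,
            "distance_to_alHG_centroid": self.distance_to_alhg_centroid(),
        })


@dataclass
class EpochedRecording:
    """Epoched multi-contact voltage data.

    ``data`` has shape (n_trials, n_contacts, n_samples); ``times`` is the
    common time axis in seconds relative to stimulus onset. ``conditions``
    holds per-trial labels ("clear"/"vocoded" for sentences, the click rate
    for click trains); ``sentence_durations`` is per-trial stimulus duration
    where applicable.
    """

    data: np.ndarray
    sample_rate: float
    times: np.ndarray
    conditions: np.ndarray
    contact_ids: np.ndarray
    sentence_durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        self.conditions = np.asarray(self.conditions)
        self.contact_ids = np.asarray(self.contact_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, contacts, samples)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match data")
        if self.data.shape[0] != self.conditions.size:
            raise ValueError("conditions do not match trial count")
        if self.data.shape[1] != self.contact_ids.size:
            raise ValueError("contact ids do not match data")
        if np.isnan(self.data).any():
            raise ValueError("epoched data contains NaNs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.data.shape[1]

    def select_trials(self, mask: np.ndarray) -> "EpochedRecording":
        dur = None if self.sentence_durations is None else self.sentence_durations[mask]
        return EpochedRecording(self.data[mask], self.sample_rate, self.times,
                                self.conditions[mask], self.contact_ids,
                                sentence_durations=dur)

    def select_contacts(self, mask: np.ndarray) -> "EpochedRecording":
        return EpochedRecording(self.data[:, mask], self.sample_rate, self.times,
                                self.conditions, self.contact_ids[mask],
                                sentence_durations=self.sentence_durations)

    def time_index(self, t: float) -> int:
        """Index of the sample at time ``t`` (exact grid arithmetic)."""
        return int(round((t - self.times[0]) * self.sample_rate))
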