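"""Optional input of real recordings: EDF files plus a contact table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContactSet

__all__ = ["load_edf", "load_contact_table"]


def load_edf(path: str | Path):
    """Read an EDF recording; returns ``(data, sample_rate, channel_names)``.

    Thin wrapper over :func:`mne.io.read_raw_edf` (optional dependency).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' extra") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


def load_contact_table(path: str | Path) -> ContactSet:
    """Read a contact-coordinate CSV into a :class:`ContactSet`.

    Expected columns: contact_id, hemisphere_id, x, y, z, zone.
    """
    df = pd.read_csv(path)
    required = {"contact_id", "hemisphere_id", "x", "y", "z", "zone"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contact table missing columns: {sorted(missing)}")
    return ContactSet(df["contact_id"].to_numpy(),
                      df["hemisphere_id"].to_numpy(),
                      df[["x", "y", "z"]].to_numpy(float),
                      df["zone"].to_numpy())
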