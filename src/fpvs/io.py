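"""Readers and writers for the formats the pipeline touches.

BDF/EDF/FIF recordings are read through MNE.  Continuous recordings can
be written as FIF; epoch stacks as HDF5 (:meth:`EpochSet.save`); spectra
and SBL tables as tidy TSV; ground truth and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Recording

__all__ = [
    "read_raw_recording",
    "write_recording_fif",
    "write_spectrum_tsv",
    "write_sbl_tsv",
    "write_json",
]


def read_raw_recording(path: str | Path, event_condition: str = "sequence") -> Recording:
    """Read a BDF/EDF/FIF file into a :class:`Recording` (microvolts).

    Annotations become (sample, description) events; stim channels are
    dropped.
    """
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    readers = {
        ".bdf": mne.io.read_raw_bdf,
        ".edf": mne.io.read_raw_edf,
        ".fif": mne.io.read_raw_fif,
    }
    if suffix not in readers:
        raise ValueError(f"unsupported recording format: {suffix}")
    raw = readers[suffix](path, preload=True, verbose="error")
    raw.pick("eeg")
    data = raw.get_data() * 1e6
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        events.append((int(round(onset * raw.info["sfreq"])), str(desc)))
    if not events:
        events = [(0, event_condition)]
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names), events)


def write_recording_fif(recording: Recording, path: str | Path) -> None:
    """Write a recording (with event annotations) to FIF."""
    import mne

    raw = recording.to_mne()
    onsets = [s / recording.sampling_rate for s, _ in recording.events]
    descs = [lbl for _, lbl in recording.events]
    raw.set_annotations(
        mne.Annotations(onsets, [0.0] * len(onsets), descs)
    )
    raw.save(path, overwrite=True, verbose="error")


def write_spectrum_tsv(
    spec,
    path: str | Path,
    fmax: float | None = 20.0,
    **extra: str,
) -> None:
    """Tidy TSV export of a spectrum, truncated at ``fmax`` by default to
    keep files reviewable (full spectra are huge at 0.0167 Hz resolution)."""
    spec.to_frame(fmax=fmax, **extra).to_csv(path, sep="\t", index=False)


def write_sbl_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
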