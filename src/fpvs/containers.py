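"""In-memory containers for EEG recordings and epoch stacks."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "EpochSet"]


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sampling_rate : float
        Hz.
    channel_labels : list of str
        Unique channel names, one per row of ``data``.
    events : list of (int, str)
        (sample index, condition label) markers at sequence onsets.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        for sample, _ in self.events:
            if not 0 <= sample < self.data.shape[1]:
                raise ValueError(f"event at sample {sample} out of bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            data, self.sampling_rate, list(self.channel_labels), list(self.events)
        )

    def to_mne(self):
        """Convert to an :class:`mne.io.RawArray` (data in volts)."""
        import mne

        info = mne.create_info(
            list(self.channel_labels), self.sampling_rate, ch_types="eeg"
        )
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")


@dataclass
class EpochSet:
    """Stack of fixed-length epochs for one condition.

    ``tmin`` is the epoch start time relative to the event onset (negative
    when a pre-pad is included); sample indexing is 0-based and epochs span
    the half-open interval [tmin, tmin + n_samples/rate).
    """

    data: np.ndarray  # trials x channels x samples, microvolts
    sampling_rate: float
    channel_labels: list[str]
    condition: str = ""
    tmin: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("one label per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray, sampling_rate: float | None = None) -> "EpochSet":
        return EpochSet(
            data,
            sampling_rate if sampling_rate is not None else self.sampling_rate,
            list(self.channel_labels),
            self.condition,
            self.tmin,
        )

    def save(self, path: str | Path) -> None:
        """Serialize to HDF5 with a JSON metadata attribute."""
        import h5py

        meta = {
            "sampling_rate": self.sampling_rate,
            "channel_labels": list(self.channel_labels),
            "condition": self.condition,
            "tmin": self.tmin,
        }
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.data)
            f.attrs["meta"] = json.dumps(meta)

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["epochs"][()]
            meta = json.loads(f.attrs["meta"])
        return cls(
            data,
            meta["sampling_rate"],
            meta["channel_labels"],
            meta["condition"],
            meta["tmin"],
        )
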