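"""64-channel electrode montage with a posterior row.

The acquisition montage is the standard Biosemi 64-channel 10-20 layout
with four sites repositioned to form an additional posterior row (PO9,
PO10, I1, I2), so that the left occipito-temporal region of interest
{P9, PO9, PO7, P7, I1} exists verbatim.  Positions come from the standard
10-05 montage shipped with MNE.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "DEFAULT_ROI",
    "channel_labels",
    "channel_positions",
    "positions_2d",
    "nearest_neighbors",
]

#: Left occipito-temporal region of interest for word-selective responses.
DEFAULT_ROI = ("P9", "PO9", "PO7", "P7", "I1")

_BIOSEMI64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3",
    "FC1", "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1",
    "P3", "P5", "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz",
    "Pz", "CPz", "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz", "C2", "C4",
    "C6", "T8", "TP8", "CP6", "CP4", "CP2", "P2", "P4", "P6", "P8",
    "P10", "PO8", "PO4", "O2",
]

# anterior sites repositioned to the extra posterior row
_SUBSTITUTIONS = {"Fpz": "PO9", "AFz": "PO10", "F1": "I1", "F2": "I2"}


@lru_cache(maxsize=1)
def channel_labels() -> tuple[str, ...]:
    """The 64 channel labels of the acquisition montage, in cap order."""
    return tuple(_SUBSTITUTIONS.get(ch, ch) for ch in _BIOSEMI64)


@lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    return {k: np.asarray(v) for k, v in montage.get_positions()["ch_pos"].items()}


def channel_positions(labels: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
    """3-D scalp positions (meters) for the given labels."""
    labels = labels or channel_labels()
    std = _standard_positions()
    missing = [ch for ch in labels if ch not in std]
    if missing:
        raise KeyError(f"no standard position for channels: {missing}")
    return {ch: std[ch] for ch in labels}


def positions_2d(labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Top-down 2-D layout coordinates (x, y), shape (n_channels, 2)."""
    pos = channel_positions(labels)
    return np.array([p[:2] for p in pos.values()])


def nearest_neighbors(
    target: str,
    candidates: list[str],
    labels: tuple[str, ...] | None = None,
    k: int = 3,
) -> list[str]:
    """The k candidate channels nearest to ``target``.

    Distances are 3-D Euclidean on the scalp surface; a flat top-down
    projection would fold the inferior posterior row (P9, PO9, I1, ...)
    onto the superior parietal ring and corrupt neighborhoods.
    """
    pos = channel_positions(tuple(dict.fromkeys(list(candidates) + [target])))
    t = pos[target]
    dists = sorted(
        (float(np.linalg.norm(pos[c] - t)), c)
        for c in candidates
        if c != target
    )
    if len(dists) < k:
        raise ValueError(
            f"only {len(dists)} candidate neighbors for {target}, need {k}"
        )
    return [c for _, c in dists[:k]]
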