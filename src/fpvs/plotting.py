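"""Static spectrum and topography figures."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .montage import positions_2d
from .spectral import AmplitudeSpectrum

__all__ = ["plot_spectrum", "plot_topography"]


def plot_spectrum(
    spec: AmplitudeSpectrum,
    channel: str | None = None,
    fmax: float = 16.0,
    ax=None,
):
    """Line plot of one channel (or the channel mean) up to ``fmax`` Hz."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mask = spec.frequencies <= fmax
    if channel is None:
        y = np.nanmean(spec.amplitudes[:, mask], axis=0)
        label = "mean"
    else:
        y = spec.amplitudes[spec.channel_labels.index(channel), mask]
        label = channel
    ax.plot(spec.frequencies[mask], y, label=label)
    ax.set_xlabel("frequency (Hz)")
    ylabels = {
        "raw": "amplitude (μV)",
        "baseline_corrected": "baseline-corrected amplitude (μV)",
        "snr": "SNR",
        "zscore": "Z",
    }
    ax.set_ylabel(ylabels.get(spec.kind, spec.kind))
    ax.legend()
    return ax


def plot_topography(
    values: Sequence[float], labels: Sequence[str], ax=None, annotate: bool = False
):
    """Scalp scatter map of per-channel values (top-down view)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = positions_2d(tuple(labels))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=np.asarray(values, float), s=120,
                    cmap="viridis")
    if annotate:
        for (x, y), ch in zip(xy, labels):
            ax.annotate(ch, (x, y), fontsize=6, ha="center", va="center")
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, shrink=0.8)
    return ax
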