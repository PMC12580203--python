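"""Frequency-domain statistics for oddball frequency-tagging.

All statistics operate on normalized amplitude spectra: the magnitude of
the FFT of the time-domain-averaged epoch divided by the number of samples
(one-sided grid, no factor of 2 — internally consistent because every
quantity is a ratio or difference of such values).  A 60-s epoch gives a
frequency resolution of 1/60 ~ 0.0167 Hz, so the 2 Hz oddball response and
its harmonics fall exactly on grid bins.

Local statistics compare each bin against its surrounding "noise" bins
(default 10 per side):

- baseline-corrected amplitude: ``x - mean(noise)``
- SNR: ``x / mean(noise)`` (1 = chance level)
- Z-score: ``(x - mean(noise)) / SD(noise)``; bins with Z > 2.33
  (p < .01, one-tailed) are deemed significant.

Harmonic summaries: the oddball harmonics up to a ceiling (2-14 Hz by
default) are enumerated, harmonics that coincide with the base rate
(10 Hz) are flagged and excluded from summation; the summed
baseline-corrected amplitude (SBL) over the remaining harmonics is the
scalar response magnitude per electrode, and electrodes are ranked by
their largest SBL over conditions and sessions to define the region of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmplitudeSpectrum",
    "NoiseWindow",
    "HarmonicSet",
    "amplitude_spectrum",
    "average_spectra",
    "baseline_correct",
    "snr",
    "zscore",
    "enumerate_harmonics",
    "significant_harmonics",
    "summed_baseline_amplitude",
    "rank_electrodes",
    "select_roi",
    "roi_mean",
    "roi_mean_values",
]

#: One-tailed p < .01 threshold on the noise-referenced Z-score.
Z_THRESHOLD = 2.33


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum on a uniform frequency grid.

    ``amplitudes`` is channels x bins; undefined bins (edges of a local
    statistic, degenerate denominators) are NaN.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    channel_labels: list[str]
    kind: str = "raw"  # raw | baseline_corrected | snr | zscore

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if self.amplitudes.shape[1] != self.frequencies.size:
            raise ValueError("amplitudes and frequency grid disagree")
        if len(self.channel_labels) != self.amplitudes.shape[0]:
            raise ValueError("one label per channel required")
        if self.frequencies.size >= 2:
            df = np.diff(self.frequencies)
            if not np.allclose(df, df[0], rtol=1e-9, atol=1e-12):
                raise ValueError("frequency grid must be uniform")

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[0]

    def bin_index(self, freq: float, tol: float = 1e-6) -> int:
        """Index of the grid bin at ``freq``; error if not bin-aligned."""
        idx = freq / self.resolution
        if abs(idx - round(idx)) > tol:
            raise ValueError(
                f"{freq} Hz is not aligned to the {self.resolution:.6f} Hz grid"
            )
        i = int(round(idx))
        if not 0 <= i < self.frequencies.size:
            raise ValueError(f"{freq} Hz outside the spectrum")
        return i

    def value_at(self, freq: float, channel: str | None = None) -> np.ndarray | float:
        i = self.bin_index(freq)
        if channel is None:
            return self.amplitudes[:, i]
        return float(self.amplitudes[self.channel_labels.index(channel), i])

    def to_frame(self, fmax: float | None = None, **extra: str) -> pd.DataFrame:
        """Tidy long-format export (channel, frequency, value, kind, ...)."""
        mask = slice(None) if fmax is None else self.frequencies <= fmax
        freqs = self.frequencies[mask]
        rows = []
        for c, ch in enumerate(self.channel_labels):
            rows.append(
                pd.DataFrame(
                    {
                        "channel": ch,
                        "frequency": freqs,
                        "value": self.amplitudes[c, mask],
                        "kind": self.kind,
                        **extra,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def amplitude_spectrum(
    avg_epoch: np.ndarray,
    sampling_rate: float,
    channel_labels: Sequence[str] | None = None,
) -> AmplitudeSpectrum:
    """Normalized amplitude spectrum of a (averaged) epoch.

    |FFT| / N on the one-sided grid from 0 to Nyquist at resolution
    1/duration.  The epoch duration must be an exact multiple of 1 s so
    integer frequencies are bin-aligned.  A cosine of peak amplitude A at
    an exact bin yields A/2 at that bin.
    """
    data = np.atleast_2d(np.asarray(avg_epoch, dtype=float))
    n = data.shape[1]
    if n < 2:
        raise ValueError("epoch too short")
    duration = n / sampling_rate
    if abs(duration - round(duration)) > 1e-9:
        raise ValueError(
            f"epoch duration {duration} s is not an integer number of seconds"
        )
    amps = np.abs(np.fft.rfft(data, axis=1)) / n
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    labels = (
        list(channel_labels)
        if channel_labels is not None
        else [f"CH{i:02d}" for i in range(data.shape[0])]
    )
    return AmplitudeSpectrum(freqs, amps, labels, kind="raw")


def average_spectra(spectra: Iterable[AmplitudeSpectrum]) -> AmplitudeSpectrum:
    """Pointwise mean of spectra on identical grids (e.g. a group average
    before computing group-level Z-scores)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("nothing to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.kind != ref.kind or s.amplitudes.shape != ref.amplitudes.shape:
            raise ValueError("spectra must share kind and shape")
        if not np.allclose(s.frequencies, ref.frequencies):
            raise ValueError("spectra must share the frequency grid")
    mean = np.mean([s.amplitudes for s in spectra], axis=0)
    return AmplitudeSpectrum(
        ref.frequencies.copy(), mean, list(ref.channel_labels), kind=ref.kind
    )


@dataclass(frozen=True)
class NoiseWindow:
    """Which surrounding bins count as local noise.

    ``bins_per_side`` on each side of the target (default 10, i.e. 20
    noise bins); ``exclude_adjacent`` immediately neighboring bins and the
    ``exclude_extremes`` smallest/largest noise values may additionally be
    dropped (defaults 0 — the plain 10-per-side window).
    """

    bins_per_side: int = 10
    exclude_adjacent: int = 0
    exclude_extremes: int = 0

    def __post_init__(self) -> None:
        if self.bins_per_side < 1:
            raise ValueError("bins_per_side must be >= 1")
        if not 0 <= self.exclude_adjacent < self.bins_per_side:
            raise ValueError("exclude_adjacent must be < bins_per_side")
        if not 0 <= self.exclude_extremes < self.bins_per_side:
            raise ValueError("exclude_extremes must be < bins_per_side")

    @property
    def reach(self) -> int:
        return self.bins_per_side + self.exclude_adjacent

    def offsets(self) -> list[int]:
        side = range(self.exclude_adjacent + 1, self.reach + 1)
        return [-o for o in reversed(side)] + list(side)


def _neighbor_stats(
    amps: np.ndarray, window: NoiseWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and SD (n-1) of the noise window; NaN where the window
    runs off the grid edge."""
    n_ch, n_bins = amps.shape
    reach = window.reach
    padded = np.full((n_ch, n_bins + 2 * reach), np.nan)
    padded[:, reach : reach + n_bins] = amps
    offs = window.offsets()
    stack = np.stack([padded[:, reach + o : reach + o + n_bins] for o in offs])
    if window.exclude_extremes:
        k = window.exclude_extremes
        valid = np.isfinite(stack).all(axis=0)
        stack_sorted = np.sort(stack, axis=0)[k : len(offs) - k]
        mean = stack_sorted.mean(axis=0)
        sd = stack_sorted.std(axis=0, ddof=1)
        mean[~valid] = np.nan
        sd[~valid] = np.nan
    else:
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
    return mean, sd


def _check_kind(spec: AmplitudeSpectrum, expected: str, op: str) -> None:
    if spec.kind != expected:
        raise ValueError(f"{op} expects a {expected!r} spectrum, got {spec.kind!r}")


def baseline_correct(
    spec: AmplitudeSpectrum, window: NoiseWindow = NoiseWindow()
) -> AmplitudeSpectrum:
    """Subtract the local noise mean from each bin.

    Bins too close to the grid edge for a full window are NaN (flagged
    undefined, never silently computed).
    """
    _check_kind(spec, "raw", "baseline_correct")
    mean, _ = _neighbor_stats(spec.amplitudes, window)
    return AmplitudeSpectrum(
        spec.frequencies.copy(),
        spec.amplitudes - mean,
        list(spec.channel_labels),
        kind="baseline_corrected",
    )


def snr(
    spec: AmplitudeSpectrum, window: NoiseWindow = NoiseWindow()
) -> AmplitudeSpectrum:
    """Divide each bin by the local noise mean (1 = chance level)."""
    _check_kind(spec, "raw", "snr")
    mean, _ = _neighbor_stats(spec.amplitudes, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean > 0, spec.amplitudes / mean, np.nan)
    return AmplitudeSpectrum(
        spec.frequencies.copy(), out, list(spec.channel_labels), kind="snr"
    )


def zscore(
    spec: AmplitudeSpectrum, window: NoiseWindow = NoiseWindow()
) -> AmplitudeSpectrum:
    """Noise-referenced Z-score: (x - mean(noise)) / SD(noise).

    Computed on raw (not baseline-corrected) amplitudes; SD uses the n-1
    denominator.  Degenerate windows (SD = 0) are NaN.
    """
    _check_kind(spec, "raw", "zscore")
    mean, sd = _neighbor_stats(spec.amplitudes, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, (spec.amplitudes - mean) / sd, np.nan)
    return AmplitudeSpectrum(
        spec.frequencies.copy(), out, list(spec.channel_labels), kind="zscore"
    )


@dataclass(frozen=True)
class HarmonicSet:
    """Consecutive harmonics of a fundamental up to a ceiling, with
    base-rate collisions flagged."""

    fundamental: float
    harmonics: tuple[float, ...]
    collisions: frozenset[float]
    ceiling: float

    @property
    def summable(self) -> tuple[float, ...]:
        """Harmonics retained for summation (collisions excluded)."""
        return tuple(h for h in self.harmonics if h not in self.collisions)


def enumerate_harmonics(
    fundamental: float, base_rate: float, ceiling: float
) -> HarmonicSet:
    """All integer multiples of ``fundamental`` up to ``ceiling``; members
    that are also integer multiples of ``base_rate`` are flagged as
    collisions (they mix oddball and base responses and are excluded from
    summation).  Defaults of the paradigm: (2, 10, 14) enumerates seven
    harmonics 2..14 Hz and sums six (10 Hz excluded)."""
    if fundamental <= 0:
        raise ValueError("fundamental must be > 0")
    harmonics = []
    k = 1
    while k * fundamental <= ceiling + 1e-9:
        harmonics.append(round(k * fundamental, 9))
        k += 1
    collisions = frozenset(
        h for h in harmonics if abs(h / base_rate - round(h / base_rate)) < 1e-9
    )
    return HarmonicSet(fundamental, tuple(harmonics), collisions, ceiling)


def significant_harmonics(
    zspec: AmplitudeSpectrum,
    hset: HarmonicSet,
    threshold: float = Z_THRESHOLD,
) -> np.ndarray:
    """Length of the run of consecutive significant harmonics.

    Starting at the fundamental, non-collision harmonics are walked in
    order; collisions are skipped without breaking the run; the run ends at
    the first non-significant (or undefined) harmonic.  Returns one count
    per channel.
    """
    _check_kind(zspec, "zscore", "significant_harmonics")
    idx = [zspec.bin_index(h) for h in hset.harmonics]  # errors if unaligned
    runs = np.zeros(zspec.n_channels, dtype=int)
    for c in range(zspec.n_channels):
        count = 0
        for h, i in zip(hset.harmonics, idx):
            if h in hset.collisions:
                continue
            z = zspec.amplitudes[c, i]
            if np.isfinite(z) and z > threshold:
                count += 1
            else:
                break
        runs[c] = count
    return runs


def summed_baseline_amplitude(
    bl_spec: AmplitudeSpectrum, hset: HarmonicSet
) -> np.ndarray:
    """Summed baseline-corrected amplitude (SBL) per channel, over the
    non-collision harmonics."""
    _check_kind(bl_spec, "baseline_corrected", "summed_baseline_amplitude")
    summable = hset.summable
    if not summable:
        raise ValueError("no summable harmonics")
    idx = [bl_spec.bin_index(h) for h in summable]
    return bl_spec.amplitudes[:, idx].sum(axis=1)


def rank_electrodes(sbl_table: pd.DataFrame) -> list[str]:
    """Order electrodes by their largest SBL over all conditions/sessions.

    ``sbl_table`` must have columns electrode, condition, session, sbl and
    the same electrode set in every condition x session cell.  Ties break
    by label order (deterministic).
    """
    required = {"electrode", "condition", "session", "sbl"}
    if not required.issubset(sbl_table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    cells = sbl_table.groupby(["condition", "session"])["electrode"].apply(set)
    if len(set(map(frozenset, cells))) != 1:
        raise ValueError("electrode set differs across condition/session cells")
    best = sbl_table.groupby("electrode")["sbl"].max()
    order = sorted(best.index, key=lambda ch: (-best[ch], ch))
    return order


def select_roi(ranking: Sequence[str], k: int = 5) -> tuple[str, ...]:
    """Top-k electrodes of a ranking."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds {len(ranking)} electrodes")
    return tuple(ranking[:k])


def roi_mean(spec: AmplitudeSpectrum, roi: Sequence[str]) -> AmplitudeSpectrum:
    """Unweighted mean over ROI channels, as a single-channel spectrum."""
    if not roi:
        raise ValueError("empty ROI")
    missing = [ch for ch in roi if ch not in spec.channel_labels]
    if missing:
        raise ValueError(f"ROI channels not in spectrum: {missing}")
    idx = [spec.channel_labels.index(ch) for ch in roi]
    mean = spec.amplitudes[idx, :].mean(axis=0, keepdims=True)
    return AmplitudeSpectrum(spec.frequencies.copy(), mean, ["ROI"], kind=spec.kind)


def roi_mean_values(
    values: np.ndarray | Sequence[float],
    labels: Sequence[str],
    roi: Sequence[str],
) -> float:
    """Unweighted mean of per-channel scalars (e.g. SBL) over an ROI."""
    if not roi:
        raise ValueError("empty ROI")
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    missing = [ch for ch in roi if ch not in labels]
    if missing:
        raise ValueError(f"ROI channels not in labels: {missing}")
    return float(np.mean([values[labels.index(ch)] for ch in roi]))
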