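"""Synthetic EEG recordings and behavioral trial tables with ground truth.

The EEG generator injects a phase-locked steady-state response — a sum of
cosines at the base rate and the oddball rate plus harmonics, weighted by a
scalp topography — into background noise with a 1/f spectral profile and an
alpha bump.  Noise is synthesized in the frequency domain: each positive-
frequency coefficient is an independent complex Gaussian whose scale
follows ``noise_scale * f**(-exponent/2)`` plus a Gaussian alpha component,
giving Rayleigh-distributed bin amplitudes with uniform phases.  Every
injected amplitude and topography weight is recorded, so parameter-recovery
tests can compare pipeline output against exact ground truth.

The behavioral generator draws lognormal reaction times and Bernoulli
word/pseudoword responses per trial, with session-2 shifts for the
categories affected by learning.  Its defaults are calibrated to the
printed group means of the study it emulates: orthographic neighbors
(ON1L) 702.99 -> 751.46 ms, pseudoword neighbors (PW1L) 880.94 -> 1120.27
ms (OP) and 860.82 -> 1021.78 ms (OPS), and novel-word word-endorsement
7.2% -> 90.8%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import Recording
from .design import OddballDesign
from .montage import DEFAULT_ROI, channel_labels, channel_positions

__all__ = [
    "SignalSpec",
    "NoiseSpec",
    "SimConfig",
    "BehaviorSpec",
    "GroundTruth",
    "simulate_recording",
    "simulate_behavior",
    "roi_concentrated_topography",
    "posterior_topography",
]

#: Gap inserted before each trial's fade-in, seconds.
INTER_TRIAL_GAP = 1.0
#: Width (SD, Hz) of the Gaussian alpha bump in the noise profile.
ALPHA_BANDWIDTH = 1.5


def roi_concentrated_topography(
    labels: Sequence[str] | None = None,
    roi: Sequence[str] = DEFAULT_ROI,
    spread: float = 0.03,
    background: float = 0.02,
) -> np.ndarray:
    """Topography peaking on a region of interest.

    Weight of each channel is the maximum over ROI channels of a Gaussian
    falloff ``exp(-d^2 / (2 spread^2))`` in 3-D scalp distance (meters),
    floored at ``background``.  ROI channels get weight 1.
    """
    labels = tuple(labels) if labels is not None else channel_labels()
    pos = channel_positions(labels)
    xyz = np.array([pos[ch] for ch in labels])
    roi_idx = [labels.index(ch) for ch in roi]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, roi_idx, :], axis=-1)
    w = np.exp(-(d**2) / (2 * spread**2)).max(axis=1)
    return np.maximum(w, background)


def posterior_topography(
    labels: Sequence[str] | None = None, spread: float = 0.06
) -> np.ndarray:
    """Broad medial-occipital topography (for the base-rate response)."""
    labels = tuple(labels) if labels is not None else channel_labels()
    if "Oz" in labels:
        return roi_concentrated_topography(labels, roi=("Oz",), spread=spread)
    return np.ones(len(labels))


@dataclass
class SignalSpec:
    """Ground-truth phase-locked response injected into the recording.

    ``base_harmonic_amplitudes`` / ``oddball_harmonic_amplitudes`` map each
    harmonic index k (frequency k x rate) to a peak cosine amplitude in
    microvolts; a channel's injected amplitude is the product with its
    topography weight.  ``None`` topographies mean uniform weight 1.
    """

    base_harmonic_amplitudes: list[tuple[int, float]] = field(
        default_factory=lambda: [(1, 1.2), (2, 0.5)]
    )
    oddball_harmonic_amplitudes: list[tuple[int, float]] = field(
        default_factory=lambda: [
            (1, 0.55), (2, 0.45), (3, 0.35), (4, 0.25), (6, 0.20), (7, 0.14),
        ]
    )
    base_topography: np.ndarray | None = None
    oddball_topography: np.ndarray | None = None
    phase_locked: bool = True

    def __post_init__(self) -> None:
        for k, a in self.base_harmonic_amplitudes + self.oddball_harmonic_amplitudes:
            if k < 1 or a < 0:
                raise ValueError("harmonic indices >= 1 and amplitudes >= 0")

    @classmethod
    def word_selective(cls, labels: Sequence[str] | None = None) -> "SignalSpec":
        """Post-learning-like response: oddball harmonics over the left
        occipito-temporal ROI (summed baseline-corrected amplitude ~0.97
        microvolts at the ROI) plus a medial base-rate response."""
        return cls(
            base_topography=posterior_topography(labels),
            oddball_topography=roi_concentrated_topography(labels),
        )

    @classmethod
    def no_oddball(cls, labels: Sequence[str] | None = None) -> "SignalSpec":
        """Pre-learning-like response: base response only."""
        return cls(
            oddball_harmonic_amplitudes=[],
            base_topography=posterior_topography(labels),
            oddball_topography=roi_concentrated_topography(labels),
        )


@dataclass
class NoiseSpec:
    """Background-noise model: 1/f profile plus an alpha bump.

    ``noise_scale`` sets the complex-Gaussian scale of a 1-Hz bin for a
    60-s epoch (roughly the expected single-trial amplitude-spectrum floor
    at 1 Hz, microvolts); the profile falls off as f^(-exponent/2) and an
    alpha bump of scale ``alpha_amplitude`` (SD 1.5 Hz) sits at
    ``alpha_peak_frequency``.
    """

    one_over_f_exponent: float = 1.0
    noise_scale: float = 0.05
    alpha_peak_frequency: float = 10.0
    alpha_amplitude: float = 0.10

    def __post_init__(self) -> None:
        if self.one_over_f_exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.noise_scale < 0 or self.alpha_amplitude < 0:
            raise ValueError("noise scales must be >= 0")

    def amplitude_profile(self, freqs: np.ndarray) -> np.ndarray:
        """Per-frequency complex-Gaussian scale (arbitrary until scaled)."""
        prof = np.zeros_like(freqs, dtype=float)
        pos = freqs > 0
        prof[pos] = self.noise_scale * freqs[pos] ** (-self.one_over_f_exponent / 2.0)
        prof += self.alpha_amplitude * np.exp(
            -((freqs - self.alpha_peak_frequency) ** 2) / (2 * ALPHA_BANDWIDTH**2)
        )
        return prof


@dataclass
class SimConfig:
    """Acquisition geometry of the simulated recording."""

    n_channels: int = 64
    sampling_rate: float = 1024.0
    n_trials_per_condition: int = 4
    epoch_duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("need at least one trial")
        n = self.epoch_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_duration x sampling_rate must be integral")

    def labels(self) -> list[str]:
        if self.n_channels == 64:
            return list(channel_labels())
        return [f"CH{i:02d}" for i in range(self.n_channels)]


@dataclass
class GroundTruth:
    """Everything injected into a simulated recording."""

    seed: int
    condition: str
    base_frequencies: dict[float, float]  # Hz -> amplitude (microvolts)
    oddball_frequencies: dict[float, float]
    base_topography: np.ndarray
    oddball_topography: np.ndarray
    phase_locked: bool
    phases: dict[str, np.ndarray]  # per trial, per component

    def expected_bin_amplitude(
        self, freq: float, kind: str = "oddball", referenced: bool = False
    ) -> np.ndarray:
        """Expected |FFT|/N amplitude per channel at an exact-bin frequency.

        A cosine of peak amplitude A at an exact DFT bin contributes A/2 to
        the one-sided |FFT|/N spectrum (half the energy sits at -f).  With
        ``referenced=True`` the topography is re-expressed in the common
        average reference (w - mean(w)), which is what a pipeline that
        includes common-average re-referencing measures.
        """
        table = self.oddball_frequencies if kind == "oddball" else self.base_frequencies
        topo = self.oddball_topography if kind == "oddball" else self.base_topography
        if referenced:
            topo = topo - topo.mean()
        return table[freq] / 2.0 * topo

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "condition": self.condition,
            "base_frequencies": {str(k): v for k, v in self.base_frequencies.items()},
            "oddball_frequencies": {
                str(k): v for k, v in self.oddball_frequencies.items()
            },
            "base_topography": self.base_topography.tolist(),
            "oddball_topography": self.oddball_topography.tolist(),
            "phase_locked": self.phase_locked,
        }


def _synthesize_noise(
    rng: np.random.Generator,
    spec: NoiseSpec,
    n_channels: int,
    n_samples: int,
    sampling_rate: float,
) -> np.ndarray:
    """Frequency-domain noise synthesis (see module docstring)."""
    if spec.noise_scale == 0 and spec.alpha_amplitude == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate)
    prof = spec.amplitude_profile(freqs)
    # Scale convention: a 60-s epoch at this rate has bin amplitudes
    # |FFT|/N with complex-Gaussian scale prof for each component, so the
    # rfft coefficients need scale prof * N.  For other epoch lengths the
    # per-bin variance follows the same spectral density (variance per Hz),
    # keeping the time-domain process consistent across segment lengths.
    ref_n = int(round(60.0 * sampling_rate))
    density = prof * np.sqrt(ref_n / n_samples)
    z = rng.standard_normal((n_channels, freqs.size)) + 1j * rng.standard_normal(
        (n_channels, freqs.size)
    )
    coeffs = density * n_samples * z / np.sqrt(2.0)
    coeffs[:, 0] = coeffs[:, 0].real * np.sqrt(2.0)  # DC must be real
    if n_samples % 2 == 0:
        coeffs[:, -1] = coeffs[:, -1].real * np.sqrt(2.0)
    return np.fft.irfft(coeffs, n=n_samples, axis=1)


def _fade_envelope(
    t: np.ndarray, fade_in: float, stim: float, fade_out: float
) -> np.ndarray:
    """Linear contrast ramp over [0, fade_in], flat over the stimulation,
    linear ramp down over the fade-out; t=0 at fade-in start."""
    env = np.ones_like(t)
    if fade_in > 0:
        env = np.where(t < fade_in, t / fade_in, env)
    if fade_out > 0:
        t_end = fade_in + stim
        env = np.where(
            t >= t_end, np.clip(1.0 - (t - t_end) / fade_out, 0.0, 1.0), env
        )
    return np.clip(env, 0.0, 1.0)


def simulate_recording(
    design: OddballDesign,
    signal: SignalSpec,
    noise: NoiseSpec,
    config: SimConfig,
    condition: str = "condition",
) -> tuple[Recording, GroundTruth]:
    """Simulate a continuous multitrial recording of one condition.

    Each trial is laid out as [1-s gap | fade-in | stimulation | fade-out]
    with an event marker at the stimulation onset.  The phase-locked signal
    component is identical across trials (phase 0 at stimulation onset);
    with ``phase_locked=False`` each component gets a fresh uniform phase
    per trial.  Noise is synthesized independently per trial chunk and per
    channel.  Fully reproducible under ``config.seed``.
    """
    if abs(design.stimulation_duration - config.epoch_duration) > 1e-9:
        raise ValueError(
            "design.stimulation_duration must match config.epoch_duration"
        )
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)
    labels = config.labels()
    n_ch = config.n_channels

    def topo(arr: np.ndarray | None) -> np.ndarray:
        if arr is None:
            return np.ones(n_ch)
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (n_ch,):
            raise ValueError("topography length must equal n_channels")
        return arr

    base_topo = topo(signal.base_topography)
    odd_topo = topo(signal.oddball_topography)

    components = [
        ("base", k, a, design.base_rate * k, base_topo)
        for k, a in signal.base_harmonic_amplitudes
    ] + [
        ("oddball", k, a, design.oddball_rate * k, odd_topo)
        for k, a in signal.oddball_harmonic_amplitudes
    ]

    n_gap = int(round(INTER_TRIAL_GAP * fs))
    n_fade_in = int(round(design.fade_in * fs))
    n_stim = int(round(design.stimulation_duration * fs))
    n_fade_out = int(round(design.fade_out * fs))
    n_trial = n_gap + n_fade_in + n_stim + n_fade_out

    chunks: list[np.ndarray] = []
    events: list[tuple[int, str]] = []
    phases: dict[str, np.ndarray] = {}
    for trial in range(config.n_trials_per_condition):
        x = _synthesize_noise(rng, noise, n_ch, n_trial, fs)
        t = (np.arange(n_fade_in + n_stim + n_fade_out)) / fs  # 0 at fade-in
        env = _fade_envelope(
            t, design.fade_in, design.stimulation_duration, design.fade_out
        )
        t_stim = t - design.fade_in  # phase referenced to stimulation onset
        if signal.phase_locked:
            ph = np.zeros(len(components))
        else:
            ph = rng.uniform(0.0, 2 * np.pi, size=len(components))
        phases[f"trial{trial}"] = ph
        sig = np.zeros((n_ch, t.size))
        for (kind, k, amp, freq, w), phi in zip(components, ph):
            if amp == 0:
                continue
            wave = amp * env * np.cos(2 * np.pi * freq * t_stim + phi)
            sig += w[:, None] * wave[None, :]
        x[:, n_gap:] += sig
        chunks.append(x)
        events.append((trial * n_trial + n_gap + n_fade_in, condition))

    data = np.concatenate(chunks, axis=1)
    recording = Recording(data, fs, labels, events)
    truth = GroundTruth(
        seed=config.seed,
        condition=condition,
        base_frequencies={
            design.base_rate * k: a for k, a in signal.base_harmonic_amplitudes
        },
        oddball_frequencies={
            design.oddball_rate * k: a for k, a in signal.oddball_harmonic_amplitudes
        },
        base_topography=base_topo,
        oddball_topography=odd_topo,
        phase_locked=signal.phase_locked,
        phases=phases,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Behavioral generator
# ---------------------------------------------------------------------------

#: Which categories carry a learning method, and the lexical status that
#: makes a "word" response correct.
CATEGORY_METHODS: Mapping[str, tuple[str, ...]] = {
    "novel": ("OP", "OPS"),
    "ON1L": ("OP", "OPS"),
    "PW1L": ("OP", "OPS"),
    "unlearned": ("none",),
    "filler_word": ("none",),
    "filler_pw": ("none",),
}
CATEGORY_IS_WORD: Mapping[str, bool] = {
    "novel": True,
    "ON1L": True,
    "PW1L": False,
    "unlearned": True,
    "filler_word": True,
    "filler_pw": False,
}


def _default_rt_means() -> dict[tuple[str, str], float]:
    return {
        ("novel", "OP"): 950.0,
        ("novel", "OPS"): 950.0,
        ("ON1L", "OP"): 702.99,
        ("ON1L", "OPS"): 702.99,
        ("PW1L", "OP"): 880.94,
        ("PW1L", "OPS"): 860.82,
        ("unlearned", "none"): 950.0,
        ("filler_word", "none"): 650.0,
        ("filler_pw", "none"): 800.0,
    }


def _default_rt_shifts() -> dict[tuple[str, str], float]:
    # post - pre mean shifts, ms
    return {
        ("ON1L", "OP"): 48.47,
        ("ON1L", "OPS"): 48.47,
        ("PW1L", "OP"): 239.33,
        ("PW1L", "OPS"): 160.96,
        ("novel", "OP"): -120.0,
        ("novel", "OPS"): -120.0,
    }


def _default_p_word() -> dict[str, tuple[float, float]]:
    # probability of a "word" response (pre, post)
    return {
        "novel": (0.072, 0.908),
        "ON1L": (0.95, 0.95),
        "PW1L": (0.10, 0.15),
        "unlearned": (0.10, 0.10),
        "filler_word": (0.95, 0.95),
        "filler_pw": (0.05, 0.05),
    }


@dataclass
class BehaviorSpec:
    """Generator settings for lexical-decision trial tables.

    Reaction times are lognormal: for a target arithmetic mean m (ms) and
    log-scale sigma, mu = ln(m) - sigma^2/2 so that E[RT] = m.  Session-2
    draws for shifted (category, method) cells use mean m + shift.
    Responses are Bernoulli draws of "word" with per-category, per-session
    probability; ``correct`` compares the response to the category's
    lexical status.
    """

    rt_mean_ms: dict[tuple[str, str], float] = field(default_factory=_default_rt_means)
    rt_shift_ms: dict[tuple[str, str], float] = field(default_factory=_default_rt_shifts)
    rt_sigma_log: float = 0.4
    p_word: dict[str, tuple[float, float]] = field(default_factory=_default_p_word)
    n_participants: int = 32
    n_items_per_category: dict[str, int] = field(
        default_factory=lambda: {
            "novel": 32,
            "ON1L": 32,
            "PW1L": 32,
            "unlearned": 32,
            "filler_word": 40,
            "filler_pw": 40,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_sigma_log <= 0:
            raise ValueError("rt_sigma_log must be > 0")
        for m in self.rt_mean_ms.values():
            if m <= 0:
                raise ValueError("RT means must be > 0")
        for pre, post in self.p_word.values():
            if not (0 <= pre <= 1 and 0 <= post <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


def simulate_behavior(spec: BehaviorSpec) -> pd.DataFrame:
    """Draw a long-format lexical-decision trial table.

    Columns: participant, session (pre/post), method (OP/OPS/none),
    category, item, rt_ms, response (word/pseudoword), correct.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for cat, n_items in spec.n_items_per_category.items():
        methods = CATEGORY_METHODS.get(cat, ("none",))
        is_word = CATEGORY_IS_WORD.get(cat, True)
        p_pre, p_post = spec.p_word.get(cat, (1.0, 1.0))
        for item in range(n_items):
            method = methods[item % len(methods)]
            key = (cat, method)
            if key not in spec.rt_mean_ms:
                key = (cat, "none")
            mean_pre = spec.rt_mean_ms[key]
            shift = spec.rt_shift_ms.get((cat, method), 0.0)
            for session, mean, p_word in (
                ("pre", mean_pre, p_pre),
                ("post", mean_pre + shift, p_post),
            ):
                mu = np.log(mean) - spec.rt_sigma_log**2 / 2.0
                rts = rng.lognormal(mu, spec.rt_sigma_log, size=spec.n_participants)
                said_word = rng.random(spec.n_participants) < p_word
                for p in range(spec.n_participants):
                    response = "word" if said_word[p] else "pseudoword"
                    rows.append(
                        {
                            "participant": f"S{p + 1:02d}",
                            "session": session,
                            "method": method,
                            "category": cat,
                            "item": f"{cat}_{item:02d}",
                            "rt_ms": rts[p],
                            "response": response,
                            "correct": said_word[p] == is_word,
                        }
                    )
    return pd.DataFrame(rows)
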