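"""Oddball stimulation-sequence design.

The stream presents items at ``base_rate`` Hz; every ``oddball_period``-th
item belongs to the deviant (oddball) category, so the oddball frequency is
``base_rate / oddball_period``.  With the defaults (10 Hz, period 5, 60 s)
a sequence holds 600 items — 480 base and 120 oddball — in the fixed
pattern BBBBO repeated, flanked by fade-in/out that is excluded from
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PresentationMode",
    "OddballDesign",
    "SequenceItem",
    "StimulusSequence",
    "SessionPlan",
    "build_sequence",
    "oddball_frequency",
    "session_plan",
    "design_from_yaml",
    "design_to_yaml",
]

#: Minimum separation between two task (color-change) events, seconds.
TASK_EVENT_MIN_SEPARATION = 1.0


class PresentationMode(str, Enum):
    """How each item reaches full contrast on screen."""

    square_wave = "square_wave"
    sinusoidal_contrast = "sinusoidal_contrast"


@dataclass(frozen=True)
class OddballDesign:
    """Parameters of a periodic oddball stimulation sequence.

    Parameters
    ----------
    base_rate : float
        Item presentation frequency, Hz.
    oddball_period : int
        Every Nth item is the deviant; must be >= 2.
    stimulation_duration : float
        Length of the analyzed stimulation window, seconds.
    fade_in, fade_out : float
        Contrast ramp durations flanking the stimulation, seconds.  Items
        presented during the fades are flagged and excluded from analysis.
    presentation_mode : PresentationMode
        Square-wave (abrupt full contrast) or sinusoidal contrast
        modulation.
    task_events : int
        Number of orthogonal-task (color change) events per sequence.
    task_event_duration : float
        Duration of each task event, seconds.
    """

    base_rate: float = 10.0
    oddball_period: int = 5
    stimulation_duration: float = 60.0
    fade_in: float = 2.0
    fade_out: float = 2.0
    presentation_mode: PresentationMode = PresentationMode.square_wave
    task_events: int = 15
    task_event_duration: float = 0.2

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if int(self.oddball_period) != self.oddball_period or self.oddball_period < 2:
            raise ValueError("oddball_period must be an integer >= 2")
        if self.stimulation_duration <= 0:
            raise ValueError("stimulation_duration must be > 0")
        if self.fade_in < 0 or self.fade_out < 0:
            raise ValueError("fade durations must be >= 0")
        if self.task_events < 0 or self.task_event_duration < 0:
            raise ValueError("task event parameters must be >= 0")

    @property
    def oddball_rate(self) -> float:
        """Oddball frequency in Hz (base_rate / oddball_period)."""
        return self.base_rate / self.oddball_period

    @property
    def n_items(self) -> int:
        """Number of items in the stimulation window (must be integral)."""
        n = self.stimulation_duration * self.base_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"stimulation_duration x base_rate = {n} is not an integer "
                "item count"
            )
        return int(round(n))


def oddball_frequency(design: OddballDesign) -> float:
    """Frequency at which the deviant category appears, Hz."""
    return design.oddball_rate


@dataclass(frozen=True)
class SequenceItem:
    onset: float  # seconds, relative to stimulation onset (fade-in < 0)
    category: str  # "base" | "oddball"
    token_id: str
    in_fade: bool = False


@dataclass
class StimulusSequence:
    """A realized stimulation sequence: items plus task-event onsets."""

    design: OddballDesign
    items: list[SequenceItem]
    task_event_onsets: np.ndarray
    seed: int

    @property
    def analyzed_items(self) -> list[SequenceItem]:
        return [it for it in self.items if not it.in_fade]

    def n_by_category(self) -> dict[str, int]:
        counts: dict[str, int] = {"base": 0, "oddball": 0}
        for it in self.analyzed_items:
            counts[it.category] += 1
        return counts

    def category_indicator(self) -> np.ndarray:
        """0/1 vector over analyzed items; 1 marks oddball positions."""
        return np.array(
            [1 if it.category == "oddball" else 0 for it in self.analyzed_items]
        )

    def to_events(self) -> "pd.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        rows = [
            {
                "onset": it.onset,
                "duration": 1.0 / self.design.base_rate,
                "trial_type": it.category,
                "token_id": it.token_id,
                "in_fade": it.in_fade,
            }
            for it in self.items
        ]
        return pd.DataFrame(rows)

    def write_events(self, path: str | Path) -> None:
        """Write a tab-separated BIDS-events-like sidecar."""
        self.to_events().to_csv(path, sep="\t", index=False)


def _draw_no_repeat(
    rng: np.random.Generator, pool: Sequence[str], previous: str | None
) -> str:
    # rejection resampling against the immediately preceding token
    if len(pool) == 1:
        token = pool[0]
        if token == previous:
            raise ValueError("pool too small to avoid immediate repetition")
        return token
    while True:
        token = pool[rng.integers(len(pool))]
        if token != previous:
            return token


def build_sequence(
    design: OddballDesign,
    base_pool: Sequence[str],
    oddball_pool: Sequence[str],
    seed: int,
) -> StimulusSequence:
    """Build a pseudo-random oddball sequence.

    Items are spaced uniformly at ``1/base_rate``; 1-based positions
    ``k * oddball_period`` carry the oddball category (pattern BBBBO for
    period 5).  Tokens are drawn uniformly from the category pool with
    rejection of the immediately preceding token, so no item repeats
    back-to-back.  Fade-in/out items are generated and flagged but excluded
    from the analysis window.  Task events are placed uniformly at random
    with a minimum 1-s separation.  Fully reproducible under ``seed``.
    """
    if not base_pool or not oddball_pool:
        raise ValueError("stimulus pools must be non-empty")
    if len(base_pool) < 2:
        raise ValueError(
            "base pool needs >= 2 tokens to avoid immediate repetition"
        )
    n_items = design.n_items  # raises on non-integral count
    rng = np.random.default_rng(seed)
    dt = 1.0 / design.base_rate

    def make_items(position0: int, onset0: float, count: int, fade: bool,
                   prev: str | None) -> tuple[list[SequenceItem], str | None]:
        out = []
        for i in range(count):
            pos = position0 + i  # 1-based within the continuous stream
            cat = "oddball" if pos % design.oddball_period == 0 else "base"
            pool = oddball_pool if cat == "oddball" else base_pool
            token = _draw_no_repeat(rng, pool, prev)
            out.append(
                SequenceItem(onset0 + i * dt, cat, token, in_fade=fade)
            )
            prev = token
        return out, prev

    n_fade_in = int(math.floor(design.fade_in * design.base_rate + 1e-9))
    n_fade_out = int(math.floor(design.fade_out * design.base_rate + 1e-9))

    items: list[SequenceItem] = []
    prev: str | None = None
    # fade-in stream continues the periodic pattern so the analyzed window
    # starts exactly at pattern position 1
    fade_in_items, prev = make_items(
        1 - n_fade_in, -n_fade_in * dt, n_fade_in, True, prev
    )
    stim_items, prev = make_items(1, 0.0, n_items, False, prev)
    fade_out_items, _ = make_items(
        n_items + 1, n_items * dt, n_fade_out, True, prev
    )
    items = fade_in_items + stim_items + fade_out_items

    task_onsets = _place_task_events(
        rng,
        n_events=design.task_events,
        duration=design.stimulation_duration,
        event_duration=design.task_event_duration,
    )
    return StimulusSequence(design, items, task_onsets, seed)


def _place_task_events(
    rng: np.random.Generator,
    n_events: int,
    duration: float,
    event_duration: float,
    min_separation: float = TASK_EVENT_MIN_SEPARATION,
) -> np.ndarray:
    if n_events == 0:
        return np.empty(0)
    upper = duration - event_duration
    if upper <= 0 or (n_events - 1) * min_separation > upper:
        raise ValueError("cannot place task events within the sequence")
    for _ in range(10_000):
        onsets = np.sort(rng.uniform(0.0, upper, size=n_events))
        if n_events == 1 or np.min(np.diff(onsets)) >= min_separation:
            return onsets
    raise RuntimeError("task-event placement did not converge")


@dataclass(frozen=True)
class SessionPlan:
    n_sequences: int
    stimulation_minutes: float


def session_plan(
    n_conditions: int, repeats: int, design: OddballDesign
) -> SessionPlan:
    """Total sequence count and stimulation time for a session.

    With the study defaults (4 conditions x 4 repeats x 60 s) this yields
    16 sequences and 16 minutes of stimulation.
    """
    if n_conditions < 1 or repeats < 1:
        raise ValueError("n_conditions and repeats must be >= 1")
    n_seq = n_conditions * repeats
    minutes = n_seq * design.stimulation_duration / 60.0
    return SessionPlan(n_seq, minutes)


def design_to_yaml(design: OddballDesign, path: str | Path) -> None:
    d = asdict(design)
    d["presentation_mode"] = design.presentation_mode.value
    Path(path).write_text(yaml.safe_dump(d))


def design_from_yaml(path: str | Path) -> OddballDesign:
    d = yaml.safe_load(Path(path).read_text())
    if "presentation_mode" in d:
        d["presentation_mode"] = PresentationMode(d["presentation_mode"])
    return OddballDesign(**d)
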