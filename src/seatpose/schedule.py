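"""Stroop-test timeline and the derived analysis intervals.

The stress-induction protocol shows a fixed sequence of word slides in
three phases of increasing cognitive load:

* ``BLACK`` — color names printed in black (familiarization, pure reading),
* ``CONGRUENT`` — color names printed in their own color,
* ``INCONGRUENT`` — color names printed in a conflicting color, where the
  Stroop interference effect makes naming the ink color stressful.

Three analysis intervals are carved out of the timeline:

* ``TI1`` — all BLACK and CONGRUENT slides (low engagement),
* ``TI2`` — INCONGRUENT slides with few words, 3–6 (medium engagement),
* ``TI3`` — INCONGRUENT slides with many words, 9–12 (high engagement).

Instruction screens (one before the test, one before the incongruent
phase) have configurable durations defaulting to 0 s; they shift window
offsets but never window durations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Phase",
    "Slide",
    "StroopSchedule",
    "TimeWindow",
    "IntervalWindows",
    "build_schedule",
    "default_schedule",
    "load_schedule_config",
    "DEFAULT_SCHEDULE_ROWS",
]

# Word count separating the medium-load from the high-load incongruent
# slides: 3-6 words fall in TI2, 9-12 words in TI3.
_TI2_MAX_WORDS = 6


class Phase(enum.Enum):
    """Slide phase in presentation order."""

    BLACK = "black"
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"

    @classmethod
    def coerce(cls, value: "Phase | str") -> "Phase":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError as exc:
            raise ValueError(f"unknown phase {value!r}") from exc


_PHASE_ORDER = {Phase.BLACK: 0, Phase.CONGRUENT: 1, Phase.INCONGRUENT: 2}


@dataclass(frozen=True)
class Slide:
    """One word slide: its phase, word count and on-screen duration [s]."""

    phase: Phase
    word_count: int
    duration: float

    def __post_init__(self) -> None:
        if self.word_count < 1:
            raise ValueError(f"word_count must be >= 1, got {self.word_count}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class TimeWindow:
    """Half-open interval [start, end) in seconds from test start."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"empty window [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class IntervalWindows:
    """The three analysis windows TI1/TI2/TI3 of a schedule."""

    ti1: TimeWindow
    ti2: TimeWindow
    ti3: TimeWindow

    def __iter__(self):
        return iter((self.ti1, self.ti2, self.ti3))

    def as_dict(self) -> dict[str, TimeWindow]:
        return {"TI1": self.ti1, "TI2": self.ti2, "TI3": self.ti3}


@dataclass(frozen=True)
class StroopSchedule:
    """Ordered word slides plus instruction-screen durations.

    ``lead_in`` is the initial instruction screen shown before the first
    slide; ``mid_instruction`` is the second instruction screen shown
    between the congruent and incongruent phases.
    """

    slides: tuple[Slide, ...]
    lead_in: float = 0.0
    mid_instruction: float = 0.0

    def __post_init__(self) -> None:
        if self.lead_in < 0 or self.mid_instruction < 0:
            raise ValueError("instruction durations must be >= 0")
        order = [_PHASE_ORDER[s.phase] for s in self.slides]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError(
                "slides must appear in phase order BLACK -> CONGRUENT -> INCONGRUENT"
            )

    def total_duration(self) -> float:
        """Total test length: all slide durations plus instruction screens."""
        return self.lead_in + self.mid_instruction + sum(
            s.duration for s in self.slides
        )

    def slide_starts(self) -> list[float]:
        """Start time of each slide, accounting for instruction screens."""
        t = self.lead_in
        starts = []
        for slide in self.slides:
            if slide.phase is Phase.INCONGRUENT:
                break
            starts.append(t)
            t += slide.duration
        t += self.mid_instruction
        for slide in self.slides[len(starts):]:
            starts.append(t)
            t += slide.duration
        return starts

    def interval_windows(self) -> IntervalWindows:
        """Derive the TI1/TI2/TI3 half-open analysis windows.

        TI1 spans the BLACK and CONGRUENT slides, TI2 the incongruent
        slides with at most 6 words, TI3 the remaining incongruent slides.
        Raises ``ValueError`` if any phase is absent.
        """
        phases = {s.phase for s in self.slides}
        missing = set(_PHASE_ORDER) - phases
        if missing:
            names = ", ".join(sorted(p.name for p in missing))
            raise ValueError(f"schedule is missing phase(s): {names}")

        starts = self.slide_starts()
        spans: dict[str, list[float]] = {"TI1": [], "TI2": [], "TI3": []}
        for slide, start in zip(self.slides, starts):
            if slide.phase is not Phase.INCONGRUENT:
                key = "TI1"
            elif slide.word_count <= _TI2_MAX_WORDS:
                key = "TI2"
            else:
                key = "TI3"
            spans[key].extend((start, start + slide.duration))
        if not spans["TI2"] or not spans["TI3"]:
            raise ValueError(
                "incongruent phase must contain both low (<=6) and high (>=9) "
                "word-count slides"
            )
        return IntervalWindows(
            ti1=TimeWindow(min(spans["TI1"]), max(spans["TI1"])),
            ti2=TimeWindow(min(spans["TI2"]), max(spans["TI2"])),
            ti3=TimeWindow(min(spans["TI3"]), max(spans["TI3"])),
        )


def build_schedule(
    config: Iterable[dict | Sequence],
    lead_in: float = 0.0,
    mid_instruction: float = 0.0,
) -> StroopSchedule:
    """Expand a schedule table into a :class:`StroopSchedule`.

    ``config`` rows are mappings ``{phase, words, n_slides, seconds}`` (or
    4-sequences in that order); each row expands to ``n_slides`` identical
    slides, in row order.
    """
    rows = list(config)
    if not rows:
        raise ValueError("schedule config is empty")
    slides: list[Slide] = []
    for row in rows:
        if isinstance(row, dict):
            phase, words = row["phase"], int(row["words"])
            n, seconds = int(row["n_slides"]), float(row["seconds"])
        else:
            phase, words, n, seconds = row
            words, n, seconds = int(words), int(n), float(seconds)
        if n < 1:
            raise ValueError(f"n_slides must be >= 1, got {n}")
        slides.extend(Slide(Phase.coerce(phase), words, seconds) for _ in range(n))
    return StroopSchedule(tuple(slides), lead_in=lead_in, mid_instruction=mid_instruction)


# Published slide schedule: (phase, words per slide, number of slides,
# seconds per slide). 24 word slides, 85 s of display time in total.
DEFAULT_SCHEDULE_ROWS: tuple[tuple[str, int, int, float], ...] = (
    ("black", 3, 2, 2.0),
    ("black", 4, 2, 2.5),
    ("black", 5, 1, 3.0),
    ("black", 6, 1, 3.5),
    ("congruent", 3, 2, 2.0),
    ("congruent", 4, 2, 2.5),
    ("congruent", 5, 1, 3.0),
    ("congruent", 6, 1, 3.5),
    ("incongruent", 3, 2, 2.5),
    ("incongruent", 4, 2, 3.0),
    ("incongruent", 5, 2, 3.5),
    ("incongruent", 6, 2, 4.0),
    ("incongruent", 9, 2, 6.0),
    ("incongruent", 12, 2, 8.0),
)


def load_schedule_config(path=None) -> dict:
    """Load a schedule config mapping from YAML.

    With no ``path``, loads the packaged default schedule.
    Expected keys: ``slides`` (list of rows), optional ``lead_in`` and
    ``mid_instruction``.
    """
    if path is None:
        text = resources.files("seatpose.data").joinpath("stroop_schedule.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "slides" not in cfg:
        raise ValueError("schedule config must be a mapping with a 'slides' key")
    return cfg


def default_schedule(lead_in: float = 0.0, mid_instruction: float = 0.0) -> StroopSchedule:
    """The standard test schedule (24 word slides, 85 s of slides)."""
    return build_schedule(
        DEFAULT_SCHEDULE_ROWS, lead_in=lead_in, mid_instruction=mid_instruction
    )


def schedule_from_config(cfg: dict) -> StroopSchedule:
    """Build a schedule from a config mapping as loaded by YAML."""
    return build_schedule(
        cfg["slides"],
        lead_in=float(cfg.get("lead_in", 0.0)),
        mid_instruction=float(cfg.get("mid_instruction", 0.0)),
    )
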