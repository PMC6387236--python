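"""Posture taxonomy: activation patterns and the posture lookup table.

The chair carries eight analog tactile pressure sensors (ATS): sensors
1-4 on the seat, sensors 5-8 on the backrest. A posture is identified by
which sensors are pressed — an ordered 8-bit activation pattern. Eight
postures P1..P8 are recognized; any other pattern is UNRECOGNIZED.

The published pattern table assigns the identical pattern
``(1,1,0,0,0,0,1,1)`` to both P7 ("front of the seat, not leaning on the
backrest") and P8 ("front of the seat plus the upper backrest"), which
contradicts P7's verbal description and makes the mapping non-injective.
The default lookup corrects P7 to ``(1,1,0,0,0,0,0,0)`` (seat front only,
no backrest contact), consistent with its description; the as-printed
table can still be constructed but refuses to build a lookup.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "PostureLabel",
    "ActivationPattern",
    "PostureLookup",
    "POSTURE_PATTERNS_PRINTED",
    "N_CHANNELS",
]

N_CHANNELS = 8


class PostureLabel(enum.Enum):
    """The eight recognized sitting postures plus the reject class."""

    P1 = "P1"  # fully seated, leaning on the backrest; all sensors pressed
    P2 = "P2"  # right leg crossed, backrest uniformly pressed
    P3 = "P3"  # left leg crossed, backrest uniformly pressed
    P4 = "P4"  # right leg crossed, not leaning on the backrest
    P5 = "P5"  # left leg crossed, not leaning on the backrest
    P6 = "P6"  # seat uniformly pressed, leaning forward off the backrest
    P7 = "P7"  # front of the seat only, off the backrest
    P8 = "P8"  # front of the seat plus upper backrest
    UNRECOGNIZED = "UNRECOGNIZED"

    @property
    def is_recognized(self) -> bool:
        return self is not PostureLabel.UNRECOGNIZED

    @classmethod
    def coerce(cls, value: "PostureLabel | str") -> "PostureLabel":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).strip().upper()]
        except KeyError as exc:
            raise ValueError(f"unknown posture token {value!r}") from exc


RECOGNIZED = tuple(p for p in PostureLabel if p.is_recognized)

ActivationPattern = tuple  # ordered 8-tuple of 0/1 (seat 1-4, backrest 5-8)


def as_pattern(bits: Iterable[int | bool]) -> tuple[int, ...]:
    """Normalize to an 8-tuple of ints in {0, 1}."""
    pat = tuple(int(bool(b)) for b in bits)
    if len(pat) != N_CHANNELS:
        raise ValueError(f"activation pattern must have {N_CHANNELS} bits, got {len(pat)}")
    return pat


# Pattern table exactly as published (seat sensors 1-4, backrest 5-8).
# Note the P7/P8 duplicate and that P4/P5 carry the seat halves one would
# expect for the opposite crossed leg; both are reproduced verbatim here.
POSTURE_PATTERNS_PRINTED: dict[PostureLabel, tuple[int, ...]] = {
    PostureLabel.P1: (1, 1, 1, 1, 1, 1, 1, 1),
    PostureLabel.P2: (0, 1, 0, 1, 1, 1, 1, 1),
    PostureLabel.P3: (1, 0, 1, 0, 1, 1, 1, 1),
    PostureLabel.P4: (1, 0, 1, 0, 0, 0, 0, 0),
    PostureLabel.P5: (0, 1, 0, 1, 0, 0, 0, 0),
    PostureLabel.P6: (1, 1, 1, 1, 0, 0, 0, 0),
    PostureLabel.P7: (1, 1, 0, 0, 0, 0, 1, 1),
    PostureLabel.P8: (1, 1, 0, 0, 0, 0, 1, 1),
}

_P7_CORRECTED = (1, 1, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class PostureLookup:
    """Injective mapping from activation pattern to posture label.

    Parameters
    ----------
    corrected_p7
        Replace P7's published pattern (identical to P8's) with the
        description-consistent seat-front-only pattern. Required for an
        injective lookup; building with ``corrected_p7=False`` raises.
    swap_p4_p5
        Swap the seat patterns of P4 and P5 to match their crossed-leg
        descriptions instead of the published table.
    """

    corrected_p7: bool = True
    swap_p4_p5: bool = False

    def patterns(self) -> Mapping[PostureLabel, tuple[int, ...]]:
        pats = dict(POSTURE_PATTERNS_PRINTED)
        if self.corrected_p7:
            pats[PostureLabel.P7] = _P7_CORRECTED
        if self.swap_p4_p5:
            pats[PostureLabel.P4], pats[PostureLabel.P5] = (
                pats[PostureLabel.P5],
                pats[PostureLabel.P4],
            )
        return pats

    def _table(self) -> dict[tuple[int, ...], PostureLabel]:
        table: dict[tuple[int, ...], PostureLabel] = {}
        for label, pat in self.patterns().items():
            if pat in table:
                raise ValueError(
                    f"pattern {pat} maps to both {table[pat].value} and "
                    f"{label.value}; the lookup must be injective "
                    "(use corrected_p7=True)"
                )
            table[pat] = label
        return table

    def __post_init__(self) -> None:
        self._table()  # reject non-injective configurations at build time

    def pattern_of(self, label: PostureLabel) -> tuple[int, ...]:
        """The activation pattern a given posture produces."""
        if not label.is_recognized:
            raise ValueError("UNRECOGNIZED has no activation pattern")
        return self.patterns()[label]

    def classify(self, pattern: Iterable[int | bool]) -> PostureLabel:
        """Exact pattern lookup; unmatched patterns are UNRECOGNIZED."""
        return self._table().get(as_pattern(pattern), PostureLabel.UNRECOGNIZED)


def classify_pattern(pattern: Iterable[int | bool], lookup: PostureLookup | None = None) -> PostureLabel:
    """Map an 8-bit activation pattern to its posture label."""
    return (lookup or PostureLookup()).classify(pattern)
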