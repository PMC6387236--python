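"""Interval posture classification with sensor quality control.

One posture is reported per analysis interval: the modal per-sample
activation pattern within the interval window is looked up in the posture
table. Participants whose recording shows a sensor failure, or whose
modal pattern in any interval is not one of the eight recognized
combinations, are excluded listwise from downstream statistics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationProfile, activation_series, calibrate, moving_average
from .postures import N_CHANNELS, PostureLabel, PostureLookup, as_pattern
from .schedule import StroopSchedule, TimeWindow
from .trace import CHANNEL_COLUMNS, SensorTrace

__all__ = [
    "ParticipantStatus",
    "ParticipantResult",
    "interval_pattern",
    "qc_trace",
    "classify_participant",
    "classify_cohort",
    "results_to_frame",
    "results_from_frame",
]


class ParticipantStatus(enum.Enum):
    OK = "OK"
    SENSOR_FAILURE = "SENSOR_FAILURE"
    UNRECOGNIZED_POSTURE = "UNRECOGNIZED_POSTURE"


@dataclass(frozen=True)
class ParticipantResult:
    """Classified postures per interval and the participant's QC status.

    Interval postures are ``None`` when the recording failed quality
    control; status is OK iff all three postures are recognized.
    """

    participant: int
    ti1: PostureLabel | None
    ti2: PostureLabel | None
    ti3: PostureLabel | None
    status: ParticipantStatus

    def __post_init__(self) -> None:
        postures = (self.ti1, self.ti2, self.ti3)
        recognized = all(p is not None and p.is_recognized for p in postures)
        if (self.status is ParticipantStatus.OK) != recognized:
            raise ValueError(
                "status OK requires (and is implied by) three recognized postures"
            )

    @property
    def triple(self) -> tuple[PostureLabel, PostureLabel, PostureLabel]:
        if self.status is not ParticipantStatus.OK:
            raise ValueError(f"participant {self.participant} is {self.status.value}")
        return (self.ti1, self.ti2, self.ti3)


def interval_pattern(activations: pd.DataFrame, window: TimeWindow) -> tuple[int, ...]:
    """Modal per-sample activation pattern within a time window.

    Ties are broken by the pattern occurring earliest inside the window,
    making the reduction deterministic.
    """
    mask = (activations["t"].to_numpy() >= window.start) & (
        activations["t"].to_numpy() < window.end
    )
    if not mask.any():
        raise ValueError(f"window [{window.start}, {window.end}) overlaps no samples")
    bits = activations.loc[mask, list(CHANNEL_COLUMNS)].to_numpy().astype(bool)
    # Pack each 8-bit row into one byte for fast exact counting.
    codes = bits @ (1 << np.arange(N_CHANNELS, dtype=np.uint16))
    values, first_idx, counts = np.unique(codes, return_index=True, return_counts=True)
    best = np.lexsort((first_idx, -counts))[0]
    code = int(values[best])
    return as_pattern((code >> i) & 1 for i in range(N_CHANNELS))


def qc_trace(trace: SensorTrace, profile: CalibrationProfile | None = None) -> ParticipantStatus:
    """Flag recordings with failed sensors.

    A channel fails if it has missing samples in the test segment, sits
    outside the supply range anywhere, or shows zero variance across the
    whole recording including the calibration segments (a working channel
    must move between its no-load and loaded levels).
    """
    volts = trace.voltages()
    test = trace.segment_mask("test") if "test" in trace.segments else slice(None)
    if np.isnan(volts[test]).any():
        return ParticipantStatus.SENSOR_FAILURE
    if trace.supply_max is not None:
        finite = volts[~np.isnan(volts)]
        if finite.size and (finite.min() < 0 or finite.max() > trace.supply_max):
            return ParticipantStatus.SENSOR_FAILURE
    if np.any(np.nanstd(volts, axis=0) == 0):
        return ParticipantStatus.SENSOR_FAILURE
    return ParticipantStatus.OK


def classify_participant(
    trace: SensorTrace,
    schedule: StroopSchedule,
    lookup: PostureLookup | None = None,
    cutoff: float = 1.0,
    participant: int | None = None,
) -> ParticipantResult:
    """Run the full per-participant pipeline on one recording.

    calibrate -> low-pass filter -> threshold activation -> modal pattern
    per interval -> posture lookup. Quality control runs first; a failed
    recording reports no postures.
    """
    lookup = lookup or PostureLookup()
    pid = participant if participant is not None else int(trace.meta.get("participant", 0))

    if qc_trace(trace) is ParticipantStatus.SENSOR_FAILURE:
        return ParticipantResult(
            participant=pid, ti1=None, ti2=None, ti3=None,
            status=ParticipantStatus.SENSOR_FAILURE,
        )

    profile = calibrate(trace)
    filtered = moving_average(trace, cutoff=cutoff)
    activations = activation_series(filtered, profile)

    test_start = trace.segments["test"][0]
    windows = schedule.interval_windows()
    postures = []
    for window in windows:
        shifted = TimeWindow(window.start + test_start, window.end + test_start)
        pattern = interval_pattern(activations, shifted)
        postures.append(lookup.classify(pattern))

    status = (
        ParticipantStatus.OK
        if all(p.is_recognized for p in postures)
        else ParticipantStatus.UNRECOGNIZED_POSTURE
    )
    return ParticipantResult(
        participant=pid, ti1=postures[0], ti2=postures[1], ti3=postures[2],
        status=status,
    )


def classify_cohort(
    traces: Sequence[SensorTrace],
    schedule: StroopSchedule,
    lookup: PostureLookup | None = None,
    cutoff: float = 1.0,
) -> list[ParticipantResult]:
    """Classify every recording; exclusions surface through ``status``."""
    return [
        classify_participant(trace, schedule, lookup=lookup, cutoff=cutoff)
        for trace in traces
    ]


def results_to_frame(results: Sequence[ParticipantResult]) -> pd.DataFrame:
    """Results as a DataFrame ``participant, ti1, ti2, ti3, status``."""

    def token(p: PostureLabel | None) -> str:
        return "" if p is None else p.value

    return pd.DataFrame(
        {
            "participant": [r.participant for r in results],
            "ti1": [token(r.ti1) for r in results],
            "ti2": [token(r.ti2) for r in results],
            "ti3": [token(r.ti3) for r in results],
            "status": [r.status.value for r in results],
        }
    )


def results_from_frame(frame: pd.DataFrame) -> list[ParticipantResult]:
    """Parse a results (or cohort fixture) table back into results.

    A ``status`` column is optional; rows without one are taken as OK.
    Raises ``ValueError`` naming the row on a malformed posture token.
    """
    required = {"participant", "ti1", "ti2", "ti3"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")
    out = []
    for idx, row in frame.iterrows():
        status = ParticipantStatus(row["status"]) if "status" in frame.columns else ParticipantStatus.OK
        postures: list[PostureLabel | None] = []
        for col in ("ti1", "ti2", "ti3"):
            value = row[col]
            if status is ParticipantStatus.SENSOR_FAILURE and (
                value is None or (isinstance(value, float) and np.isnan(value)) or value == ""
            ):
                postures.append(None)
                continue
            try:
                postures.append(PostureLabel.coerce(value))
            except ValueError as exc:
                raise ValueError(f"row {idx}: {exc}") from exc
        out.append(
            ParticipantResult(
                participant=int(row["participant"]),
                ti1=postures[0], ti2=postures[1], ti3=postures[2],
                status=status,
            )
        )
    return out
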