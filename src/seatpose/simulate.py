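"""Synthetic chair-signal generator and exact-margin cohort fixtures.

The textile pressure sensors have an inverted response: each channel
outputs a high no-load voltage ``v_zero`` and drops toward ``v_maxload``
when pressed. The analysis uses them purely as switches, so the generator
models each channel as two-level (loaded / unloaded) plus additive
Gaussian noise, optional linear drift, and clipping to the supply rail.

Every simulated recording is prepended with the two calibration
acquisitions the protocol prescribes: a no-load segment (chair empty) and
a fully-seated segment (posture P1, every sensor pressed).

:func:`generate_fixture_cohort` builds a deterministic cohort of posture
triples whose pairwise transition counts reproduce two given 8x8
contingency tables exactly — the bundled reference tables by default —
so the whole pipeline can be validated cell-for-cell against the
published cohort statistics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .postures import N_CHANNELS, PostureLabel, PostureLookup, RECOGNIZED
from .schedule import StroopSchedule
from .trace import CHANNEL_COLUMNS, SensorTrace

__all__ = [
    "SensorModel",
    "PostureScript",
    "CohortFixture",
    "FailureMode",
    "simulate_trace",
    "inject_failure",
    "generate_fixture_cohort",
    "cohort_to_traces",
    "script_from_triple",
]


@dataclass(frozen=True)
class SensorModel:
    """Two-level electrical model of the eight pressure channels.

    Per-channel no-load (``v_zero``) and fully-loaded (``v_maxload``)
    output voltages, Gaussian noise, optional linear drift, and the
    supply rail that clips the output. Inverted response is enforced:
    ``0 <= v_maxload < v_zero <= supply_max`` on every channel.
    """

    v_zero: np.ndarray
    v_maxload: np.ndarray
    noise_sd: float = 0.02
    drift_rate: float = 0.0
    supply_max: float = 3.3

    def __post_init__(self) -> None:
        vz = np.asarray(self.v_zero, dtype=float)
        vm = np.asarray(self.v_maxload, dtype=float)
        if vz.shape != (N_CHANNELS,) or vm.shape != (N_CHANNELS,):
            raise ValueError(f"v_zero and v_maxload must have {N_CHANNELS} entries")
        object.__setattr__(self, "v_zero", vz)
        object.__setattr__(self, "v_maxload", vm)
        if np.any(vm < 0) or np.any(vm >= vz) or np.any(vz > self.supply_max):
            raise ValueError(
                "inverted response requires 0 <= v_maxload < v_zero <= supply_max "
                "per channel"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def draw(
        cls,
        rng: np.random.Generator | int,
        v_zero_range: tuple[float, float] = (2.8, 3.3),
        v_maxload_range: tuple[float, float] = (0.8, 1.3),
        **kwargs,
    ) -> "SensorModel":
        """Draw per-channel baselines uniformly from the given ranges.

        Mimics real hardware where every sensor settles at its own
        no-load and loaded level.
        """
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        vz = rng.uniform(*v_zero_range, size=N_CHANNELS)
        vm = rng.uniform(*v_maxload_range, size=N_CHANNELS)
        return cls(v_zero=vz, v_maxload=vm, **kwargs)

    def noiseless(self) -> "SensorModel":
        return replace(self, noise_sd=0.0, drift_rate=0.0)

    @property
    def voltage_range(self) -> np.ndarray:
        return self.v_zero - self.v_maxload


@dataclass(frozen=True)
class PostureScript:
    """Ground-truth posture timeline for the test segment.

    Ordered, non-overlapping ``(posture, start, end)`` segments in seconds
    from test-segment start; together they must tile the scripted span.
    """

    segments: tuple[tuple[PostureLabel, float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("posture script is empty")
        prev_end = None
        for label, start, end in self.segments:
            label = PostureLabel.coerce(label)
            if not label.is_recognized:
                raise ValueError("posture script may only contain P1..P8")
            if end <= start:
                raise ValueError(f"empty script segment [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("script segments overlap or are out of order")
            prev_end = end
        object.__setattr__(
            self,
            "segments",
            tuple((PostureLabel.coerce(l), float(a), float(b)) for l, a, b in self.segments),
        )

    @property
    def duration(self) -> float:
        return self.segments[-1][2]

    def posture_at(self, t: float) -> PostureLabel | None:
        for label, start, end in self.segments:
            if start <= t < end:
                return label
        return None


class FailureMode(enum.Enum):
    """Sensor failure modes injected for quality-control testing."""

    STUCK_ZERO = "stuck_zero"  # channel frozen at its no-load level
    STUCK_FULL = "stuck_full"  # channel frozen at its fully-loaded level
    DROPOUT = "dropout"        # samples missing (NaN) over a span


@dataclass(frozen=True)
class CohortFixture:
    """One synthetic participant: id, posture triple, optional own model/seed."""

    participant: int
    ti1: PostureLabel
    ti2: PostureLabel
    ti3: PostureLabel
    model: SensorModel | None = None
    seed: int | None = None

    @property
    def triple(self) -> tuple[PostureLabel, PostureLabel, PostureLabel]:
        return (self.ti1, self.ti2, self.ti3)


def simulate_trace(
    script: PostureScript,
    model: SensorModel,
    fs: float = 45.0,
    seed: int | np.random.Generator = 0,
    lookup: PostureLookup | None = None,
    calibration_s: float = 2.0,
) -> SensorTrace:
    """Simulate one full recording: calibration segments plus scripted test.

    The trace starts with a ``no_load`` segment (all channels at
    ``v_zero``) and a ``seated_p1`` segment (all channels at
    ``v_maxload``), each ``calibration_s`` long, followed by the scripted
    ``test`` segment. Within a scripted posture, channels active in that
    posture's pattern sit at ``v_maxload``, inactive ones at ``v_zero``;
    Gaussian noise and linear drift are added and the result is clipped to
    ``[0, supply_max]``. Identical seeds produce identical traces.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    lookup = lookup or PostureLookup()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t_test0 = 2.0 * calibration_s
    total = t_test0 + script.duration
    n = int(round(total * fs))
    t = np.arange(n) / fs

    level = np.empty((n, N_CHANNELS))
    no_load = t < calibration_s
    seated = (t >= calibration_s) & (t < t_test0)
    level[no_load] = model.v_zero
    level[seated] = model.v_maxload
    test_idx = np.nonzero(t >= t_test0)[0]
    for label, start, end in script.segments:
        pattern = np.asarray(lookup.pattern_of(label), dtype=bool)
        seg = test_idx[
            (t[test_idx] - t_test0 >= start) & (t[test_idx] - t_test0 < end)
        ]
        level[seg] = np.where(pattern, model.v_maxload, model.v_zero)

    volts = level + model.drift_rate * t[:, None]
    if model.noise_sd > 0:
        volts = volts + rng.normal(0.0, model.noise_sd, size=volts.shape)
    clipped = np.clip(volts, 0.0, model.supply_max)
    clip_fraction = float(np.mean(clipped != volts))

    data = pd.DataFrame({"t": t} | dict(zip(CHANNEL_COLUMNS, clipped.T)))
    return SensorTrace(
        data=data,
        fs=fs,
        segments={
            "no_load": (0.0, calibration_s),
            "seated_p1": (calibration_s, t_test0),
            "test": (t_test0, total),
        },
        supply_max=model.supply_max,
        meta={"clip_fraction": clip_fraction},
    )


def inject_failure(
    trace: SensorTrace,
    channel: int,
    mode: FailureMode | str,
    span: tuple[float, float] | None = None,
) -> SensorTrace:
    """Replace one channel (1-based index) with a failure signature.

    STUCK_ZERO / STUCK_FULL freeze the channel at its no-load / loaded
    level over the whole recording; DROPOUT blanks samples (NaN) over
    ``span`` (defaults to the test segment).
    """
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel must be in 1..{N_CHANNELS}, got {channel}")
    mode = FailureMode(mode) if not isinstance(mode, FailureMode) else mode
    col = CHANNEL_COLUMNS[channel - 1]
    data = trace.data.copy()

    if mode in (FailureMode.STUCK_ZERO, FailureMode.STUCK_FULL):
        # Freeze at the channel's own calibration level, estimated from the
        # trace so the failure is self-consistent with its baselines.
        seg = "no_load" if mode is FailureMode.STUCK_ZERO else "seated_p1"
        value = float(trace.segment(seg)[col].mean())
        data[col] = value
    else:
        span = span or trace.segments.get("test")
        if span is None:
            raise ValueError("DROPOUT needs a span when the trace has no test segment")
        mask = (data["t"] >= span[0]) & (data["t"] < span[1])
        data.loc[mask, col] = np.nan
    return trace.with_data(data)


def generate_fixture_cohort(
    table_12: np.ndarray,
    table_23: np.ndarray,
) -> list[CohortFixture]:
    """Deterministic cohort of posture triples with exact pairwise margins.

    Builds N participants (N = grand total of ``table_12``) whose
    (TI1, TI2) pair counts reproduce ``table_12`` cell-for-cell and whose
    (TI2, TI3) pair counts reproduce ``table_23`` cell-for-cell. TI3 is
    coupled to TI1 only through TI2: within each group of participants
    sharing a TI2 posture (taken in participant-id order), the matching
    row of ``table_23`` is dealt out column by column.

    Requires margin consistency: column sums of ``table_12`` must equal
    row sums of ``table_23``.
    """
    t12 = np.asarray(table_12, dtype=int)
    t23 = np.asarray(table_23, dtype=int)
    k = len(RECOGNIZED)
    if t12.shape != (k, k) or t23.shape != (k, k):
        raise ValueError(f"transition tables must be {k}x{k}")
    if np.any(t12 < 0) or np.any(t23 < 0):
        raise ValueError("transition counts must be non-negative")
    col12 = t12.sum(axis=0)
    row23 = t23.sum(axis=1)
    for j, (a, b) in enumerate(zip(col12, row23)):
        if a != b:
            raise ValueError(
                f"margin mismatch for {RECOGNIZED[j].value}: first table's "
                f"column sum {a} != second table's row sum {b}"
            )

    # (TI1, TI2) pairs in row-major table order; participant ids 1..N.
    pairs: list[tuple[PostureLabel, PostureLabel]] = []
    for i in range(k):
        for j in range(k):
            pairs.extend([(RECOGNIZED[i], RECOGNIZED[j])] * t12[i, j])

    # Deal each TI2 group's TI3 postures from the matching row of t23,
    # in participant-id order within the group.
    ti3_queue: dict[PostureLabel, list[PostureLabel]] = {}
    for j in range(k):
        out: list[PostureLabel] = []
        for m in range(k):
            out.extend([RECOGNIZED[m]] * t23[j, m])
        ti3_queue[RECOGNIZED[j]] = out

    cursors = {label: 0 for label in RECOGNIZED}
    cohort = []
    for pid, (p1, p2) in enumerate(pairs, start=1):
        p3 = ti3_queue[p2][cursors[p2]]
        cursors[p2] += 1
        cohort.append(CohortFixture(participant=pid, ti1=p1, ti2=p2, ti3=p3))
    return cohort


def script_from_triple(
    triple: Sequence[PostureLabel | str],
    schedule: StroopSchedule,
) -> PostureScript:
    """Posture script holding each interval's posture over its window.

    Gaps between windows (instruction screens) inherit the posture of the
    preceding interval, so the script tiles the whole test span.
    """
    windows = schedule.interval_windows()
    p1, p2, p3 = (PostureLabel.coerce(p) for p in triple)
    total = schedule.total_duration()
    return PostureScript(
        segments=(
            (p1, 0.0, windows.ti2.start),
            (p2, windows.ti2.start, windows.ti3.start),
            (p3, windows.ti3.start, total),
        )
    )


def cohort_to_traces(
    cohort: Sequence[CohortFixture],
    schedule: StroopSchedule,
    model: SensorModel | None = None,
    seed: int = 0,
    fs: float = 45.0,
    lookup: PostureLookup | None = None,
    calibration_s: float = 2.0,
) -> list[tuple[CohortFixture, SensorTrace]]:
    """Simulate one full recording per cohort participant.

    Each participant's trace holds their TI1/TI2/TI3 posture over the
    corresponding schedule window, preceded by the calibration segments.
    Per-participant randomness is spawned from ``seed`` so the cohort is
    reproducible as a whole; a fixture's own ``model``/``seed`` override
    the shared ones.
    """
    if model is None:
        model = SensorModel.draw(np.random.default_rng(seed))
    base = np.random.SeedSequence(seed)
    out = []
    for fixture, child in zip(cohort, base.spawn(len(cohort))):
        rng = np.random.default_rng(fixture.seed if fixture.seed is not None else child)
        script = script_from_triple(fixture.triple, schedule)
        trace = simulate_trace(
            script,
            fixture.model or model,
            fs=fs,
            seed=rng,
            lookup=lookup,
            calibration_s=calibration_s,
        )
        trace.meta["participant"] = fixture.participant
        out.append((fixture, trace))
    return out


def cohort_to_frame(cohort: Sequence[CohortFixture]) -> pd.DataFrame:
    """Cohort fixtures as a DataFrame ``participant, ti1, ti2, ti3``."""
    return pd.DataFrame(
        {
            "participant": [f.participant for f in cohort],
            "ti1": [f.ti1.value for f in cohort],
            "ti2": [f.ti2.value for f in cohort],
            "ti3": [f.ti3.value for f in cohort],
        }
    )
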