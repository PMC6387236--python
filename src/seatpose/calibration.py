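"""Adaptive per-test calibration, low-pass filtering, and activation.

Every sensor settles at its own no-load voltage and its own loaded
voltage, and both differ between participants, so no fixed threshold
works. Instead each recording carries two calibration acquisitions:

* ``no_load`` — chair empty; the per-channel mean is ``v_zero``;
* ``seated_p1`` — participant fully seated (posture P1, every sensor
  pressed); the per-channel mean is ``v_maxload``.

The activation threshold per channel is the midpoint of that range,
``v_maxload + 0.5 * (v_zero - v_maxload)``. Signals are smoothed with a
centered moving-average filter whose window length is chosen from the
-3 dB criterion for the requested cutoff (N = 20 samples at 45 Hz for a
1 Hz cutoff); a channel counts as pressed while its filtered voltage is
strictly below its threshold (the response is inverted: load pulls the
output down).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .postures import N_CHANNELS
from .trace import CHANNEL_COLUMNS, SensorTrace

__all__ = [
    "CalibrationProfile",
    "estimate_vzero",
    "estimate_vmaxload",
    "compute_threshold",
    "calibrate",
    "moving_average",
    "moving_average_window",
    "moving_average_gain",
    "activation_series",
]

MIN_CALIBRATION_S = 0.5

# -3 dB point of an N-sample moving average sits at ~0.443 * fs / N,
# so the window for a given cutoff is N = round(0.443 * fs / cutoff).
_MA_3DB_CONST = 0.443


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-channel baselines and the midpoint activation threshold."""

    v_zero: np.ndarray
    v_maxload: np.ndarray

    def __post_init__(self) -> None:
        vz = np.asarray(self.v_zero, dtype=float)
        vm = np.asarray(self.v_maxload, dtype=float)
        if vz.shape != (N_CHANNELS,) or vm.shape != (N_CHANNELS,):
            raise ValueError(f"profiles carry {N_CHANNELS} channels")
        object.__setattr__(self, "v_zero", vz)
        object.__setattr__(self, "v_maxload", vm)
        if np.any(vm >= vz):
            bad = [i + 1 for i in np.nonzero(vm >= vz)[0]]
            raise ValueError(
                f"channel(s) {bad} do not discriminate: v_maxload >= v_zero"
            )

    @property
    def threshold(self) -> np.ndarray:
        return compute_threshold(self.v_zero, self.v_maxload)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            f"ats{i + 1}": {
                "v_zero": float(self.v_zero[i]),
                "v_maxload": float(self.v_maxload[i]),
                "threshold": float(self.threshold[i]),
            }
            for i in range(N_CHANNELS)
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationProfile":
        payload = json.loads(Path(path).read_text())
        vz = [payload[c]["v_zero"] for c in CHANNEL_COLUMNS]
        vm = [payload[c]["v_maxload"] for c in CHANNEL_COLUMNS]
        return cls(v_zero=np.array(vz), v_maxload=np.array(vm))


def _segment_mean(trace: SensorTrace, name: str) -> np.ndarray:
    mask = trace.segment_mask(name)
    n_min = int(np.ceil(MIN_CALIBRATION_S * trace.fs))
    if mask.sum() < n_min:
        raise ValueError(
            f"{name!r} segment too short: need >= {MIN_CALIBRATION_S} s "
            f"({n_min} samples at {trace.fs} Hz), got {int(mask.sum())}"
        )
    return trace.data.loc[mask, list(CHANNEL_COLUMNS)].mean().to_numpy()


def estimate_vzero(trace: SensorTrace) -> np.ndarray:
    """Per-channel mean voltage over the annotated no-load segment."""
    return _segment_mean(trace, "no_load")


def estimate_vmaxload(trace: SensorTrace) -> np.ndarray:
    """Per-channel mean voltage over the fully-seated (P1) segment.

    The mean of the loaded-state level is used rather than the per-sample
    minimum so that noise does not bias the estimate downward.
    """
    return _segment_mean(trace, "seated_p1")


def compute_threshold(v_zero, v_maxload) -> np.ndarray | float:
    """Midpoint threshold: 50% of the range between v_maxload and v_zero."""
    vz = np.asarray(v_zero, dtype=float)
    vm = np.asarray(v_maxload, dtype=float)
    if np.any(vm >= vz):
        raise ValueError("v_maxload must be strictly below v_zero")
    out = vm + 0.5 * (vz - vm)
    return float(out) if out.ndim == 0 else out


def calibrate(trace: SensorTrace) -> CalibrationProfile:
    """Estimate the per-test calibration profile from a trace's segments."""
    return CalibrationProfile(
        v_zero=estimate_vzero(trace), v_maxload=estimate_vmaxload(trace)
    )


def moving_average_window(fs: float, cutoff: float) -> int:
    """Moving-average length whose -3 dB point falls at ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    return max(1, int(round(_MA_3DB_CONST * fs / cutoff)))


def moving_average_gain(f: float, fs: float, n: int) -> float:
    """Amplitude gain of an N-sample moving average at frequency ``f``.

    Dirichlet-kernel closed form ``|sin(pi f N / fs) / (N sin(pi f / fs))|``.
    """
    if f == 0:
        return 1.0
    return abs(np.sin(np.pi * f * n / fs) / (n * np.sin(np.pi * f / fs)))


def moving_average(trace: SensorTrace, cutoff: float = 1.0) -> SensorTrace:
    """Low-pass filter all channels with a centered moving average.

    The window length comes from :func:`moving_average_window`; the window
    is centered (zero phase for offline analysis) and shrinks at the trace
    edges so the output has the same length as the input.
    """
    n = moving_average_window(trace.fs, cutoff)
    data = trace.data.copy()
    cols = list(CHANNEL_COLUMNS)
    data[cols] = data[cols].rolling(window=n, center=True, min_periods=1).mean()
    out = trace.with_data(data)
    out.meta["ma_window"] = n
    return out


def activation_series(filtered: SensorTrace, profile: CalibrationProfile) -> pd.DataFrame:
    """Binary activation per channel: pressed while strictly below threshold.

    Returns a boolean DataFrame aligned to the trace (``t`` column plus
    ``ats1..ats8``). Values exactly at the threshold count as inactive;
    missing samples (NaN) count as inactive.
    """
    volts = filtered.voltages()
    with np.errstate(invalid="ignore"):
        active = volts < profile.threshold[None, :]
    out = pd.DataFrame(dict(zip(CHANNEL_COLUMNS, active.T)))
    out.insert(0, "t", filtered.t)
    return out
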