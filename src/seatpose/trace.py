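"""The multichannel voltage-trace container and its CSV/JSON round trip.

A :class:`SensorTrace` holds the eight sensor voltage series sampled at a
fixed rate together with segment annotations marking the calibration
acquisitions (``no_load``, ``seated_p1``) and the ``test`` span. Traces
are stored as a pandas DataFrame with a time column ``t`` [s] and channel
columns ``ats1``..``ats8`` [V]; missing samples (sensor dropout) are NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .postures import N_CHANNELS

__all__ = ["SensorTrace", "CHANNEL_COLUMNS"]

CHANNEL_COLUMNS = tuple(f"ats{i}" for i in range(1, N_CHANNELS + 1))


@dataclass(frozen=True)
class SensorTrace:
    """Timestamped 8-channel voltage series with segment annotations.

    ``segments`` maps segment names to half-open ``(start, end)`` spans in
    seconds on the trace's time axis. ``supply_max`` is the ADC full-scale
    voltage, used by quality control to detect saturation.
    """

    data: pd.DataFrame
    fs: float
    segments: dict[str, tuple[float, float]] = field(default_factory=dict)
    supply_max: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        missing = [c for c in ("t", *CHANNEL_COLUMNS) if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace is missing columns: {missing}")

    # -- accessors ---------------------------------------------------------

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    def voltages(self) -> np.ndarray:
        """(n_samples, 8) voltage array in channel order."""
        return self.data[list(CHANNEL_COLUMNS)].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def segment_mask(self, name: str) -> np.ndarray:
        """Boolean sample mask of a named segment ([start, end))."""
        try:
            start, end = self.segments[name]
        except KeyError as exc:
            raise ValueError(f"trace has no {name!r} segment") from exc
        t = self.t
        return (t >= start) & (t < end)

    def segment(self, name: str) -> pd.DataFrame:
        return self.data.loc[self.segment_mask(name)]

    def with_data(self, data: pd.DataFrame) -> "SensorTrace":
        return replace(self, data=data)

    # -- persistence -------------------------------------------------------

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the trace CSV and its JSON segment sidecar.

        The sidecar defaults to ``<path>.json`` and records the sampling
        rate, segments, supply voltage and any metadata.
        """
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
        payload = {
            "fs": self.fs,
            "segments": {k: list(v) for k, v in self.segments.items()},
            "supply_max": self.supply_max,
            "meta": self.meta,
        }
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "SensorTrace":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"segment sidecar not found: {sidecar}")
        payload = json.loads(sidecar.read_text())
        return cls(
            data=data,
            fs=float(payload["fs"]),
            segments={k: (float(a), float(b)) for k, (a, b) in payload["segments"].items()},
            supply_max=payload.get("supply_max"),
            meta=payload.get("meta", {}),
        )
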