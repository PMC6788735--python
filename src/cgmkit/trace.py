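"""Core in-memory representation of a continuous glucose monitor recording.

A :class:`GlucoseTrace` is the currency passed between every stage of the
pipeline: readers produce one, the cleaner transforms one, and the metric
and report modules consume them.  Glucose is always stored in mg/dL.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440.0


@dataclass(eq=False)
class GlucoseTrace:
    """One subject's ordered sensor glucose series.

    Sensor dropouts are represented by jumps in the timestamp sequence,
    never by null rows, so every stored glucose value is a real reading.

    Parameters
    ----------
    subject_id
        Identifier copied into every downstream output row.
    times
        Strictly increasing timestamps, kept at second precision.
    glucose
        Sensor glucose in mg/dL; finite and strictly positive.
    """

    subject_id: str
    times: pd.DatetimeIndex
    glucose: np.ndarray

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times).round("s")
        glucose = np.asarray(self.glucose, dtype=float)
        if len(times) != len(glucose):
            raise ValueError("times and glucose must have equal length")
        if len(times) > 1 and not (np.diff(times.asi8) > 0).all():
            raise ValueError(
                f"{self.subject_id}: timestamps must be strictly increasing"
            )
        if len(glucose) and bool((~np.isfinite(glucose) | (glucose <= 0)).any()):
            raise ValueError(
                f"{self.subject_id}: glucose values must be finite and > 0 mg/dL"
            )
        self.times = times
        self.glucose = glucose

    def __len__(self) -> int:
        return len(self.glucose)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlucoseTrace):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and len(self) == len(other)
            and bool(np.array_equal(self.times.asi8, other.times.asi8))
            and bool(np.array_equal(self.glucose, other.glucose))
        )

    @property
    def diffs_minutes(self) -> np.ndarray:
        """Successive timestamp differences in minutes."""
        return np.diff(self.times.asi8) / 60e9

    @property
    def span_minutes(self) -> float:
        """Total wear span from first to last reading, in minutes."""
        if len(self) < 2:
            return 0.0
        return float((self.times.asi8[-1] - self.times.asi8[0]) / 60e9)

    @property
    def clock_minutes(self) -> np.ndarray:
        """Minute-of-day (0 <= m < 1440) of every sample."""
        delta = self.times - self.times.normalize()
        return np.asarray(delta.total_seconds(), dtype=float) / 60.0

    def take(self, indices) -> "GlucoseTrace":
        """New trace restricted to ``indices`` (boolean mask or index array)."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.nonzero(indices)[0]
        return GlucoseTrace(self.subject_id, self.times[indices], self.glucose[indices])

    def to_frame(self) -> pd.DataFrame:
        """Three-column interchange layout as a DataFrame."""
        ids = [self.subject_id] + [""] * (len(self) - 1) if len(self) else []
        return pd.DataFrame(
            {
                "subjectid": ids,
                "timestamp": self.times.strftime("%Y-%m-%d %H:%M:%S"),
                "sensorglucose": self.glucose,
            }
        )
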