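"""Reproducible synthetic CGM traces and device-dialect fixture writers.

The generator composes a multi-day glucose signal from four analytic
ingredients — a constant baseline, a sinusoidal circadian rhythm, triangular
meal excursions at fixed clock times, and Gaussian sensor noise — then
deletes samples to inject gaps.  Because every ingredient is recorded in a
truth record, downstream computations (mean, SD, MAGE, excursion counts,
gap bookkeeping) can be checked against known values rather than against
another implementation.

Triangular meal bumps are deliberately not biophysical: their peak
amplitude and timing are exact, which makes them analytic truth for
excursion and MAGE tests.  Glucose is clipped at a 40 mg/dL sensor floor,
the one nonlinearity that can perturb that truth; test configurations
avoid parameter ranges that clip.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .readers import write_clean
from .trace import GlucoseTrace

SENSOR_FLOOR = 40.0  # mg/dL
_CIRCADIAN_PEAK_MINUTE = 960  # 16:00; trough 04:00


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe a 29-day wear at the 5-minute Dexcom/iPro cadence
    (8352 readings per subject; three such subjects give the ~25,000-value
    pool used for aggregate-overlay reporting), a 120 mg/dL baseline with a
    15 mg/dL circadian swing peaking at 16:00, three 60 mg/dL triangular
    meal excursions of 2 h at fixed clock times, and 10 mg/dL sensor noise.
    """

    n_days: int = 29
    interval_minutes: float = 5.0
    baseline_mean: float = 120.0
    circadian_amplitude: float = 15.0
    n_meals_per_day: int = 3
    meal_amplitude: float = 60.0
    meal_duration: float = 120.0
    noise_sd: float = 10.0
    #: gaps to inject, as (start_offset_minutes, duration_minutes); samples
    #: strictly inside each window are deleted, so the resulting
    #: timestamp jump equals the stated duration when both ends are on-grid.
    gap_spec: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.interval_minutes <= 0:
            raise ValueError("need n_days >= 1 and a positive interval")
        if self.noise_sd < 0 or self.meal_amplitude < 0 or self.meal_duration <= 0:
            raise ValueError("invalid meal/noise parameters")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive mg/dL")


def meal_clock_minutes(n_meals: int) -> np.ndarray:
    """Meal start times, evenly spaced between 07:00 and 19:00."""
    if n_meals <= 0:
        return np.array([])
    return np.linspace(7 * 60, 19 * 60, n_meals)


def simulate_trace(config: SimConfig | None = None, subject_id: str = "S001",
                   start: str = "2024-03-01") -> tuple[GlucoseTrace, dict]:
    """Generate one trace plus the truth record of everything injected."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    step = config.interval_minutes
    n = int(round(config.n_days * 1440 / step))
    offsets = np.arange(n) * step  # minutes from start
    t0 = pd.Timestamp(start)
    clock = (offsets + (t0 - t0.normalize()).total_seconds() / 60.0) % 1440

    g = np.full(n, config.baseline_mean)
    if config.circadian_amplitude:
        g = g + config.circadian_amplitude * np.sin(
            2 * np.pi * (clock - (_CIRCADIAN_PEAK_MINUTE - 360)) / 1440.0
        )
    meals = meal_clock_minutes(config.n_meals_per_day)
    half = config.meal_duration / 2.0
    for m in meals:
        peak = m + half
        dist = np.abs(clock - peak)
        dist = np.minimum(dist, 1440 - dist)  # clock wraps
        g = g + config.meal_amplitude * np.clip(1.0 - dist / half, 0.0, None)
    if config.noise_sd > 0:
        g = g + rng.normal(0.0, config.noise_sd, n)
    g = np.maximum(g, SENSOR_FLOOR)

    keep = np.ones(n, dtype=bool)
    for gap_start, gap_len in config.gap_spec:
        keep &= ~((offsets > gap_start) & (offsets < gap_start + gap_len))

    times = t0 + pd.to_timedelta(offsets[keep], unit="m")
    trace = GlucoseTrace(subject_id, pd.DatetimeIndex(times), g[keep])
    truth = {
        "config": config,
        "subject_id": subject_id,
        "start": str(t0),
        "meal_clock_minutes": meals.tolist(),
        "circadian_peak_minute": _CIRCADIAN_PEAK_MINUTE,
        "n_before_gaps": n,
        "n_after_gaps": int(keep.sum()),
    }
    return trace, truth


# ---------------------------------------------------------------------------
# dialect fixture writers (each emits the signature readers detect it by)

def _fmt_g(g: float) -> str:
    return repr(float(g))


def _write_dexcom(trace: GlucoseTrace, path: Path) -> None:
    lines = ["Index,Timestamp (YYYY-MM-DDThh:mm:ss),Event Type,Glucose Value (mg/dL)"]
    stamps = trace.times.strftime("%Y-%m-%dT%H:%M:%S")
    for i, (ts, g) in enumerate(zip(stamps, trace.glucose), start=1):
        lines.append(f"{i},{ts},EGV,{_fmt_g(g)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_libre(trace: GlucoseTrace, path: Path) -> None:
    lines = [
        trace.subject_id,
        "ID\tTime\tRecord Type\tHistoric Glucose (mg/dL)",
    ]
    stamps = trace.times.strftime("%m/%d/%Y %H:%M")
    for i, (ts, g) in enumerate(zip(stamps, trace.glucose), start=1):
        lines.append(f"{i}\t{ts}\t0\t{_fmt_g(g)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_ipro2(trace: GlucoseTrace, path: Path) -> None:
    lines = [
        f"Patient ID,{trace.subject_id}",
        "Device,iPro2",
        "",
        "Index,Timestamp,Sensor Glucose (mg/dL)",
    ]
    stamps = trace.times.strftime("%m/%d/%Y %H:%M:%S")
    for i, (ts, g) in enumerate(zip(stamps, trace.glucose), start=1):
        lines.append(f"{i},{ts},{_fmt_g(g)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_carelink(trace: GlucoseTrace, path: Path) -> None:
    lines = [
        f"Patient ID,{trace.subject_id}",
        "Device,CareLink",
        "",
        "Index,Date,Time,Sensor Glucose (mg/dL),ISIG Value",
    ]
    dates = trace.times.strftime("%m/%d/%Y")
    clocks = trace.times.strftime("%H:%M:%S")
    for i, (d, c, g) in enumerate(zip(dates, clocks, trace.glucose), start=1):
        lines.append(f"{i},{d},{c},{_fmt_g(g)},10.0")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_diasend(trace: GlucoseTrace, path: Path) -> None:
    lines = [
        f"Name\t{trace.subject_id}",
        "Export\tDiasend",
        "Time\tmg/dL",
    ]
    stamps = trace.times.strftime("%m/%d/%Y %H:%M")
    for ts, g in zip(stamps, trace.glucose):
        lines.append(f"{ts}\t{_fmt_g(g)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


_WRITERS = {
    "dexcom": _write_dexcom,
    "libre": _write_libre,
    "ipro2": _write_ipro2,
    "carelink": _write_carelink,
    "diasend": _write_diasend,
}


def write_dialect_fixture(trace: GlucoseTrace, dialect: str, path) -> Path:
    """Write ``trace`` in the requested device dialect.

    The emitted file carries exactly the header signature that
    :func:`cgmkit.readers.detect_dialect` probes for, and parsing it
    reproduces ``trace`` (minute-precision dialects require
    minute-aligned timestamps, which simulated traces always have).
    """
    path = Path(path)
    if dialect == "generic3col":
        return write_clean(trace, path)
    if dialect not in _WRITERS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from "
                         f"{('generic3col',) + tuple(_WRITERS)}")
    if len(trace) == 0:
        raise ValueError("refusing to write an empty fixture")
    _WRITERS[dialect](trace, path)
    return path
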