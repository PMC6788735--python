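"""Gap handling for CGM traces.

Sensors drop readings (compression lows, signal loss, warm-up), leaving
holes in the record that bias duration-weighted summaries.  The cleaner
infers the nominal sampling cadence, linearly interpolates short gaps, and
optionally deletes whole 24-hour chunks that still contain long gaps so
that daytime and nighttime are represented equally — the balance that
day/night AUC comparisons rely on.

Conventions (documented because the two rules must partition all gaps):

* a *gap* is any successive-timestamp difference strictly greater than the
  nominal interval;
* a gap of duration exactly ``maximumgap`` is on the *fillable* side
  (filled when ``gapfill`` is on, never a reason to remove a chunk);
* 24-hour chunks are anchored at the subject's first sample timestamp, not
  at midnight, so any start time yields equal day/night coverage.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import GlucoseTrace

logger = logging.getLogger(__name__)

_EPS = 1e-9
_DAY_S = 86_400


@dataclass
class CleanConfig:
    """Options mirroring the cleaner's three user-facing knobs.

    ``maximumgap`` (minutes) is both the longest gap filled by
    interpolation and the threshold above which a gap condemns its
    24-hour chunk.  ``drop_partial_days`` additionally removes a trailing
    chunk shorter than 24 h even when gapless, for strict day/night
    balance; it is off by default so that cleaning a gapless trace is the
    identity.
    """

    gapfill: bool = True
    removegaps: bool = True
    maximumgap: float = 20.0
    drop_partial_days: bool = False

    def __post_init__(self) -> None:
        if self.maximumgap <= 0:
            raise ValueError("maximumgap must be > 0 minutes")


@dataclass
class CleanReport:
    """Audit trail of one cleaning run."""

    n_interpolated: int = 0
    n_days_removed: int = 0
    gaps_found: list = field(default_factory=list)  # (start, end, minutes)


def infer_interval(trace: GlucoseTrace) -> float:
    """Nominal sampling interval: the modal successive difference, minutes.

    The mode is robust to isolated gaps; ties resolve to the smallest
    candidate (the denser cadence).
    """
    if len(trace) < 2:
        raise ValueError(f"{trace.subject_id}: need >= 2 samples to infer an interval")
    diffs = trace.diffs_minutes
    values, counts = np.unique(diffs, return_counts=True)
    return float(values[np.argmax(counts)])


def find_gaps(trace: GlucoseTrace, interval: float) -> list[tuple]:
    """Maximal runs of missing samples, as (start, end, minutes) triples.

    ``start``/``end`` are the bounding *present* sample timestamps; a run
    of k consecutive missing samples is one gap of (k+1)*interval minutes.
    """
    if interval <= 0:
        raise ValueError("interval must be > 0")
    diffs = trace.diffs_minutes
    idx = np.nonzero(diffs > interval + _EPS)[0]
    return [
        (trace.times[i], trace.times[i + 1], float(diffs[i]))
        for i in idx
    ]


def fill_gaps(trace: GlucoseTrace, config: CleanConfig | None = None,
              interval: float | None = None) -> tuple[GlucoseTrace, CleanReport]:
    """Linearly interpolate every gap no longer than ``maximumgap``.

    Inserted timestamps continue the nominal grid from the gap's left
    edge; glucose values lie exactly on the line joining the bounding
    readings.  Longer gaps are reported but left untouched.
    """
    config = config or CleanConfig()
    if interval is None:
        interval = infer_interval(trace)
    gaps = find_gaps(trace, interval)
    report = CleanReport(gaps_found=gaps)
    if not gaps:
        return trace, report

    step_s = int(round(interval * 60))
    t_s = trace.times.asi8 // 10**9
    new_t: list[int] = []
    new_g: list[float] = []
    gap_left = {pd.Timestamp(s).value // 10**9: m for s, _, m in gaps}
    for i in range(len(trace)):
        new_t.append(int(t_s[i]))
        new_g.append(float(trace.glucose[i]))
        if i + 1 == len(trace):
            break
        minutes = gap_left.get(int(t_s[i]))
        if minutes is None or minutes > config.maximumgap + _EPS:
            continue
        left, right = int(t_s[i]), int(t_s[i + 1])
        gl, gr = float(trace.glucose[i]), float(trace.glucose[i + 1])
        t = left + step_s
        while t < right:
            frac = (t - left) / (right - left)
            new_t.append(t)
            new_g.append(gl + frac * (gr - gl))
            report.n_interpolated += 1
            t += step_s
    times = pd.DatetimeIndex(np.array(new_t, dtype="int64") * 10**9)
    filled = GlucoseTrace(trace.subject_id, times, np.array(new_g))
    return filled, report


def remove_gap_days(trace: GlucoseTrace, config: CleanConfig | None = None,
                    interval: float | None = None) -> tuple[GlucoseTrace, CleanReport]:
    """Delete whole 24-hour chunks that contain a gap longer than ``maximumgap``.

    Chunks are consecutive 24-h windows anchored at the first sample; a
    chunk is condemned when the open interval of any long gap overlaps it.
    Surviving chunks are concatenated in order.
    """
    config = config or CleanConfig()
    if len(trace) == 0:
        return trace, CleanReport()
    if interval is None:
        interval = infer_interval(trace)
    gaps = find_gaps(trace, interval)
    long_gaps = [g for g in gaps if g[2] > config.maximumgap + _EPS]
    report = CleanReport(gaps_found=gaps)

    t_s = trace.times.asi8 // 10**9
    t0 = int(t_s[0])
    chunk = (t_s - t0) // _DAY_S
    n_chunks = int(chunk[-1]) + 1

    bad: set[int] = set()
    for start, end, _ in long_gaps:
        lo = (int(pd.Timestamp(start).value // 10**9) + 1 - t0) // _DAY_S
        hi = (int(pd.Timestamp(end).value // 10**9) - 1 - t0) // _DAY_S
        bad.update(range(int(lo), int(hi) + 1))
    if config.drop_partial_days and n_chunks >= 1:
        step_s = int(round(interval * 60))
        complete = int(t_s[-1]) >= t0 + n_chunks * _DAY_S - step_s
        if not complete:
            bad.add(n_chunks - 1)
            warnings.warn(
                f"{trace.subject_id}: trailing partial 24-h chunk dropped",
                stacklevel=2,
            )
    bad &= set(range(n_chunks))

    keep = ~np.isin(chunk, sorted(bad))
    report.n_days_removed = len(bad)
    out = trace.take(keep)
    if len(out) == 0:
        warnings.warn(
            f"{trace.subject_id}: no data survived 24-h chunk removal", stacklevel=2
        )
    return out, report


def clean(trace: GlucoseTrace, config: CleanConfig | None = None
          ) -> tuple[GlucoseTrace, CleanReport]:
    """Full cleaning pipeline: infer cadence, fill short gaps, drop gap days."""
    config = config or CleanConfig()
    interval = infer_interval(trace)
    report = CleanReport(gaps_found=find_gaps(trace, interval))
    out = trace
    if config.gapfill:
        out, fill_rep = fill_gaps(out, config, interval)
        report.n_interpolated = fill_rep.n_interpolated
    if config.removegaps:
        out, rm_rep = remove_gap_days(out, config, interval)
        report.n_days_removed = rm_rep.n_days_removed
    return out, report
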