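"""Glycemic summary variables for one cleaned CGM trace.

Implements the standard descriptive set used in diabetes research: wear
percentage, distributional statistics, estimated HbA1c and the glucose
management indicator (GMI), time above/below/in-range with duration-gated
excursion counts, day/night splits, trapezoidal AUC, MAGE via Baghurst's
turning-point elimination, CONGA, MODD, the J-index, and the Kovatchev
low/high blood glucose risk indices.  One call to :func:`summarize`
produces one output row per subject keyed by patient id.

Boundary semantics follow the conventional printed definitions: "time over
T" counts samples at or above T, "time under U" counts samples at or below
U, and in-range is 70-180 mg/dL inclusive — so a sample sitting exactly on
a cutoff contributes to both adjacent bands.  :func:`time_in_band` exposes
strict variants for callers needing an exact partition of wear time.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cleaning import infer_interval
from .trace import GlucoseTrace

_MAGE_K = {"1sd": 1.0, "1.5sd": 1.5, "2sd": 2.0}


@dataclass
class MetricsConfig:
    """Thresholds, duration gates and windows for the summary variables.

    Defaults: hyperglycemic cutoffs {120, 140, 180, 200, 250} mg/dL and
    hypoglycemic cutoffs {54, 60, 70} mg/dL; an excursion must persist 35
    min above or 10 min below its threshold; daytime is the clock window
    [06:00, 22:00); MAGE keeps excursions exceeding 1 SD; CONGA lag 1 h.
    """

    over_thresholds: tuple = (120, 140, 180, 200, 250)
    under_thresholds: tuple = (54, 60, 70)
    min_over_duration: float = 35.0
    min_under_duration: float = 10.0
    daystart: int = 6
    dayend: int = 22
    magedef: str = "1sd"
    conga_hours: int = 1
    #: Constant of the printed J-index formula 0.324 x (mean + SD)^2.  The
    #: mmol/L literature uses 0.324 and the mg/dL rescaling 0.001; the
    #: printed mg/dL formula keeps 0.324, so that is the default and the
    #: knob is exposed rather than second-guessed.
    j_index_constant: float = 0.324
    cv_percent: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.daystart < self.dayend <= 24):
            raise ValueError("need 0 <= daystart < dayend <= 24")
        if self.magedef not in _MAGE_K:
            raise ValueError(f"magedef must be one of {sorted(_MAGE_K)}")
        if self.min_over_duration <= 0 or self.min_under_duration <= 0:
            raise ValueError("excursion duration gates must be > 0")
        if any(t <= 0 for t in self.over_thresholds + self.under_thresholds):
            raise ValueError("thresholds must be positive mg/dL")
        if self.conga_hours < 1:
            raise ValueError("conga_hours must be a positive integer")


# ---------------------------------------------------------------------------
# closed-form transforms of the mean (and SD)

def estimated_a1c(mean_glucose: float) -> float:
    """Estimated HbA1c (%) from mean glucose: (46.7 + mean) / 28.7."""
    if mean_glucose <= 0:
        raise ValueError("mean glucose must be > 0 mg/dL")
    return (46.7 + mean_glucose) / 28.7


def gmi(mean_glucose: float) -> float:
    """Glucose management indicator (%): 3.31 + 0.02392 x mean."""
    if mean_glucose <= 0:
        raise ValueError("mean glucose must be > 0 mg/dL")
    return 3.31 + 0.02392 * mean_glucose


def j_index(mean: float, sd: float, constant: float = 0.324) -> float:
    """J-index: ``constant`` x (mean + SD)^2."""
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be non-negative")
    return constant * (mean + sd) ** 2


# ---------------------------------------------------------------------------
# wear and distributional statistics

def percent_cgm_wear(trace: GlucoseTrace, interval: float | None = None) -> float:
    """Readings as a percentage of potential readings over the worn span."""
    if len(trace) < 2:
        raise ValueError("need >= 2 samples")
    if interval is None:
        interval = infer_interval(trace)
    potential = math.floor(trace.span_minutes / interval + 1e-9) + 1
    return 100.0 * len(trace) / potential


def basic_stats(trace: GlucoseTrace, cv_percent: bool = False) -> dict:
    """Mean, quartiles (type-7), sample SD, CV, min, max."""
    if len(trace) < 2:
        raise ValueError("need >= 2 samples")
    g = trace.glucose
    q1, med, q3 = np.percentile(g, [25, 50, 75])  # linear interpolation
    mean = float(np.mean(g))
    sd = float(np.std(g, ddof=1))
    cv = sd / mean
    return {
        "average_sensor": mean,
        "q1_sensor": float(q1),
        "median_sensor": float(med),
        "q3_sensor": float(q3),
        "standard_deviation": sd,
        "cv": 100.0 * cv if cv_percent else cv,
        "min_sensor": float(np.min(g)),
        "max_sensor": float(np.max(g)),
    }


# ---------------------------------------------------------------------------
# time in bands and excursions

def time_in_band(trace: GlucoseTrace, lower: float | None = None,
                 upper: float | None = None, interval: float | None = None, *,
                 lower_inclusive: bool = True, upper_inclusive: bool = True) -> float:
    """Minutes with glucose inside [lower, upper]; each reading counts one
    nominal interval."""
    if interval is None:
        interval = infer_interval(trace)
    g = trace.glucose
    mask = np.ones(len(g), dtype=bool)
    if lower is not None:
        mask &= (g >= lower) if lower_inclusive else (g > lower)
    if upper is not None:
        mask &= (g <= upper) if upper_inclusive else (g < upper)
    return float(mask.sum()) * interval


def time_metrics(trace: GlucoseTrace, config: MetricsConfig | None = None,
                 interval: float | None = None) -> dict:
    """Minutes and percent of wear time over/under each threshold and in
    70-180 mg/dL, with the overlapping boundary semantics described in the
    module docstring."""
    config = config or MetricsConfig()
    if interval is None:
        interval = infer_interval(trace)
    total = len(trace) * interval
    out: dict = {}
    for t in config.over_thresholds:
        mins = time_in_band(trace, lower=t, interval=interval)
        out[f"min_spent_over_{_fmt(t)}"] = mins
        out[f"percent_time_over_{_fmt(t)}"] = 100.0 * mins / total
    for u in config.under_thresholds:
        mins = time_in_band(trace, upper=u, interval=interval)
        out[f"min_spent_under_{_fmt(u)}"] = mins
        out[f"percent_time_under_{_fmt(u)}"] = 100.0 * mins / total
    mins = time_in_band(trace, lower=70, upper=180, interval=interval)
    out["min_spent_70_180"] = mins
    out["percent_time_70_180"] = 100.0 * mins / total
    return out


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def excursions(trace: GlucoseTrace, config: MetricsConfig | None = None,
               interval: float | None = None) -> dict:
    """Duration-gated excursion counts.

    An over-excursion at threshold T is a maximal run of consecutive
    readings at or above T lasting at least ``min_over_duration`` minutes
    (each reading counts one nominal interval); under-excursions are
    analogous with at-or-below and ``min_under_duration``.  Per-day
    averages divide by wear time in days.
    """
    config = config or MetricsConfig()
    if interval is None:
        interval = infer_interval(trace)
    days = len(trace) * interval / 1440.0
    out: dict = {}
    for t in config.over_thresholds:
        runs = _runs(trace.glucose >= t)
        n = sum(1 for _, ln in runs if ln * interval >= config.min_over_duration - 1e-9)
        out[f"excursions_over_{_fmt(t)}"] = n
        out[f"avg_excur_over_{_fmt(t)}_per_day"] = n / days
    for u in config.under_thresholds:
        runs = _runs(trace.glucose <= u)
        n = sum(1 for _, ln in runs if ln * interval >= config.min_under_duration - 1e-9)
        out[f"excursions_under_{_fmt(u)}"] = n
    return out


# ---------------------------------------------------------------------------
# AUC and day/night splits

def _day_mask(trace: GlucoseTrace, daystart: int, dayend: int) -> np.ndarray:
    clock = trace.clock_minutes
    return (clock >= daystart * 60) & (clock < dayend * 60)


def auc_trapezoid(trace: GlucoseTrace, config: MetricsConfig | None = None) -> dict:
    """Trapezoidal area under the glucose curve, in mg.min/dL.

    Sums (g_i + g_{i+1})/2 x dt over successive sample pairs; a pair
    straddling the day/night boundary belongs to the window of its left
    sample, so daytime + nighttime AUC equals the total exactly.
    """
    config = config or MetricsConfig()
    if len(trace) < 2:
        raise ValueError("need >= 2 samples for AUC")
    g = trace.glucose
    dt = trace.diffs_minutes
    areas = (g[:-1] + g[1:]) / 2.0 * dt
    day = _day_mask(trace, config.daystart, config.dayend)[:-1]
    return {
        "auc": float(areas.sum()),
        "daytime_auc": float(areas[day].sum()),
        "nighttime_auc": float(areas[~day].sum()),
    }


def daynight_stats(trace: GlucoseTrace, config: MetricsConfig | None = None) -> dict:
    """Mean/min/max/SD of glucose split by the daytime clock window."""
    config = config or MetricsConfig()
    out: dict = {}
    day = _day_mask(trace, config.daystart, config.dayend)
    for label, mask in (("daytime", day), ("nighttime", ~day)):
        g = trace.glucose[mask]
        if len(g) == 0:
            warnings.warn(f"{trace.subject_id}: no {label} samples in window",
                          stacklevel=2)
            vals = dict.fromkeys(("mean", "min", "max", "sd"), float("nan"))
        else:
            vals = {
                "mean": float(np.mean(g)),
                "min": float(np.min(g)),
                "max": float(np.max(g)),
                "sd": float(np.std(g, ddof=1)) if len(g) > 1 else float("nan"),
            }
        out.update({f"{label}_{k}": v for k, v in vals.items()})
    return out


# ---------------------------------------------------------------------------
# variability indices

def _turning_points(glucose: np.ndarray) -> list[float]:
    """Values of alternating interior local extrema (plateaus collapsed)."""
    v = [float(glucose[0])] if len(glucose) else []
    for x in glucose[1:]:
        if float(x) != v[-1]:
            v.append(float(x))
    tps = []
    for i in range(1, len(v) - 1):
        if (v[i] - v[i - 1]) * (v[i + 1] - v[i]) < 0:
            tps.append(v[i])
    return tps


def baghurst_amplitudes(glucose: np.ndarray, threshold: float) -> list[float]:
    """Amplitudes of the excursions retained by Baghurst elimination.

    Starting from the alternating turning points of the series, the
    smallest adjacent-pair amplitude is located; while it does not exceed
    ``threshold`` that pair of turning points is deleted (ties broken by
    earliest time) and the amplitudes re-scanned.  Deleting an adjacent
    pair preserves alternation, so the loop terminates with every retained
    swing exceeding the threshold.
    """
    tps = _turning_points(np.asarray(glucose, dtype=float))
    while len(tps) >= 2:
        amps = np.abs(np.diff(tps))
        j = int(np.argmin(amps))
        if amps[j] > threshold:
            break
        del tps[j : j + 2]
    if len(tps) < 2:
        return []
    return [abs(b - a) for a, b in zip(tps, tps[1:])]


def mage(trace: GlucoseTrace, magedef: str = "1sd") -> float:
    """Mean amplitude of glycemic excursions (Baghurst's algorithm).

    Keeps excursions whose amplitude exceeds k x SD of the whole trace
    (k = 1, 1.5 or 2 per ``magedef``) and averages the retained
    inter-turning-point amplitudes, ascending and descending limbs alike.
    Returns NaN when no excursion qualifies.
    """
    k = _MAGE_K[magedef]
    if len(trace) < 4:
        return float("nan")
    sd = float(np.std(trace.glucose, ddof=1))
    if sd == 0:
        return float("nan")
    amps = baghurst_amplitudes(trace.glucose, k * sd)
    if not amps:
        return float("nan")
    return float(np.mean(amps))


def _grid_index(trace: GlucoseTrace, interval: float) -> np.ndarray:
    t_s = trace.times.asi8 / 1e9
    return np.rint((t_s - t_s[0]) / (interval * 60)).astype(np.int64)


def conga(trace: GlucoseTrace, n_hours: int = 1,
          interval: float | None = None) -> float:
    """Continuous overall net glycemic action.

    Sample SD of the differences g(t) - g(t - n hours) over every reading
    with a partner exactly n hours earlier (matched by grid position, so
    cleaned traces with removed chunks pair correctly).  NaN when fewer
    than two pairs exist.
    """
    if interval is None:
        interval = infer_interval(trace)
    lag = int(round(n_hours * 60 / interval))
    if lag < 1:
        return float("nan")
    idx = _grid_index(trace, interval)
    pos = {int(i): k for k, i in enumerate(idx)}
    diffs = [
        trace.glucose[k] - trace.glucose[pos[int(i) - lag]]
        for k, i in enumerate(idx)
        if int(i) - lag in pos
    ]
    if len(diffs) < 2:
        return float("nan")
    return float(np.std(diffs, ddof=1))


def modd(trace: GlucoseTrace, interval: float | None = None) -> float:
    """Mean of daily differences: mean |g(t) - g(t - 24 h)| over clock
    times present on consecutive days (grid-matched).  NaN below 24 h."""
    if interval is None:
        interval = infer_interval(trace)
    lag = int(round(1440 / interval))
    idx = _grid_index(trace, interval)
    pos = {int(i): k for k, i in enumerate(idx)}
    diffs = [
        abs(trace.glucose[k] - trace.glucose[pos[int(i) - lag]])
        for k, i in enumerate(idx)
        if int(i) - lag in pos
    ]
    if not diffs:
        return float("nan")
    return float(np.mean(diffs))


def bgi(trace: GlucoseTrace) -> tuple[float, float]:
    """Kovatchev low and high blood glucose indices (LBGI, HBGI).

    The mg/dL symmetrization f(g) = 1.509 x ((ln g)^1.084 - 5.381) maps
    the skewed glucose scale onto a symmetric risk space; readings below
    the neutral point (~112.5 mg/dL) contribute 10 f^2 to LBGI, readings
    above it contribute 10 f^2 to HBGI.
    """
    g = trace.glucose
    if len(g) == 0 or (g <= 0).any():
        raise ValueError("glucose must be positive mg/dL")
    f = 1.509 * (np.log(g) ** 1.084 - 5.381)
    risk = 10.0 * f**2
    lbgi = float(np.mean(np.where(f < 0, risk, 0.0)))
    hbgi = float(np.mean(np.where(f > 0, risk, 0.0)))
    return lbgi, hbgi


# ---------------------------------------------------------------------------
# orchestration

def _fmt(threshold) -> str:
    return str(int(threshold)) if float(threshold).is_integer() else str(threshold)


def summary_columns(config: MetricsConfig | None = None) -> list[str]:
    """Ordered output column names for one summary row."""
    config = config or MetricsConfig()
    cols = [
        "subject_id", "percent_cgm_wear", "average_sensor", "estimated_a1c",
        "gmi", "q1_sensor", "median_sensor", "q3_sensor", "standard_deviation",
        "cv", "min_sensor", "max_sensor",
    ]
    for t in config.over_thresholds:
        f = _fmt(t)
        cols += [f"excursions_over_{f}", f"min_spent_over_{f}",
                 f"percent_time_over_{f}", f"avg_excur_over_{f}_per_day"]
    for u in config.under_thresholds:
        f = _fmt(u)
        cols += [f"min_spent_under_{f}", f"percent_time_under_{f}"]
    cols += ["min_spent_70_180", "percent_time_70_180"]
    for label in ("daytime", "nighttime"):
        cols += [f"{label}_{k}" for k in ("mean", "min", "max", "sd", "auc")]
    cols += ["auc", "r_mage", "j_index", "conga", "modd", "lbgi", "hbgi"]
    return cols


def summarize(trace: GlucoseTrace, config: MetricsConfig | None = None) -> dict:
    """Compute the full summary-variable row for one subject."""
    config = config or MetricsConfig()
    if len(trace) < 2:
        raise ValueError(f"{trace.subject_id}: need >= 2 samples to summarize")
    interval = infer_interval(trace)
    stats = basic_stats(trace, cv_percent=config.cv_percent)
    mean, sd = stats["average_sensor"], stats["standard_deviation"]
    lbgi, hbgi = bgi(trace)
    aucs = auc_trapezoid(trace, config)
    row: dict = {
        "subject_id": trace.subject_id,
        "percent_cgm_wear": percent_cgm_wear(trace, interval),
        **stats,
        "estimated_a1c": estimated_a1c(mean),
        "gmi": gmi(mean),
        **time_metrics(trace, config, interval),
        **excursions(trace, config, interval),
        **daynight_stats(trace, config),
        **aucs,
        "r_mage": mage(trace, config.magedef),
        "j_index": j_index(mean, sd, config.j_index_constant),
        "conga": conga(trace, config.conga_hours, interval),
        "modd": modd(trace, interval),
        "lbgi": lbgi,
        "hbgi": hbgi,
    }
    return {c: row[c] for c in summary_columns(config)}
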