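"""Aggregate daily overlay (ADO) and ambulatory glucose profile reports.

All subjects' readings are pooled by time of day on a 10-minute grid (144
bins), summarized as 5/25/50/75/95th percentile curves smoothed with
Tukey running medians, and plotted three ways: the percentile-band AGP,
a loess-smoothed aggregate mean over every raw point, and per-subject
loess curves.  The clock is treated as circular for the running-median
smoother so midnight is not an artificial endpoint.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import GlucoseTrace

GRID_MINUTES = np.arange(0, 1440, 10)
N_BINS = len(GRID_MINUTES)  # 144
_PCTL = (5, 25, 50, 75, 95)


@dataclass
class PlotConfig:
    """Axis range and smoother settings for the report plots."""

    yaxis_min: float = 0.0
    yaxis_max: float = 400.0
    loess_span: float = 0.3
    loess_degree: int = 2

    def __post_init__(self) -> None:
        if self.yaxis_min >= self.yaxis_max:
            raise ValueError("yaxis_min must be < yaxis_max")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")


@dataclass
class AGPCurve:
    """Percentile summaries per 10-minute clock bin."""

    grid: np.ndarray
    p05: np.ndarray
    p25: np.ndarray
    p50: np.ndarray
    p75: np.ndarray
    p95: np.ndarray
    n_per_bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clock_minute": self.grid,
                "p05": self.p05,
                "p25": self.p25,
                "p50": self.p50,
                "p75": self.p75,
                "p95": self.p95,
                "n": self.n_per_bin,
            }
        )


def clock_bin(minutes: np.ndarray) -> np.ndarray:
    """Nearest 10-minute bin index, rounding halves up; 23:57 wraps to 00:00."""
    return (np.floor(np.asarray(minutes, dtype=float) / 10.0 + 0.5).astype(int)
            % N_BINS)


def bin_to_grid(traces) -> tuple[list[np.ndarray], np.ndarray]:
    """Pool every subject's readings into 144 time-of-day bins."""
    pools: list[list[float]] = [[] for _ in range(N_BINS)]
    for tr in traces:
        for b, g in zip(clock_bin(tr.clock_minutes), tr.glucose):
            pools[b].append(float(g))
    arrays = [np.asarray(p, dtype=float) for p in pools]
    counts = np.array([len(p) for p in arrays])
    return arrays, counts


def tukey_smooth(x: np.ndarray, circular: bool = True) -> np.ndarray:
    """Tukey 3R smoothing: running medians of 3 repeated to a fixed point.

    With ``circular`` the first and last points are neighbours (clock time
    wraps); otherwise endpoints are left unchanged.  NaN entries (empty
    bins) are ignored inside each window, which fills isolated holes with
    the median of their neighbours.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return x.copy()
    cur = x.copy()
    for _ in range(2 * len(x)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            if circular:
                stack = np.vstack([np.roll(cur, 1), cur, np.roll(cur, -1)])
                new = np.nanmedian(stack, axis=0)
            else:
                new = cur.copy()
                stack = np.vstack([cur[:-2], cur[1:-1], cur[2:]])
                new[1:-1] = np.nanmedian(stack, axis=0)
        if np.array_equal(new, cur, equal_nan=True):
            break
        cur = new
    return cur


def percentile_curves(pools, counts=None, smooth: bool = True) -> AGPCurve:
    """Per-bin 5/25/50/75/95 percentiles, Tukey-smoothed and re-ordered.

    Running medians of the five series independently can let curves cross
    by a hair; any post-smoothing crossing is repaired by sorting the five
    values at that grid point.
    """
    if counts is None:
        counts = np.array([len(p) for p in pools])
    curves = np.full((len(_PCTL), N_BINS), np.nan)
    for b, pool in enumerate(pools):
        if len(pool):
            curves[:, b] = np.percentile(pool, _PCTL)
    if smooth:
        curves = np.vstack([tukey_smooth(c, circular=True) for c in curves])
        curves = np.sort(curves, axis=0)
    return AGPCurve(GRID_MINUTES.copy(), *curves, np.asarray(counts))


def loess_curve(x: np.ndarray, y: np.ndarray, span: float = 0.3,
                degree: int = 2, grid: np.ndarray | None = None) -> np.ndarray:
    """Local polynomial regression with tricube weights on a fixed grid.

    At each grid point the nearest ``ceil(span * n)`` observations are fit
    with a weighted degree-``degree`` polynomial and the fit evaluated at
    the point.  Degree 2 reproduces quadratics (hence lines and constants)
    exactly when the window spans the data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = GRID_MINUTES.astype(float)
    n = len(x)
    if n == 0:
        raise ValueError("no points to smooth")
    q = min(n, max(int(np.ceil(span * n)), degree + 1))
    fitted = np.empty(len(grid))
    for k, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argpartition(d, q - 1)[:q] if q < n else np.arange(n)
        dmax = d[idx].max()
        if dmax > 0:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        else:
            w = np.ones(q)
        if w.sum() <= 0:
            w = np.ones(q)
        t = x[idx] - x0
        design = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        fitted[k] = coef[0]
    return fitted


# ---------------------------------------------------------------------------
# rendering

def _pool_points(traces):
    mins = np.concatenate([tr.clock_minutes for tr in traces])
    gluc = np.concatenate([tr.glucose for tr in traces])
    return mins, gluc


def _hours(minutes):
    return np.asarray(minutes, dtype=float) / 60.0


def _decorate(ax, config: PlotConfig, title: str) -> None:
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 3))
    ax.set_ylim(config.yaxis_min, config.yaxis_max)
    ax.set_xlabel("Time of day (h)")
    ax.set_ylabel("Sensor glucose (mg/dL)")
    ax.set_title(title)


def plot_percentile_overlay(curve: AGPCurve, config: PlotConfig | None = None):
    """Median line with IQR and 5-95% bands by time of day."""
    import matplotlib.pyplot as plt

    config = config or PlotConfig()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    h = _hours(curve.grid)
    ax.fill_between(h, curve.p05, curve.p95, alpha=0.25, label="5-95%")
    ax.fill_between(h, curve.p25, curve.p75, alpha=0.45, label="IQR")
    ax.plot(h, curve.p50, lw=2, label="median")
    ax.legend(loc="upper right")
    _decorate(ax, config, "Aggregate daily overlay (Tukey smoothing)")
    return fig


def plot_loess_overlay(traces, config: PlotConfig | None = None):
    """All raw readings with a loess-smoothed aggregate mean."""
    import matplotlib.pyplot as plt

    config = config or PlotConfig()
    mins, gluc = _pool_points(traces)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(_hours(mins), gluc, ".", ms=2, alpha=0.2, color="gray")
    fit = loess_curve(mins, gluc, config.loess_span, config.loess_degree)
    ax.plot(_hours(GRID_MINUTES), fit, lw=2, color="C0", label="loess mean")
    ax.legend(loc="upper right")
    _decorate(ax, config, "Aggregate daily overlay (loess smoothing)")
    return fig


def plot_subject_loess(traces, config: PlotConfig | None = None):
    """One loess curve per subject, colour-coded."""
    import matplotlib.pyplot as plt

    config = config or PlotConfig()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for tr in traces:
        fit = loess_curve(tr.clock_minutes, tr.glucose,
                          config.loess_span, config.loess_degree)
        ax.plot(_hours(GRID_MINUTES), fit, lw=1.5, label=str(tr.subject_id))
    ax.legend(loc="upper right", fontsize=7)
    _decorate(ax, config, "Daily overlay per subject (loess smoothing)")
    return fig


def render_reports(traces, output_dir, config: PlotConfig | None = None) -> dict:
    """Write the three report images plus the percentile-curve CSV.

    Returns a mapping of artifact name to written path.
    """
    import matplotlib.pyplot as plt

    traces = list(traces)
    if not traces:
        raise ValueError("no traces to report on")
    config = config or PlotConfig()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    pools, counts = bin_to_grid(traces)
    curve = percentile_curves(pools, counts)
    paths = {}
    for name, fig in (
        ("agp_tukey", plot_percentile_overlay(curve, config)),
        ("agp_loess", plot_loess_overlay(traces, config)),
        ("agp_by_subject", plot_subject_loess(traces, config)),
    ):
        p = output_dir / f"{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[name] = p
    csv_path = output_dir / "agp_curves.csv"
    curve.to_frame().to_csv(csv_path, index=False)
    paths["agp_curves"] = csv_path
    return paths
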