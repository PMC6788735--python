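# Methods

This note records the models, conventions and numerical choices behind
`cgmkit`, in the order data flows through the package.

## Canonical representation

A `GlucoseTrace` holds one subject's sensor glucose series: strictly
increasing timestamps at second precision and strictly positive glucose in
mg/dL. Sensor dropouts are represented as timestamp jumps, never as null
rows, so every stored value is a real reading. mg/dL is the canonical unit
throughout (every formula below is stated in mg/dL); mmol/L exports are
rejected rather than silently converted.

The interchange format is a three-column CSV — `subjectid`, `timestamp`,
`sensorglucose` — with the subject id in the first data cell only. Glucose
is written with shortest-round-trip float formatting, so
`read_clean(write_clean(t)) == t` exactly.

Device dialects are recognized by header keywords: Dexcom by a
`Glucose Value (mg/dL)` column, Libre by `Historic Glucose (mg/dL)`,
CareLink by `Sensor Glucose (mg/dL)` together with `ISIG Value`, iPro 2 by
`Sensor Glucose (mg/dL)` with an `iPro` device line, and Diasend by a
`Diasend` line with a `Time`/`mg/dL` header. The platforms publish no
stable schemas, so these signatures are this package's contract; the
synthetic module emits exactly these layouts, which is what makes the
detection/parsing closure testable offline. Ambiguous day/month timestamps
are resolved month-first (US-market exports). Duplicate timestamps keep the
first occurrence (deterministic and order-stable); rows without numeric
glucose (calibrations, events) are dropped.

## Cleaning

The nominal sampling interval is the *modal* successive-timestamp
difference (robust to gaps; ties resolve to the denser cadence). A *gap*
is any successive difference strictly greater than that interval; a run of
k missing readings is one gap of (k+1)·interval minutes.

With `gapfill` on, every gap no longer than `maximumgap` (default 20 min)
is filled by linear interpolation on the nominal grid continued from the
gap's left edge; a final partial step shorter than the interval is not
inserted. Filled values are convex combinations of the bounding readings
by construction. A gap of exactly `maximumgap` is on the fillable side, so
the fill and remove rules partition all gaps.

With `removegaps` on, the trace is partitioned into consecutive 24-hour
chunks anchored at the subject's *first sample* (not midnight — this keeps
day and night equally represented for any start time, the balance that
day/night AUC comparisons rely on). Any chunk overlapped by a remaining
gap longer than `maximumgap` is deleted whole. A trailing chunk shorter
than 24 h is treated like any other chunk by default, so cleaning a
gapless trace is the identity; `drop_partial_days=True` removes it for
strict day/night balance. Removing an *interior* chunk necessarily leaves
a seam of (whole days + one interval) between surviving samples; callers
computing AUC should be aware of it (below).

## Summary variables

* **percent_cgm_wear** = 100 · n_readings / (⌊span/interval⌋ + 1).
* **Distribution**: mean, type-7 quartiles (linear interpolation between
  order statistics, R's default), sample SD (n−1), CV = SD/mean reported
  as a ratio (a percent variant is a config flag), min, max.
* **estimated_a1c** (%) = (46.7 + mean)/28.7; **gmi** (%) =
  3.31 + 0.02392·mean; **j_index** = 0.324·(mean + SD)². The J-index
  constant is exposed (`j_index_constant`) because 0.324 is the mmol/L
  literature constant; the printed mg/dL form is implemented as-is.
* **Time in bands**: each reading contributes one nominal interval. "Over
  T" means glucose ≥ T, "under U" means glucose ≤ U, in-range is 70–180
  inclusive — the conventional printed definitions, which deliberately
  double-count a reading sitting exactly on a cutoff. `time_in_band`
  exposes strict bounds; strictly-above-180 + strictly-below-70 +
  inclusive-70–180 partitions wear time exactly.
* **Excursions**: maximal runs of consecutive readings at/beyond a
  threshold whose duration (run length × interval) meets the gate —
  35 min above, 10 min below by default. Per-day averages divide by wear
  time in days (n·interval/1440).
* **AUC**: trapezoidal rule over all successive pairs, mg·min/dL. A pair
  straddling the day/night boundary belongs to its left sample's window,
  so daytime + nighttime AUC = total exactly. Day defaults to
  [06:00, 22:00). Interior day-removal seams contribute one long
  trapezoid; prefer traces whose removed chunks are at the edges when AUC
  matters.
* **MAGE** (Baghurst): collapse plateaus; take the alternating interior
  turning points; repeatedly find the smallest adjacent-pair amplitude
  (ties: earliest) and, while it does not *exceed* k·SD of the whole trace
  (k = 1, 1.5, 2 via `magedef`), delete that pair — deleting an adjacent
  pair preserves alternation, so the loop terminates with every retained
  swing exceeding the gate. MAGE is the mean of the retained amplitudes,
  ascending and descending limbs counted once each; no qualifying
  excursion gives NaN, never 0. Monotone or constant series have no
  turning points → NaN.
* **CONGA(n)**: sample SD of g(t) − g(t − n h) over readings with a
  partner exactly n hours earlier, matched by grid position relative to
  the first sample (so chunk-removed traces pair correctly). **MODD**:
  mean |g(t) − g(t − 24 h)| grid-matched the same way; NaN below 24 h of
  span.
* **LBGI/HBGI** (Kovatchev, mg/dL constants): f(g) = 1.509·((ln g)^1.084 −
  5.381); risk = 10·f²; LBGI averages risk over readings with f < 0, HBGI
  over f > 0. The neutral glucose (f = 0) is ≈ 112.5 mg/dL.

Output columns use the REDCap-compatible names (`percent_cgm_wear`,
`average_sensor`, …, `r_mage`, `conga`, `modd`, `lbgi`, `hbgi`), one row
per subject keyed by `subject_id`.

## Aggregate daily overlay

All subjects' readings are pooled by clock time rounded to the nearest
10-minute mark (half-up: 06:05 → 06:10; 23:58 wraps to 00:00), giving 144
bins. Per-bin 5/25/50/75/95th percentiles are smoothed with Tukey running
medians in the 3R variant — repeated median-of-3 to a fixed point, the
simplest member of the family — treating the day as circular so midnight
is not an endpoint artifact. Empty bins (NaN) are ignored within each
3-window, which fills isolated holes with their neighbours' median.
Because the five series are smoothed independently, a crossing of a hair's
width is possible afterwards; the five values at any such grid point are
re-sorted. Running medians are selections, so smoothing never leaves the
range of its input.

The loess overlays use local quadratic regression with tricube weights:
at each grid point the nearest ⌈span·n⌉ observations (span default 0.3
over clock minutes, exposed in `PlotConfig` since no reference value
exists) are fit by weighted least squares and evaluated at the point.
Degree 2 reproduces quadratics exactly when the window spans the data,
which is the property the tests pin. Loess is *not* circular at midnight;
the Tukey smoother is — both choices are package conventions, not claims
about any other implementation.

Plots default to a 0–400 mg/dL y-axis (overridable, e.g. 70–300).

## Synthetic traces

The generator composes glucose(t) = baseline + circadian + meals + noise:

* baseline_mean (default 120 mg/dL — a well-managed T1D/prediabetes range
  that keeps the default trace clear of the 40 mg/dL sensor floor);
* a sinusoid of amplitude 15 mg/dL peaking at 16:00 with its nadir at
  04:00 (dawn-phenomenon-like timing);
* `n_meals_per_day` triangular excursions (default 3 × 60 mg/dL over 2 h)
  at fixed clock times evenly spaced 07:00–19:00 — triangles rather than
  biophysical responses so that peak amplitude and timing are *analytic
  truth* for MAGE and excursion tests;
* Gaussian sensor noise (default SD 10 mg/dL, within the MARD-equivalent
  range of current sensors).

Defaults simulate 29 days at the 5-minute Dexcom/iPro cadence (8352
readings; three subjects ≈ 25,000 readings, the pool size used for the
aggregate-overlay report). Gaps are injected by deleting samples strictly
inside stated windows, so the resulting timestamp jump equals the stated
duration. Glucose is clipped at a 40 mg/dL sensor floor — the one
nonlinearity that can perturb the analytic truth; test configurations stay
clear of it. A fixed seed gives byte-identical traces.

What the simulator does *not* emulate: sensor drift and calibration error,
autocorrelated noise, glucose–insulin dynamics, irregular meal timing, or
compression-low artifacts. Passing tests therefore demonstrate
correctness of the *computations* on realistic-scale data, not robustness
to every pathology of clinical exports.

## Problem sizes and tolerances

Oracle-equivalence tests run the brute-force checks on hundreds of random
traces of ≤ 50–600 points (exact agreement, 1e-12 relative, since both
sides do the same arithmetic in different code); closed-form checks
(triangle-wave MAGE, linear loess recovery) use 1e-8/1e-9 absolute.
Aggregate-overlay properties run on the full three-subject, ~25,000-value
simulation; noise-recovery checks use ~8,000 readings, where the sampling
error of an SD is ≈ 0.8%, comfortably inside the 3% assertion. The whole
suite completes in a few seconds on one core.

## Known limitations

* Only glucose rows are read from exports; insulin, carb, event and
  calibration records are ignored.
* mmol/L files are rejected, not converted.
* Header signatures are this package's own; a vendor layout change
  requires a new signature, and real-export parsing beyond the documented
  layouts is untested here.
* Excursion counting by maximal threshold runs can differ by ±1 from
  proprietary counters whose (unpublished) algorithms differ in boundary
  handling.
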