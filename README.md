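# cgmkit

Cleaning, glycemic summary metrics, and ambulatory glucose profile (AGP)
reports for continuous glucose monitor (CGM) data.

CGM devices sample interstitial glucose every 5–15 minutes for days to
weeks, but each vendor exports its history in a different text layout and
reports a different, limited set of summary statistics. `cgmkit` gives
clinical researchers one reproducible path from a directory of raw exports
to a standard variable set: it detects the originating platform, converts
everything to a common three-column format, repairs sensor dropouts, and
computes the descriptive metrics used in diabetes research — time in
range, estimated HbA1c and GMI, MAGE, CONGA, MODD, the J-index, and the
Kovatchev low/high blood-glucose risk indices — plus the percentile-band
daily-overlay plots of the standard AGP report. A seeded synthetic-trace
generator makes the entire pipeline testable without any clinical data.

## The metrics

For a cleaned trace g(t) in mg/dL sampled at nominal interval Δ:

- **Time in range**: each reading contributes Δ minutes to every band its
  value falls in; "over T" means g ≥ T, "under U" means g ≤ U, in-range is
  70–180 mg/dL inclusive. **Excursions** are maximal runs beyond a
  threshold lasting ≥ 35 min (above) or ≥ 10 min (below).
- **eA1c** = (46.7 + mean)/28.7; **GMI** = 3.31 + 0.02392·mean;
  **J-index** = 0.324·(mean + SD)².
- **MAGE** (Baghurst): from the alternating turning points of the series,
  iteratively delete the smallest adjacent swing until every retained
  amplitude exceeds k·SD (k = 1, 1.5 or 2); MAGE is the mean retained
  amplitude.
- **CONGA(n)** = SD of g(t) − g(t − n h); **MODD** = mean |g(t) − g(t − 24 h)|,
  both grid-matched.
- **LBGI/HBGI**: with f(g) = 1.509·((ln g)^1.084 − 5.381) and risk 10·f²,
  LBGI averages risk where f < 0 and HBGI where f > 0.
- **AUC**: trapezoidal rule, with daytime/nighttime splits over a
  configurable clock window (default 06:00–22:00).

Cleaning linearly interpolates gaps ≤ 20 min (configurable) and removes
whole 24-hour chunks — anchored at the subject's first sample — that
contain longer gaps, keeping day and night equally represented. Full
definitions and conventions are in [docs/methods.md](docs/methods.md).

## Supported export dialects

Detection is by header signature (vendors publish no stable schemas; these
signatures are this package's contract, and the built-in simulator writes
fixtures in exactly these layouts):

| dialect | signature |
|---|---|
| `dexcom` | `Glucose Value (mg/dL)` column |
| `libre` | `Historic Glucose (mg/dL)` column (tab-separated) |
| `carelink` | `Sensor Glucose (mg/dL)` + `ISIG Value` columns |
| `ipro2` | `Sensor Glucose (mg/dL)` column + `iPro` device line |
| `diasend` | `Diasend` line + `Time`/`mg/dL` header (tab-separated) |
| `generic3col` | header `subjectid,timestamp,sensorglucose` |

All glucose is mg/dL; mmol/L exports are rejected, not converted.

## Worked example

```python
from cgmkit import CleanConfig, clean, summarize
from cgmkit.synthetic import SimConfig, simulate_trace

cfg = SimConfig(n_days=7, noise_sd=10, seed=42,
                gap_spec=((700.0, 15.0), (3000.0, 60.0)))
trace, _ = simulate_trace(cfg, subject_id="S001")   # 2003 readings
cleaned, report = clean(trace, CleanConfig())
# report: 2 readings interpolated (the 15-min gap), 1 day removed
# (the 60-min gap), 1728 readings survive
row = summarize(cleaned)
```

prints, for this seed:

```
      percent_cgm_wear: 85.714
        average_sensor: 126.969
         estimated_a1c: 6.051
                   gmi: 6.347
    standard_deviation: 22.810
                    cv: 0.180
   percent_time_70_180: 96.817
                r_mage: 39.504
                 conga: 25.667
                  modd: 11.329
                  lbgi: 0.131
                  hbgi: 1.305
```

Reading the row: the subject wore the sensor 85.7% of the analysed span
(one full day was discarded around the 60-minute dropout), mean glucose
127 mg/dL corresponds to an estimated HbA1c of 6.05%, 96.8% of wear time
was in the 70–180 mg/dL target range, and the mean qualifying glycemic
swing (MAGE) was 39.5 mg/dL. LBGI ≈ 0.13 indicates minimal hypoglycemic
risk; HBGI ≈ 1.3 mild hyperglycemic exposure.

### Command line

```bash
cgmkit simulate exports/ --subjects 3 --days 29 --dialect dexcom --seed 1
cgmkit clean exports/ cleaned/                    # fill ≤20-min gaps, drop gap days
cgmkit clean exports/ cleaned/ --no-removegaps --gapfill --maximumgap 30
cgmkit variables cleaned/ out/                    # one summary row per subject
cgmkit variables cleaned/ out/ --daystart 8 --dayend 23 --magedef 2sd
cgmkit report cleaned/ report/ --yaxis 70 300     # AGP plots + percentile CSV
```

`clean` writes one `<subject_id>.csv` per input plus a run log;
`variables` writes `cgm_summary.csv` with REDCap-compatible column names;
`report` writes the Tukey-smoothed percentile overlay, the loess overlay
over all points, the per-subject loess plot, and `agp_curves.csv` with the
5/25/50/75/95th percentile bands on the 10-minute clock grid.

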