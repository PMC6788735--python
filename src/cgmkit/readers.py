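"""Device-export detection and canonicalization.

Commercial CGM platforms export glucose history in mutually incompatible
text layouts.  This module detects which platform produced a file from its
header signature, extracts the (timestamp, glucose) rows, and canonicalizes
them to a :class:`~cgmkit.trace.GlucoseTrace`.  The cleaned three-column
interchange format (subject id, timestamp, sensor glucose) written by
:func:`write_clean` is what every downstream stage consumes.

Header signatures are defined by this package (the platforms do not publish
stable schemas); the synthetic module emits fixtures carrying exactly these
signatures, so detection and parsing are round-trip tested without any
proprietary export.  All dialects are parsed as mg/dL; mmol/L exports are
rejected rather than silently converted.
"""
from __future__ import annotations

import csv
import logging
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import GlucoseTrace

logger = logging.getLogger(__name__)

DIALECTS = ("dexcom", "libre", "ipro2", "carelink", "diasend", "generic3col")

GENERIC_HEADER = ("subjectid", "timestamp", "sensorglucose")

#: Human-readable description of each dialect's header signature.
SIGNATURES = {
    "generic3col": "header row 'subjectid,timestamp,sensorglucose'",
    "dexcom": "a 'Glucose Value (mg/dL)' column header",
    "libre": "a 'Historic Glucose (mg/dL)' column header",
    "carelink": "'Sensor Glucose (mg/dL)' plus 'ISIG Value' column headers",
    "ipro2": "a 'Sensor Glucose (mg/dL)' column header with an 'iPro' device line",
    "diasend": "a 'Diasend' export line with a 'Time<TAB>mg/dL' header",
}

# Timestamp conventions per dialect.  Ambiguous day/month orders are
# resolved month-first (US-market exports).
_TS_FORMATS = {
    "generic3col": ("%Y-%m-%d %H:%M:%S", "%Y-%m-%d %H:%M"),
    "dexcom": ("%Y-%m-%dT%H:%M:%S", "%Y-%m-%d %H:%M:%S"),
    "libre": ("%m/%d/%Y %H:%M", "%m/%d/%Y %H:%M:%S"),
    "ipro2": ("%m/%d/%Y %H:%M:%S", "%m/%d/%Y %H:%M"),
    "carelink": ("%m/%d/%Y %H:%M:%S", "%m/%d/%Y %H:%M"),
    "diasend": ("%m/%d/%Y %H:%M", "%m/%d/%Y %H:%M:%S"),
}


class DialectError(ValueError):
    """Raised when a file matches no known export signature."""


class ParseError(ValueError):
    """Raised when a recognized file cannot be converted to a trace."""


def _head_lines(path, n: int = 15) -> list[str]:
    with open(path, "r", encoding="utf-8-sig", errors="replace") as fh:
        return [fh.readline() for _ in range(n)]


def detect_dialect(path) -> str:
    """Identify the export dialect of ``path`` from its header signature.

    Raises
    ------
    DialectError
        If no signature matches; the message lists every signature probed.
    """
    lines = [ln for ln in _head_lines(path) if ln.strip()]
    if lines:
        first = [c.strip().lower() for c in lines[0].strip().split(",")]
        if tuple(first) == GENERIC_HEADER:
            return "generic3col"
        blob = "".join(lines)
        if "Glucose Value (mg/dL)" in blob:
            return "dexcom"
        if "Historic Glucose" in blob:
            return "libre"
        if "Sensor Glucose (mg/dL)" in blob and "ISIG" in blob:
            return "carelink"
        if "Sensor Glucose (mg/dL)" in blob and "iPro" in blob:
            return "ipro2"
        if "diasend" in blob.lower():
            return "diasend"
    tried = "; ".join(f"{d}: {s}" for d, s in SIGNATURES.items())
    raise DialectError(f"{path}: unknown dialect (signatures tried — {tried})")


def _parse_ts(text: str, formats, path, rowno: int) -> datetime:
    for fmt in formats:
        try:
            return datetime.strptime(text.strip(), fmt)
        except ValueError:
            continue
    raise ParseError(f"{path}: row {rowno}: unparseable timestamp {text!r}")


def _to_float(cell: str):
    try:
        return float(cell.strip())
    except (ValueError, AttributeError):
        return None


def _assemble(subject_id: str, rows, path) -> GlucoseTrace:
    """Build a trace from (rowno, datetime, glucose) triples.

    Rows are sorted by timestamp (stable, so file order breaks ties) and
    duplicate timestamps keep the first occurrence.  Non-positive glucose
    violates the mg/dL invariant and is a hard error naming the row.
    """
    if not rows:
        raise ParseError(f"{path}: no valid glucose rows found")
    for rowno, _, g in rows:
        if g <= 0:
            raise ParseError(f"{path}: row {rowno}: non-positive glucose {g!r}")
    order = sorted(range(len(rows)), key=lambda i: rows[i][1])
    if order != list(range(len(rows))):
        logger.warning("%s: timestamps out of order; rows re-sorted", path)
    seen: set = set()
    kept = []
    dropped = 0
    for i in order:
        rowno, ts, g = rows[i]
        if ts in seen:
            dropped += 1
            continue
        seen.add(ts)
        kept.append((ts, g))
    if dropped:
        logger.warning("%s: dropped %d duplicate-timestamp rows (first kept)", path, dropped)
    times = pd.DatetimeIndex([ts for ts, _ in kept])
    glucose = np.array([g for _, g in kept], dtype=float)
    return GlucoseTrace(subject_id, times, glucose)


def _rows_csv(path, delimiter: str = ",") -> list[list[str]]:
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        return list(csv.reader(fh, delimiter=delimiter))


def _find_header(raw, needle: str):
    for i, row in enumerate(raw):
        if any(needle in cell for cell in row):
            return i, row
    raise ParseError(f"no header row containing {needle!r}")


def _col(header, needle: str) -> int:
    for j, cell in enumerate(header):
        if needle in cell:
            return j
    raise ParseError(f"no column containing {needle!r}")


def _parse_dexcom(path):
    raw = _rows_csv(path)
    hi, header = _find_header(raw, "Glucose Value (mg/dL)")
    t_col = _col(header, "Timestamp")
    g_col = _col(header, "Glucose Value (mg/dL)")
    rows = []
    for rowno, row in enumerate(raw[hi + 1 :], start=hi + 2):
        if len(row) <= max(t_col, g_col):
            continue
        g = _to_float(row[g_col])
        if g is None:
            continue  # calibration / event rows carry no glucose
        rows.append((rowno, _parse_ts(row[t_col], _TS_FORMATS["dexcom"], path, rowno), g))
    return None, rows


def _parse_libre(path):
    raw = _rows_csv(path, delimiter="\t")
    subject = raw[0][0].strip() if raw and raw[0] else None
    hi, header = _find_header(raw, "Historic Glucose")
    t_col = _col(header, "Time")
    g_col = _col(header, "Historic Glucose")
    rows = []
    for rowno, row in enumerate(raw[hi + 1 :], start=hi + 2):
        if len(row) <= max(t_col, g_col):
            continue
        g = _to_float(row[g_col])
        if g is None:
            continue
        rows.append((rowno, _parse_ts(row[t_col], _TS_FORMATS["libre"], path, rowno), g))
    return subject or None, rows


def _medtronic_preamble_id(raw) -> str | None:
    for row in raw[:10]:
        if len(row) >= 2 and row[0].strip().lower() == "patient id":
            return row[1].strip()
    return None


def _parse_ipro2(path):
    raw = _rows_csv(path)
    subject = _medtronic_preamble_id(raw)
    hi, header = _find_header(raw, "Sensor Glucose (mg/dL)")
    t_col = _col(header, "Timestamp")
    g_col = _col(header, "Sensor Glucose (mg/dL)")
    rows = []
    for rowno, row in enumerate(raw[hi + 1 :], start=hi + 2):
        if len(row) <= max(t_col, g_col):
            continue
        g = _to_float(row[g_col])
        if g is None:
            continue
        rows.append((rowno, _parse_ts(row[t_col], _TS_FORMATS["ipro2"], path, rowno), g))
    return subject, rows


def _parse_carelink(path):
    raw = _rows_csv(path)
    subject = _medtronic_preamble_id(raw)
    hi, header = _find_header(raw, "Sensor Glucose (mg/dL)")
    d_col = _col(header, "Date")
    t_col = _col(header, "Time")
    g_col = _col(header, "Sensor Glucose (mg/dL)")
    rows = []
    for rowno, row in enumerate(raw[hi + 1 :], start=hi + 2):
        if len(row) <= max(d_col, t_col, g_col):
            continue
        g = _to_float(row[g_col])
        if g is None:
            continue
        stamp = f"{row[d_col].strip()} {row[t_col].strip()}"
        rows.append((rowno, _parse_ts(stamp, _TS_FORMATS["carelink"], path, rowno), g))
    return subject, rows


def _parse_diasend(path):
    raw = _rows_csv(path, delimiter="\t")
    subject = None
    for row in raw[:5]:
        if len(row) >= 2 and row[0].strip().lower() == "name":
            subject = row[1].strip()
    hi, header = _find_header(raw, "mg/dL")
    t_col = _col(header, "Time")
    g_col = _col(header, "mg/dL")
    rows = []
    for rowno, row in enumerate(raw[hi + 1 :], start=hi + 2):
        if len(row) <= max(t_col, g_col):
            continue
        g = _to_float(row[g_col])
        if g is None:
            continue
        rows.append((rowno, _parse_ts(row[t_col], _TS_FORMATS["diasend"], path, rowno), g))
    return subject, rows


_PARSERS = {
    "dexcom": _parse_dexcom,
    "libre": _parse_libre,
    "ipro2": _parse_ipro2,
    "carelink": _parse_carelink,
    "diasend": _parse_diasend,
}


def parse_export(path, dialect: str | None = None) -> GlucoseTrace:
    """Parse a device export into a canonical trace.

    ``dialect`` defaults to :func:`detect_dialect`.  Rows without a numeric
    glucose value (calibrations, events) are dropped; duplicate timestamps
    keep the first occurrence; the subject id comes from the dialect's id
    field when it has one, else the file name stem.
    """
    path = Path(path)
    if dialect is None:
        dialect = detect_dialect(path)
    if dialect == "generic3col":
        return read_clean(path)
    if dialect not in _PARSERS:
        raise DialectError(f"{path}: unsupported dialect {dialect!r}")
    subject, rows = _PARSERS[dialect](path)
    return _assemble(subject or path.stem, rows, path)


def write_clean(trace: GlucoseTrace, path) -> Path:
    """Write the cleaned three-column interchange file.

    Column 1 holds the subject id in its first data cell only; columns 2-3
    are the ISO timestamp (second precision) and the glucose value written
    at full float precision so that :func:`read_clean` inverts exactly.
    """
    if len(trace) == 0:
        raise ValueError(f"refusing to write empty trace {trace.subject_id!r}")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GENERIC_HEADER)
        stamps = trace.times.strftime("%Y-%m-%d %H:%M:%S")
        for i, (ts, g) in enumerate(zip(stamps, trace.glucose)):
            writer.writerow([trace.subject_id if i == 0 else "", ts, repr(float(g))])
    return path


def read_clean(path) -> GlucoseTrace:
    """Inverse of :func:`write_clean`; validates like :func:`parse_export`."""
    path = Path(path)
    raw = _rows_csv(path)
    if not raw or tuple(c.strip().lower() for c in raw[0]) != GENERIC_HEADER:
        raise ParseError(f"{path}: not a three-column interchange file")
    subject = None
    rows = []
    for rowno, row in enumerate(raw[1:], start=2):
        if not row or not any(c.strip() for c in row):
            continue
        if len(row) < 3:
            raise ParseError(f"{path}: row {rowno}: expected 3 columns")
        if subject is None and row[0].strip():
            subject = row[0].strip()
        g = _to_float(row[2])
        if g is None:
            continue
        rows.append((rowno, _parse_ts(row[1], _TS_FORMATS["generic3col"], path, rowno), g))
    return _assemble(subject or path.stem, rows, path)
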