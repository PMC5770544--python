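"""Reading and writing gate-abundance tables, annotations, and reports.

Tables are flat delimited text (comma or tab, auto-detected): the first
column is the sampling time in hours (conventionally named ``time_h``),
every further column a gate label.  Raw cytometry files are deliberately
not parsed - gating happens upstream and this tool starts from gate
abundances.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import (
    COMPOSITION_SUM_TOL,
    DisturbanceAnnotation,
    EcologicalSituation,
    GateAbundanceSeries,
    check_windows_disjoint,
)
from .errors import InputDataError
from .metrics import StabilityReport, online_resilience
from .reference import DeviationTrace

_REPORT_FLOAT_FMT = "%.12g"  # >= 6 significant digits, round-trips to 1e-9 easily


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"input file not found: {path}")
    try:
        # sep=None sniffs comma vs tab (python engine)
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise InputDataError(f"could not parse {path}: {exc}") from exc


def read_gate_table(
    path,
    mode: str = "fractions",
    tolerance: float = COMPOSITION_SUM_TOL,
) -> GateAbundanceSeries:
    """Read a gate-abundance table into a validated, normalized series.

    ``mode="counts"``: rows hold raw per-gate cell counts and are divided
    by their row sums.  ``mode="fractions"``: rows hold relative
    abundances; any row whose sum deviates from 1 by more than *tolerance*
    is rejected (naming the row), the rest are renormalized to sum
    exactly 1.
    """
    return GateAbundanceSeries.from_dataframe(_read_delimited(path), mode=mode, tolerance=tolerance)


def write_gate_table(series: GateAbundanceSeries, path) -> None:
    """Write a series back to a comma-delimited table (first column time_h)."""
    series.to_dataframe().to_csv(path, index=False, float_format=_REPORT_FLOAT_FMT)


def read_disturbances(path) -> List[DisturbanceAnnotation]:
    """Read disturbance annotations (columns: label, kind, onset_h, window_end_h).

    Returns the annotations sorted by onset; overlapping windows are an error.
    """
    df = _read_delimited(path)
    required = {"label", "kind", "onset_h", "window_end_h"}
    missing = required - set(df.columns)
    if missing:
        raise InputDataError(f"disturbance table missing columns: {sorted(missing)}")
    windows = [
        DisturbanceAnnotation(
            label=str(row["label"]),
            kind=str(row["kind"]),
            onset_time=float(row["onset_h"]),
            window_end=float(row["window_end_h"]),
        )
        for _, row in df.iterrows()
    ]
    return check_windows_disjoint(windows)


def write_disturbances(windows, path) -> None:
    rows = [
        {"label": w.label, "kind": w.kind, "onset_h": w.onset_time, "window_end_h": w.window_end}
        for w in windows
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reference_replicates(path) -> np.ndarray:
    """Read a table of replicate compositions (one row per replicate).

    A leading ``time_h`` or ``replicate`` column, if present, is dropped;
    remaining columns are gate abundances, renormalized per row.
    """
    df = _read_delimited(path)
    if df.columns[0] in ("time_h", "replicate", "id"):
        df = df.iloc[:, 1:]
    values = df.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise InputDataError("replicate table must have at least one row")
    if np.any(values < 0) or np.any(~np.isfinite(values)):
        raise InputDataError("replicate table contains negative or non-finite entries")
    sums = values.sum(axis=1)
    if np.any(sums == 0):
        raise InputDataError("replicate table contains an all-zero row")
    return values / sums[:, None]


def validate_series(series: GateAbundanceSeries) -> List[str]:
    """Report every invariant violation of a series (empty list = valid).

    Checked: strictly increasing times, non-negative entries, and rows
    summing to 1 within the standard tolerance.  Each issue names the
    offending row/column.
    """
    issues: List[str] = []
    diffs = np.diff(series.times)
    for i in np.nonzero(diffs <= 0)[0]:
        kind = "duplicate" if diffs[i] == 0 else "non-increasing"
        issues.append(
            f"{kind} times at rows {int(i)} and {int(i) + 1} "
            f"({series.times[i]!r}, {series.times[i + 1]!r})"
        )
    for r, c in np.argwhere(series.abundances < 0):
        issues.append(
            f"negative abundance {series.abundances[r, c]!r} at row {int(r)}, "
            f"gate {series.gate_ids[c]!r}"
        )
    sums = series.abundances.sum(axis=1)
    for r in np.nonzero(np.abs(sums - 1.0) > COMPOSITION_SUM_TOL)[0]:
        issues.append(f"row {int(r)} sums to {sums[r]!r} (should be 1)")
    return issues


# -- stability report files ------------------------------------------------

_NA = "NA"


def _fmt(value) -> str:
    return _NA if value is None else (_REPORT_FLOAT_FMT % value)


def write_stability_report(report: StabilityReport, trace: DeviationTrace, path) -> None:
    """Write one disturbance window's report to a delimited text file.

    The file holds a ``#``-prefixed key=value header block (RS, DS, RL, E,
    metric, reference radius, trace anchors, and the six ecological-
    situation features) followed by CSV data rows with columns time_h,
    deviation, running_max and rl_online.  Undefined properties are
    written as an explicit ``NA`` marker, never as a number.  Values
    round-trip at >= 6 significant digits.
    """
    online = online_resilience(trace)
    lines = []
    header = {
        "window": report.window_label,
        "metric": report.metric,
        "RS": _fmt(report.resistance),
        "DS": _fmt(report.displacement_speed),
        "RL": _fmt(report.resilience),
        "E": _fmt(report.elasticity),
        "resilient": str(report.resilient_flag).lower(),
        "reference_radius": _fmt(report.reference_radius),
        "t_ref": _fmt(trace.t_ref),
        "d_max": _fmt(trace.d_max),
        "t_max": _fmt(trace.t_max),
        "d_end": _fmt(trace.d_end),
        "t_end": _fmt(trace.t_end),
    }
    header.update(
        {f"situation.{k}": v for k, v in report.situation.as_dict().items()}
    )
    for key, value in header.items():
        lines.append(f"# {key}={value}")
    lines.append("time_h,deviation,running_max,rl_online")
    for t, d, m, rl in zip(trace.times, trace.deviations, online.running_max, online.rl_online):
        lines.append(",".join(_REPORT_FLOAT_FMT % v for v in (t, d, m, rl)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_stability_report(path) -> Tuple[dict, pd.DataFrame]:
    """Read back a report file written by :func:`write_stability_report`.

    Returns the header as a dict (numeric values parsed to float, ``NA``
    to None) and the per-sample columns as a DataFrame.
    """
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"report file not found: {path}")
    header: dict = {}
    data_lines: List[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            if key.startswith("situation.") or key in ("window", "metric"):
                header[key] = value
            elif key == "resilient":
                header[key] = value == "true"
            else:
                header[key] = None if value == _NA else float(value)
        elif line.strip():
            data_lines.append(line)
    if not data_lines:
        raise InputDataError(f"report file {path} has no data rows")
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)))
    return header, df
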