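"""Readers and writers for the file formats the tool touches.

Supported formats:

* plain CSV with a header row — one column of RR intervals (ms) or
  instantaneous HR (bpm);
* Polar ProTrainer HRM text exports in RR-recording mode — the ``[HRData]``
  section holds one integer RR interval (ms) per line, other sections are
  tolerated and ignored;
* correction-log CSV with columns ``index, original_value, action,
  replacement_value, method`` plus commented metadata lines carrying the
  source length and exclusion flag.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .series import BeatSeries, CorrectionLog, Edit

__all__ = [
    "read_csv",
    "write_csv",
    "read_hrm",
    "write_hrm",
    "read_log",
    "write_log",
    "read_manual_edits",
]

PathLike = Union[str, Path]


def read_csv(
    path: PathLike,
    unit: str,
    column: Union[str, int, None] = None,
    label: str = "",
) -> BeatSeries:
    """Read a beat series from a CSV file.

    Parameters
    ----------
    path
        CSV file with a header row.
    unit
        Unit of the stored values, ``"bpm"`` or ``"ms"``.
    column
        Column name or 0-based position holding the values; default is the
        first column.

    Raises
    ------
    ValueError
        On an empty file, a missing column, or a non-numeric or non-positive
        entry (the offending row is named).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if column is None:
        col = df.iloc[:, 0]
    elif isinstance(column, int):
        col = df.iloc[:, column]
    else:
        if column not in df.columns:
            raise ValueError(f"{path}: no column named {column!r}")
        col = df[column]
    values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values) | (values <= 0))
    if bad.size:
        row = int(bad[0])
        raise ValueError(
            f"{path}: row {row + 2} has non-numeric or non-positive "
            f"value {col.iloc[row]!r}"
        )
    return BeatSeries(values=values, unit=unit, label=label or path.stem)


def write_csv(series: BeatSeries, path: PathLike) -> None:
    """Write a beat series as a one-column CSV (header = unit name)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([series.unit])
        for v in series.values:
            w.writerow([repr(float(v))])


def read_hrm(path: PathLike, label: str = "") -> BeatSeries:
    """Read RR intervals (ms) from a Polar HRM text export.

    Only the RR-recording dialect is supported: the ``[HRData]`` section must
    hold one integer RR value per line.  Multi-column HRData rows (HRM files
    recorded with speed/cadence/altitude channels) are rejected.

    Raises
    ------
    ValueError
        If the file has no ``[HRData]`` section, a non-integer RR line, or
        multi-column rows.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.strip().lower() == "[hrdata]"
        )
    except StopIteration:
        raise ValueError(f"{path}: no [HRData] section — not an HRM RR export")
    values = []
    for lineno, raw in enumerate(lines[start + 1 :], start=start + 2):
        ln = raw.strip()
        if not ln:
            continue
        if ln.startswith("["):  # next section
            break
        fields = ln.split()
        if len(fields) != 1:
            raise ValueError(
                f"{path}: line {lineno}: multi-column HRData rows are not "
                "supported (expected one RR value in ms per line)"
            )
        try:
            values.append(int(fields[0]))
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: non-integer RR value {ln!r}"
            ) from None
    if not values:
        raise ValueError(f"{path}: [HRData] section is empty")
    return BeatSeries(
        values=np.asarray(values, dtype=float), unit="ms", label=label or path.stem
    )


def write_hrm(series: BeatSeries, path: PathLike) -> None:
    """Write a series as a minimal HRM RR export.

    Values are stored as integer milliseconds (the device records with 1 ms
    accuracy); non-ms series are converted first and values are rounded to
    the nearest integer.
    """
    rr = np.rint(series.to("ms").values).astype(int)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("[Params]\nVersion=106\nMode=3\n\n[HRData]\n")
        fh.write("\n".join(str(int(v)) for v in rr))
        fh.write("\n")


_LOG_COLUMNS = ["index", "original_value", "action", "replacement_value", "method"]


def write_log(log: CorrectionLog, path: PathLike) -> None:
    """Serialize a correction log to CSV (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# source_length={log.source_length}\n")
        fh.write(f"# excluded={log.excluded}\n")
        w = csv.writer(fh)
        w.writerow(_LOG_COLUMNS)
        for e in log.edits:
            w.writerow(
                [
                    e.index,
                    repr(float(e.original_value)),
                    e.action,
                    "" if e.replacement_value is None else repr(float(e.replacement_value)),
                    e.method,
                ]
            )


def read_log(path: PathLike) -> CorrectionLog:
    """Read a correction log written by :func:`write_log`."""
    path = Path(path)
    source_length: Optional[int] = None
    excluded = False
    rows = []
    with path.open() as fh:
        for raw in fh:
            ln = raw.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                key, _, val = ln.lstrip("# ").partition("=")
                if key == "source_length":
                    source_length = int(val)
                elif key == "excluded":
                    excluded = val.strip().lower() == "true"
                continue
            rows.append(ln)
    if source_length is None:
        raise ValueError(f"{path}: missing '# source_length=' metadata line")
    reader = csv.reader(rows)
    header = next(reader, None)
    if header != _LOG_COLUMNS:
        raise ValueError(f"{path}: unexpected log header {header!r}")
    edits = []
    for rec in reader:
        idx, orig, action, repl, method = rec
        edits.append(
            Edit(
                index=int(idx),
                original_value=float(orig),
                action=action,
                replacement_value=float(repl) if repl else None,
                method=method,
            )
        )
    return CorrectionLog(
        edits=tuple(edits), source_length=source_length, excluded=excluded
    )


def read_manual_edits(path: PathLike) -> list[int]:
    """Read a manual-edit CSV of ``index[,reason]`` rows (visual deletions).

    Returns the 0-based beat indices, in file order.  The reason column is
    free text for the analyst's record and is not interpreted.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "index" not in df.columns:
        raise ValueError(f"{path}: manual-edit file needs an 'index' column")
    return [int(i) for i in df["index"]]
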