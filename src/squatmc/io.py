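"""Readers/writers for the motion-capture ecosystem's plain-text formats.

TRC (marker trajectories) and MOT/STO (header + tab-separated time-series
columns) are parsed strictly: malformed headers, label/column mismatches,
non-monotone time and truncated rows raise :class:`~squatmc.errors.ParseError`
naming the offending line, never silently coerce.  Internally everything is
SI (m, N, rad, s); unit conversion (mm, degrees) happens at the file
boundary according to the file's own header.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

_KNOWN_MOTSTO_KEYS = {
    "version", "nrows", "ncolumns", "indegrees", "name", "datatype",
    "opensimversion", "units",
}


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def read_trc(path) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
    """Read a TRC marker file.

    Returns ``(time (F,), markers {label: (F, 3) m}, data_rate)``.
    Coordinates are converted to metres according to the Units field.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated TRC file ({len(lines)} lines)")
    hdr_keys = lines[1].split("\t")
    hdr_vals = lines[2].split("\t")
    if len(hdr_vals) < len(hdr_keys):
        raise ParseError(f"{path}: line 3: header value count does not match line 2")
    hdr = dict(zip(hdr_keys, hdr_vals))
    try:
        n_frames = int(hdr["NumFrames"])
        n_markers = int(hdr["NumMarkers"])
        rate = float(hdr["DataRate"])
        units = hdr["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: line 2-3: malformed TRC header ({exc})") from exc
    to_m = {"mm": 1e-3, "cm": 1e-2, "m": 1.0}.get(units)
    if to_m is None:
        raise ParseError(f"{path}: line 3: unknown Units {units!r}")
    labels = [x for x in lines[3].split("\t")[2:] if x.strip()]
    if len(labels) != n_markers:
        raise ParseError(
            f"{path}: line 4: {len(labels)} marker labels but NumMarkers={n_markers}"
        )
    data_start = 5
    while data_start < len(lines) and not lines[data_start].strip():
        data_start += 1
    rows = []
    for ln in range(data_start, len(lines)):
        if not lines[ln].strip():
            continue
        fields = lines[ln].split("\t")
        expected = 2 + 3 * n_markers
        if len(fields) < expected:
            raise ParseError(
                f"{path}: line {ln + 1}: {len(fields)} columns, expected {expected}"
            )
        try:
            rows.append([float(x) for x in fields[:expected]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln + 1}: non-numeric value ({exc})") from exc
    if len(rows) != n_frames:
        raise ParseError(f"{path}: {len(rows)} data rows but NumFrames={n_frames}")
    arr = np.asarray(rows)
    time = arr[:, 1]
    if np.any(np.diff(time) <= 0):
        raise ParseError(f"{path}: time column is not strictly increasing")
    markers = {
        lab: arr[:, 2 + 3 * i: 2 + 3 * i + 3] * to_m for i, lab in enumerate(labels)
    }
    return time, markers, rate


def write_trc(path, time: np.ndarray, markers: dict[str, np.ndarray]) -> None:
    """Write markers to TRC (mm).  Planar (F, 2) arrays gain a zero Z."""
    time = np.asarray(time, dtype=float)
    F = time.size
    labels = list(markers)
    data = []
    for lab in labels:
        m = np.asarray(markers[lab], dtype=float)
        if m.shape[1] == 2:
            m = np.column_stack([m, np.zeros(F)])
        data.append(m * 1e3)
    rate = 1.0 / (time[1] - time[0]) if F > 1 else 100.0
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:.6f}\t{rate:.6f}\t{F}\t{len(labels)}\tmm\t{rate:.6f}\t1\t{F}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t\t\n")
        fh.write(
            "\t\t"
            + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(labels)))
            + "\n\n"
        )
        for f in range(F):
            row = [str(f + 1), f"{time[f]:.17g}"]
            for m in data:
                row.extend(f"{v:.17g}" for v in m[f])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# MOT / STO
# ---------------------------------------------------------------------------

def read_motsto(path, convert_degrees: bool = True) -> tuple[pd.DataFrame, dict]:
    """Read a MOT/STO time-series file.

    Returns ``(table, header)``.  If the header says ``inDegrees=yes`` and
    ``convert_degrees`` is true, all non-time columns are converted to
    radians (MOT angle files store degrees by convention).
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    i = 0
    if lines and "=" not in lines[0] and lines[0].strip().lower() != "endheader":
        header["name"] = lines[0].strip()
        i = 1
    end = None
    for j in range(i, len(lines)):
        s = lines[j].strip()
        if s.lower() == "endheader":
            end = j
            break
        if "=" in s:
            k, v = s.split("=", 1)
            header[k.strip()] = v.strip()
            if k.strip().lower() not in _KNOWN_MOTSTO_KEYS:
                warnings.warn(f"{path}: unknown header key {k.strip()!r}", stacklevel=2)
        elif s:
            raise ParseError(f"{path}: line {j + 1}: malformed header line {s!r}")
    if end is None:
        raise ParseError(f"{path}: missing 'endheader' line")
    cols = lines[end + 1].split("\t")
    cols = [c.strip() for c in cols if c.strip()]
    if not cols:
        raise ParseError(f"{path}: line {end + 2}: empty column header")
    if "time" not in cols:
        raise ParseError(f"{path}: missing 'time' column")
    hdr_lc = {k.lower(): v for k, v in header.items()}
    if "ncolumns" in hdr_lc and int(hdr_lc["ncolumns"]) != len(cols):
        raise ParseError(
            f"{path}: header says nColumns={hdr_lc['ncolumns']} but found {len(cols)}"
        )
    rows = []
    for ln in range(end + 2, len(lines)):
        if not lines[ln].strip():
            continue
        fields = [f for f in lines[ln].split("\t") if f.strip()]
        if len(fields) != len(cols):
            raise ParseError(
                f"{path}: line {ln + 1}: {len(fields)} values for {len(cols)} columns"
            )
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln + 1}: non-numeric value ({exc})") from exc
    if "nrows" in hdr_lc and int(hdr_lc["nrows"]) != len(rows):
        raise ParseError(
            f"{path}: header says nRows={hdr_lc['nrows']} but found {len(rows)}"
        )
    df = pd.DataFrame(rows, columns=cols)
    if np.any(np.diff(df["time"].to_numpy()) < 0):
        raise ParseError(f"{path}: time column is not monotone")
    in_degrees = hdr_lc.get("indegrees", "no").lower() == "yes"
    if in_degrees and convert_degrees:
        for c in cols:
            if c != "time":
                df[c] = np.radians(df[c])
    return df, header


def write_motsto(
    table: pd.DataFrame, path, in_degrees: bool = False, name: str | None = None
) -> None:
    """Write a MOT/STO file; with ``in_degrees`` non-time columns are
    converted from radians to degrees and flagged in the header."""
    if "time" not in table.columns:
        raise ValidationError("table needs a 'time' column")
    df = table.copy()
    if in_degrees:
        for c in df.columns:
            if c != "time":
                df[c] = np.degrees(df[c])
    with open(path, "w") as fh:
        fh.write(f"{name or Path(path).stem}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(df)}\n")
        fh.write(f"nColumns={len(df.columns)}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(f"{v:.17g}" for v in row.to_numpy()) + "\n")


# ---------------------------------------------------------------------------
# CV tables / landmark files
# ---------------------------------------------------------------------------

def read_cv_table(path) -> pd.DataFrame:
    """Literature CV table: CSV with muscle,parameter,cv,n_subjects[,source]."""
    df = pd.read_csv(path)
    required = {"muscle", "parameter", "cv", "n_subjects"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: CV table missing columns {sorted(missing)}")
    return df


def write_cv_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_landmarks(path) -> dict[str, float]:
    """Flat key-value CSV of landmark-pair distances (m)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: landmark file needs two columns (pair, distance)")
    out = {}
    for _, row in df.iterrows():
        out[str(row.iloc[0])] = float(row.iloc[1])
    return out
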