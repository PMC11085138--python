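"""Plain-text file formats for sensor logs, calibration data and tables.

All formats are delimited text (comma by default), UTF-8, decimal point,
with a header row.  Time is always hours since inoculation; no datetime
parsing.  Documented formats:

* OD log (long format): ``channel, time_h, od`` — one row per sample,
  several channels per file.  Corrected-space logs carry a
  ``# space=corrected`` comment on the first line.
* Calibration pairs: ``od_sensor, od_reference``.
* Substrate table: ``time_h, conc_g_per_L``.
* Pigment table: ``species, mode, light, substrate, phase, pigment,
  replicate, percent_dw``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, CalibrationPair
from .errors import ParseError
from .growth import ODTimeSeries
from .pigments import TABLE_COLUMNS
from .substrate import SubstrateSeries

__all__ = [
    "read_od_log", "write_od_log",
    "read_calibration_pairs", "read_calibration_json", "write_calibration_json",
    "read_substrate_table", "write_substrate_table",
    "read_pigment_table", "write_pigment_table",
]


def _read_table(path, required: list[str], numeric: list[str]) -> tuple[pd.DataFrame, int]:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    has_comment = first.startswith("#")
    offset = 2 + int(has_comment)  # 1-based data line numbers: header + optional comment
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path} missing column(s): {missing}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        if df[col].isna().any():
            bad = np.union1d(bad, np.flatnonzero(df[col].isna().to_numpy()))
        if bad.size:
            raise ParseError(f"non-numeric value in column '{col}'", line=int(bad[0]) + offset)
        df[col] = vals
    if len(df) == 0:
        raise ParseError(f"{path} contains a header but no data rows")
    return df, offset


def read_od_log(path) -> list[ODTimeSeries]:
    """Parse a long-format OD log into one series per channel.

    Channels are returned sorted by name with times in file order, which
    must be strictly increasing per channel; a duplicated or backwards
    timestamp is a parse error naming the offending line.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    space = "corrected" if first.startswith("#") and "space=corrected" in first else "sensor"
    df, offset = _read_table(path, ["channel", "time_h", "od"], ["time_h", "od"])
    series = []
    for channel, grp in df.groupby("channel", sort=True):
        t = grp["time_h"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            line = int(grp.index[bad[0] + 1]) + offset
            raise ParseError(
                f"non-increasing time in channel {channel!r}", line=line
            )
        if np.any(grp["od"].to_numpy() < 0):
            line = int(grp.index[np.argmax(grp["od"].to_numpy() < 0)]) + offset
            raise ParseError(f"negative OD in channel {channel!r}", line=line)
        series.append(ODTimeSeries(times=t, values=grp["od"].to_numpy(dtype=float),
                                   space=space, channel=str(channel)))
    return series


def write_od_log(path, series: list[ODTimeSeries]) -> None:
    path = Path(path)
    spaces = {s.space for s in series}
    if len(spaces) != 1:
        raise ParseError("all series in one log must share a space")
    with open(path, "w", encoding="utf-8") as fh:
        if spaces == {"corrected"}:
            fh.write("# space=corrected\n")
        fh.write("channel,time_h,od\n")
        for s in series:
            for t, v in zip(s.times, s.values):
                fh.write(f"{s.channel},{t:.6g},{v:.8g}\n")


def read_calibration_pairs(path) -> list[CalibrationPair]:
    df, _ = _read_table(path, ["od_sensor", "od_reference"], ["od_sensor", "od_reference"])
    return [CalibrationPair(float(a), float(b))
            for a, b in zip(df["od_sensor"], df["od_reference"])]


def read_calibration_json(path) -> CalibrationModel:
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path} is not valid JSON: {exc}") from exc
    try:
        return CalibrationModel(
            a=float(obj["a"]), b=float(obj["b"]),
            label=obj.get("label", ""), n_pairs=int(obj.get("n_pairs", 0)),
            r_squared=float(obj.get("r_squared", float("nan"))),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path} lacks valid calibration constants: {exc}") from exc


def write_calibration_json(path, model: CalibrationModel) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"a": model.a, "b": model.b, "label": model.label,
             "n_pairs": model.n_pairs, "r_squared": model.r_squared},
            fh, indent=2,
        )
        fh.write("\n")


def read_substrate_table(path, substrate: str = "") -> SubstrateSeries:
    df, offset = _read_table(path, ["time_h", "conc_g_per_L"], ["time_h", "conc_g_per_L"])
    t = df["time_h"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ParseError("non-increasing time", line=int(bad[0] + 1) + offset)
    return SubstrateSeries(times=t, concentration=df["conc_g_per_L"].to_numpy(dtype=float),
                           substrate=substrate)


def write_substrate_table(path, series: SubstrateSeries) -> None:
    pd.DataFrame({"time_h": series.times, "conc_g_per_L": series.concentration}).to_csv(
        path, index=False
    )


def read_pigment_table(path) -> pd.DataFrame:
    df, _ = _read_table(path, TABLE_COLUMNS, ["light", "replicate", "percent_dw"])
    return df[TABLE_COLUMNS]


def write_pigment_table(path, table: pd.DataFrame) -> None:
    table[TABLE_COLUMNS].to_csv(path, index=False)
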