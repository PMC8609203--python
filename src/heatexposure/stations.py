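"""Weather-station records in the NOAA Integrated Surface Database dialects.

Two dialects are supported and auto-detected per file:

* **ISD-Lite** — the simplified fixed-width hourly format: year, month,
  day, hour, then air temperature, dew point, sea-level pressure (all in
  tenths), wind direction, wind speed (tenths), sky condition and two
  precipitation fields; ``-9999`` marks missing.  ISD-Lite is already
  quality-controlled upstream, so its records carry an implicit passing
  QC code.
* **full ISD** — the mandatory data section of the raw format, from which
  station id, timestamp, air temperature, dew point and their one-digit
  quality codes are decoded (scaled integers in tenths of a degree,
  ``+9999`` missing).

QC filtering keeps records whose temperature and dew-point codes are in
the accepted set {1, 5} ("passed all quality control checks"), and
additionally enforces dew point <= temperature and plausibility bounds.
Station wet bulb temperature is computed with exactly the same
psychrometric machinery as the in-situ pipeline.
"""

from __future__ import annotations

import gzip
from datetime import timezone

import numpy as np
import pandas as pd

from . import psychro, wbgt

__all__ = [
    "read_isd",
    "qc_filter",
    "hourly_aggregate",
    "station_tw",
    "write_isd_lite",
    "write_isd_full",
    "QC_PASS",
]

#: ISD quality codes accepted as "passed all quality control checks".
QC_PASS = {"1", "5"}

_MISSING_LITE = -9999
_COLUMNS = [
    "station_id",
    "timestamp",
    "temperature_c",
    "dew_point_c",
    "temperature_qc",
    "dew_point_qc",
]


def _open_text(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "r")


def _parse_lite_line(line, station_id):
    f = line.split()
    if len(f) < 6:
        raise ValueError("short ISD-Lite line")
    year, month, day, hour = int(f[0]), int(f[1]), int(f[2]), int(f[3])
    t_raw, td_raw = int(f[4]), int(f[5])
    ts = pd.Timestamp(year=year, month=month, day=day, hour=hour, tz=timezone.utc)
    t = np.nan if t_raw == _MISSING_LITE else t_raw / 10.0
    td = np.nan if td_raw == _MISSING_LITE else td_raw / 10.0
    return (station_id, ts, t, td, "1", "1")


def _parse_full_line(line):
    # 1-based spec offsets -> python slices of the mandatory section
    usaf = line[4:10]
    wban = line[10:15]
    date = line[15:23]
    hhmm = line[23:27]
    t_raw = line[87:92]
    t_qc = line[92]
    td_raw = line[93:98]
    td_qc = line[98]
    ts = pd.Timestamp(
        year=int(date[0:4]),
        month=int(date[4:6]),
        day=int(date[6:8]),
        hour=int(hhmm[0:2]),
        minute=int(hhmm[2:4]),
        tz=timezone.utc,
    )
    t = np.nan if t_raw == "+9999" else int(t_raw) / 10.0
    td = np.nan if td_raw == "+9999" else int(td_raw) / 10.0
    sid = usaf if wban.strip() in ("", "99999") else f"{usaf}-{wban}"
    return (sid.strip(), ts, t, td, t_qc, td_qc)


def read_isd(path, station_id=None):
    """Read a station file in ISD-Lite or full-ISD format (auto-detected).

    Parameters
    ----------
    path : str or Path
        Text file, optionally gzip-compressed.  ISD-Lite files carry no
        station id, so one may be supplied (defaults to the file stem).
    """
    from pathlib import Path

    if station_id is None:
        station_id = Path(str(path)).name.split(".")[0].removesuffix(".gz")
    rows, skipped = [], 0
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                # full ISD mandatory section is 105 chars; ISD-Lite ~61
                if len(line) >= 105:
                    rows.append(_parse_full_line(line))
                else:
                    rows.append(_parse_lite_line(line, station_id))
            except (ValueError, IndexError):
                skipped += 1
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.attrs["skipped_lines"] = skipped
    return df


def qc_filter(records, t_bounds=(-30.0, 60.0)):
    """Keep records whose T and Td quality codes pass and are physical.

    Removals are counted by reason: ``qc_code`` (either field's code not
    in the accepted set), ``missing`` (T or Td absent), ``consistency``
    (dew point above temperature) and ``extreme`` (outside plausibility
    bounds).  Filtering is idempotent.
    """
    rec = records
    code_ok = rec["temperature_qc"].astype(str).isin(QC_PASS) & rec[
        "dew_point_qc"
    ].astype(str).isin(QC_PASS)
    present = rec["temperature_c"].notna() & rec["dew_point_c"].notna()
    consistent = rec["dew_point_c"] <= rec["temperature_c"]
    lo, hi = t_bounds
    plaus = rec["temperature_c"].between(lo, hi) & rec["dew_point_c"].between(lo, hi)
    keep = code_ok & present & consistent.fillna(False) & plaus.fillna(False)
    report = {
        "input": int(len(rec)),
        "kept": int(keep.sum()),
        "removed_qc_code": int((~code_ok).sum()),
        "removed_missing": int((code_ok & ~present).sum()),
        "removed_consistency": int(
            (code_ok & present & ~consistent.fillna(False)).sum()
        ),
        "removed_extreme": int(
            (code_ok & present & consistent.fillna(False) & ~plaus.fillna(False)).sum()
        ),
    }
    return rec[keep].reset_index(drop=True), report


def hourly_aggregate(records):
    """Clock-hour field-wise means per station.

    Sub-hourly records are binned to [h:00, h+1:00); temperature and dew
    point are averaged independently over whatever values each record
    carries, so an hour may combine T from one record with Td from
    another.
    """
    rec = records.copy()
    rec["timestamp"] = rec["timestamp"].dt.floor("h")
    out = rec.groupby(["station_id", "timestamp"], as_index=False)[
        ["temperature_c", "dew_point_c"]
    ].mean()
    out["temperature_qc"] = "1"
    out["dew_point_qc"] = "1"
    return out


def station_tw(records):
    """Wet bulb temperature for hourly station records (local time, UTC+8).

    RH is recovered from the dew point (``100 es(Td)/es(T)``) and the
    same Stull formula with the same saturation rule as the in-situ
    pipeline is applied.  Returns a frame with ``unit_id`` (station id),
    local ``timestamp``, ``temperature_c``, ``dew_point_c`` and ``tw_c``.
    """
    rec = records.dropna(subset=["temperature_c", "dew_point_c"]).copy()
    t = rec["temperature_c"].to_numpy(dtype=float)
    td = np.minimum(rec["dew_point_c"].to_numpy(dtype=float), t)
    rh = psychro.relative_humidity_from_vp(
        t, psychro.saturation_vapour_pressure(td)
    )
    rec["tw_c"] = psychro.stull_wet_bulb(t, rh, out_of_range="nan")
    rec["timestamp"] = rec["timestamp"].dt.tz_convert(wbgt.LOCAL_TZ)
    rec = rec.rename(columns={"station_id": "unit_id"})
    return rec[["unit_id", "timestamp", "temperature_c", "dew_point_c", "tw_c"]]


# ----------------------------------------------------------------- writers


def _lite_int(value):
    return _MISSING_LITE if value is None or (isinstance(value, float) and np.isnan(value)) else int(round(value * 10))


def write_isd_lite(records, path):
    """Write records as ISD-Lite fixed-width text (one station per file)."""
    with open(path, "w") as fh:
        for _, r in records.sort_values("timestamp").iterrows():
            ts = r["timestamp"].tz_convert(timezone.utc)
            t = _lite_int(r["temperature_c"])
            td = _lite_int(r["dew_point_c"])
            fh.write(
                f"{ts.year:04d} {ts.month:02d} {ts.day:02d} {ts.hour:02d} "
                f"{t:5d} {td:5d} {_MISSING_LITE:5d} {_MISSING_LITE:5d} "
                f"{_MISSING_LITE:5d} {_MISSING_LITE:5d} {_MISSING_LITE:5d} "
                f"{_MISSING_LITE:5d}\n"
            )


def _full_temp(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "+9999"
    scaled = int(round(value * 10))
    return f"{'+' if scaled >= 0 else '-'}{abs(scaled):04d}"


def write_isd_full(records, path):
    """Write records as full-ISD mandatory-section lines (with QC codes)."""
    with open(path, "w") as fh:
        for _, r in records.sort_values("timestamp").iterrows():
            ts = r["timestamp"].tz_convert(timezone.utc)
            usaf = str(r["station_id"])[:6].ljust(6)
            line = (
                "0081"
                + usaf
                + "99999"
                + f"{ts.year:04d}{ts.month:02d}{ts.day:02d}"
                + f"{ts.hour:02d}{ts.minute:02d}"
                + "4"  # source flag
                + "+00000" + "+000000" + "FM-12" + "+0000" + "99999" + "V020"
                + "999" + "9" + "9" + "9999" + "9"  # wind group
                + "99999" + "9" + "9" + "N"  # ceiling group
                + "999999" + "9" + "9" + "9"  # visibility group
                + _full_temp(r["temperature_c"])
                + str(r.get("temperature_qc", "1"))
                + _full_temp(r["dew_point_c"])
                + str(r.get("dew_point_qc", "1"))
                + "+9999" + "9"  # sea-level pressure
            )
            assert len(line) == 105
            fh.write(line + "\n")
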