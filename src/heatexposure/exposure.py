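"""Exposure summaries: daily maxima, threshold exceedance runs, bands.

The summaries here are the quantities a heat-stress exposure study
reports: the daily maximum wet bulb temperature per unit (earliest record
wins a tie), maximal continuous periods above WBGT activity thresholds
with short recording gaps bridged, run-length and threshold-band
frequency tables, a day/night split, and the paired comparison of in-situ
daily maxima against weather-station daily maxima.

Activity thresholds follow the ISO 7243 occupational heat-stress
reference values for an acclimatised person: 25 degC (heavy work, the
lowest band at which health and productivity effects are reported),
28 degC (moderate/light work), 30 degC (light work) and 33 degC
(resting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ActivityThresholds",
    "DEFAULT_THRESHOLDS",
    "ExceedanceRun",
    "daily_max_tw",
    "exceedance_runs",
    "run_length_histogram",
    "band_frequencies",
    "day_night_split",
    "station_comparison",
]


@dataclass(frozen=True)
class ActivityThresholds:
    """Ordered WBGT activity thresholds (label -> degC, strictly increasing)."""

    values: dict = field(
        default_factory=lambda: {
            "heavy_work": 25.0,
            "moderate_light_work": 28.0,
            "light_work": 30.0,
            "resting": 33.0,
        }
    )

    def __post_init__(self):
        vals = list(self.values.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def celsius(self):
        return list(self.values.values())


DEFAULT_THRESHOLDS = ActivityThresholds()


@dataclass(frozen=True)
class ExceedanceRun:
    """A maximal continuous period at or above a WBGT threshold.

    ``duration_h`` counts clock hours from the first to the last
    above-threshold record inclusive (bridged missing hours count);
    ``n_records`` counts only observed above-threshold records.
    """

    unit_id: str
    threshold: float
    start: pd.Timestamp
    end: pd.Timestamp
    duration_h: float
    n_records: int
    n_bridged_gaps: int


def daily_max_tw(series, value_col="tw_c", unit_col="unit_id"):
    """Daily maximum TW per unit; ties go to the earliest record of the day.

    Parameters
    ----------
    series : pandas.DataFrame
        Columns ``unit_col``, ``timestamp`` (timezone-aware local) and
        ``value_col``.

    Returns
    -------
    pandas.DataFrame with ``unit_id, date, value, at``.
    """
    df = series[[unit_col, "timestamp", value_col]].dropna(subset=[value_col])
    if len(df) == 0:
        return pd.DataFrame(columns=["unit_id", "date", "value", "at"])
    df = df.sort_values("timestamp", kind="stable")
    df = df.assign(date=df["timestamp"].dt.date)
    # idxmax returns the first occurrence of the maximum -> earliest record
    idx = df.groupby([unit_col, "date"])[value_col].idxmax()
    out = df.loc[idx, [unit_col, "date", value_col, "timestamp"]]
    out = out.rename(
        columns={unit_col: "unit_id", value_col: "value", "timestamp": "at"}
    )
    return out.reset_index(drop=True)


def exceedance_runs(series, threshold, max_gap_h=2.0, value_col="wbgt_c",
                    unit_id=""):
    """Maximal runs of records at/above ``threshold``, bridging short gaps.

    A run extends across a silent (missing-record) interval of up to
    ``max_gap_h`` hours between consecutive above-threshold records; an
    *observed* below-threshold record always terminates the run, however
    close in time — the gap rule compensates for two-hourly sampling
    cadence, not for cool interludes.

    Parameters
    ----------
    series : pandas.DataFrame
        Time-sorted ``timestamp`` + ``value_col`` for a single unit;
        records with missing values are treated as absent.

    Returns
    -------
    list of ExceedanceRun, time-ordered and non-overlapping.
    """
    df = series[["timestamp", value_col]].dropna(subset=[value_col])
    ts = df["timestamp"].to_numpy()
    if len(ts) > 1 and np.any(ts[1:] < ts[:-1]):
        raise ValueError("series must be sorted by timestamp")
    vals = df[value_col].to_numpy(dtype=float)
    runs = []
    cur = None  # [start, last_ts, n_records, n_bridged]
    gap = pd.Timedelta(hours=max_gap_h)
    one_h = pd.Timedelta(hours=1)
    for t, v in zip(df["timestamp"], vals):
        if v >= threshold:
            if cur is not None and (t - cur[1]) <= gap:
                if t - cur[1] > one_h:
                    cur[3] += 1
                cur[1] = t
                cur[2] += 1
            else:
                if cur is not None:
                    runs.append(cur)
                cur = [t, t, 1, 0]
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)
    return [
        ExceedanceRun(
            unit_id=unit_id,
            threshold=float(threshold),
            start=s,
            end=e,
            duration_h=(e - s) / one_h + 1.0,
            n_records=n,
            n_bridged_gaps=b,
        )
        for s, e, n, b in runs
    ]


def run_length_histogram(runs, duration_cutoffs=(5.0,)):
    """Counts of runs by (threshold, integer duration) plus cut-off tallies.

    Returns
    -------
    histogram : pandas.DataFrame with columns threshold, duration_h, count
    cutoff_counts : dict  {(threshold, cutoff): count of runs > cutoff hours}
    """
    if not runs:
        return (
            pd.DataFrame(columns=["threshold", "duration_h", "count"]),
            {},
        )
    df = pd.DataFrame(
        {"threshold": [r.threshold for r in runs],
         "duration_h": [r.duration_h for r in runs]}
    )
    hist = (
        df.groupby(["threshold", "duration_h"])
        .size()
        .rename("count")
        .reset_index()
    )
    cutoffs = {
        (thr, c): int(((df["threshold"] == thr) & (df["duration_h"] > c)).sum())
        for thr in df["threshold"].unique()
        for c in duration_cutoffs
    }
    return hist, cutoffs


def band_frequencies(values, thresholds=DEFAULT_THRESHOLDS):
    """Fractions of records per threshold band and cumulative >= fractions.

    Bands are half-open ``[t_i, t_{i+1})`` plus below-lowest and
    at-or-above-highest; band fractions sum to 1.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    t = thresholds.celsius
    edges = [-np.inf] + t + [np.inf]
    labels = (
        [f"<{t[0]:g}"]
        + [f"[{a:g},{b:g})" for a, b in zip(t, t[1:])]
        + [f">={t[-1]:g}"]
    )
    counts, _ = np.histogram(v, bins=edges)
    n = max(len(v), 1)
    bands = {lab: c / n for lab, c in zip(labels, counts)}
    cumulative = {f">={thr:g}": float((v >= thr).mean()) if len(v) else 0.0
                  for thr in t}
    return {"bands": bands, "cumulative": cumulative, "n": int(len(v))}


def day_night_split(records, day_start=6, day_end=18):
    """Partition records into (day, night) by local clock hour.

    Day is the half-open window [day_start:00, day_end:00); with the
    default 06:00-18:00 this matches the nearly constant 12-hour
    equatorial daylight.
    """
    hours = records["timestamp"].dt.hour
    is_day = (hours >= day_start) & (hours < day_end)
    return records[is_day], records[~is_day]


def station_comparison(in_situ, station, per_station=True):
    """Paired same-day comparison of in-situ vs station daily maxima.

    For every calendar day the in-situ side is the maximum daily-max TW
    across all settlement units; the station side is the maximum across
    stations (the collective view), with per-station pairings also
    reported.  Days missing from either side are excluded and counted.

    Parameters
    ----------
    in_situ, station : pandas.DataFrame
        ``daily_max_tw``-shaped frames (``unit_id, date, value, at``).

    Returns
    -------
    dict with ``differences`` (DataFrame date/in_situ/station/difference),
    ``mean_difference``, ``se_difference``, ``n_days``,
    ``n_unpaired_days`` and, optionally, ``per_station`` means.
    """
    situ_daily = in_situ.groupby("date")["value"].max()
    stat_daily = station.groupby("date")["value"].max()
    paired = pd.concat(
        {"in_situ": situ_daily, "station": stat_daily}, axis=1, join="inner"
    ).dropna()
    if len(paired) == 0:
        raise ValueError("no overlapping days between in-situ and station series")
    paired["difference"] = paired["in_situ"] - paired["station"]
    n_all_days = len(situ_daily.index.union(stat_daily.index))
    result = {
        "differences": paired.reset_index(),
        "mean_difference": float(paired["difference"].mean()),
        "se_difference": float(
            paired["difference"].std(ddof=1) / np.sqrt(len(paired))
        )
        if len(paired) > 1
        else float("nan"),
        "n_days": int(len(paired)),
        "n_unpaired_days": int(n_all_days - len(paired)),
    }
    if per_station:
        per = {}
        for sid, grp in station.groupby("unit_id"):
            s = grp.groupby("date")["value"].max()
            p = pd.concat(
                {"in_situ": situ_daily, "station": s}, axis=1, join="inner"
            ).dropna()
            if len(p):
                per[str(sid)] = {
                    "mean_difference": float((p["in_situ"] - p["station"]).mean()),
                    "n_days": int(len(p)),
                }
        result["per_station"] = per
    return result
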