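"""Raw logger records to analysis-ready thermal records.

The processing chain mirrors how a dense, partly sun-exposed network of
cheap temperature/humidity loggers is homogenized before any heat-stress
index is computed:

1. :func:`joint_validity_filter` — drop (settlement, period) blocks where
   either temperature or humidity retrieval failed entirely.
2. :func:`percentile_adjust` — cap solar-inflated readings at the
   cross-sectional 95th percentile of each (settlement, placement,
   timestamp) group.
3. :func:`house_hourly_mean` — average the up-to-six loggers per house
   into one hourly house series.
4. :func:`settlement_median_vp` — settlement-level hourly median vapour
   pressure from the RH-carrying outdoor loggers.
5. :func:`reconstruct_humidity` — per-unit RH and dew point from the
   settlement vapour pressure and the unit's own adjusted temperature.
6. :func:`build_thermal_records` — attach wet bulb temperature (Stull)
   and WBGT (Bernard for houses, Liljegren for outdoor loggers).

:func:`process` runs the whole chain and returns the thermal records plus
a JSON-serializable processing report counting every capped, dropped and
flagged record per settlement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import psychro, wbgt

__all__ = [
    "PipelineConfig",
    "read_logger_csv",
    "joint_validity_filter",
    "percentile_adjust",
    "house_hourly_mean",
    "settlement_median_vp",
    "reconstruct_humidity",
    "build_thermal_records",
    "process",
    "LOGGER_COLUMNS",
]

LOGGER_COLUMNS = [
    "logger_id",
    "site_id",
    "placement",
    "house_id",
    "timestamp",
    "temperature_c",
    "rh_pct",
]


@dataclass
class PipelineConfig:
    """Tunable knobs of the sensor pipeline.

    quantile
        Cross-sectional quantile used for the solar-inflation cap.
    grouping
        ``"settlement"`` pools the quantile within (settlement, placement,
        timestamp); ``"citywide"`` pools across settlements (sensitivity
        mode).
    wind_ms, solar_wm2
        Constants used for the outdoor Liljegren WBGT when no hourly
        wind/solar series is supplied.  Defaults are deliberately
        conservative (1 m/s, no sun); realistic sun exposure is explored
        through the scenario machinery.
    validity_period
        Pandas period frequency defining the blocks of the joint
        temperature+humidity validity rule.
    """

    quantile: float = 0.95
    grouping: str = "settlement"
    wind_ms: float = 1.0
    solar_wm2: float = 0.0
    latitude: float = wbgt.MAKASSAR_LAT
    longitude: float = wbgt.MAKASSAR_LON
    validity_period: str = "M"
    scenarios: tuple = field(default_factory=lambda: wbgt.DEFAULT_SCENARIOS)


def read_logger_csv(path):
    """Read a logger CSV (ISO-8601 timestamps; empty fields are missing).

    Naive timestamps are assumed to be local time (UTC+8).
    """
    df = pd.read_csv(path, dtype={"logger_id": str, "site_id": str, "house_id": str})
    missing = set(LOGGER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"logger CSV missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    df["timestamp"] = ts.dt.tz_convert(wbgt.LOCAL_TZ)
    df["house_id"] = df["house_id"].fillna("")
    return df


def joint_validity_filter(records, period="M"):
    """Keep only (settlement, period) blocks with both T and RH coverage.

    A block is valid when the settlement has at least one temperature
    record and at least one humidity record within the period (default:
    calendar month).  Returns the filtered records and a per-settlement
    coverage report.
    """
    records = records.copy()
    per = records["timestamp"].dt.tz_localize(None).dt.to_period(period)
    key = pd.MultiIndex.from_arrays([records["site_id"], per])
    has_t = records["temperature_c"].notna()
    has_rh = records["rh_pct"].notna()
    valid_blocks = (
        pd.DataFrame({"t": has_t.values, "rh": has_rh.values}, index=key)
        .groupby(level=[0, 1])
        .any()
    )
    ok = valid_blocks["t"] & valid_blocks["rh"]
    keep = pd.Series(ok.reindex(key).values, index=records.index).fillna(False)
    out = records[keep.astype(bool)]
    report = {}
    for site, grp in records.groupby("site_id"):
        kept = int(keep[grp.index].sum())
        report[site] = {
            "input_records": int(len(grp)),
            "kept_records": kept,
            "dropped_records": int(len(grp) - kept),
        }
    return out.reset_index(drop=True), report


def percentile_adjust(records, quantile=0.95, grouping="settlement"):
    """Cap temperatures above the cross-sectional group quantile.

    For every timestamp, within each (settlement, placement) group —
    or (placement) only under ``grouping="citywide"`` — readings above
    the q-quantile (linear interpolation between order statistics) are
    set to it.  Readings at or below pass through unchanged, so the
    operation is idempotent and conserves the record count.

    Returns the records with two new columns, ``adj_temperature_c`` and
    ``capped``, plus an adjustment report.
    """
    if grouping not in ("settlement", "citywide"):
        raise ValueError("grouping must be 'settlement' or 'citywide'")
    records = records.copy()
    keys = ["placement", "timestamp"]
    if grouping == "settlement":
        keys = ["site_id"] + keys
    cap = records.groupby(keys)["temperature_c"].transform(
        lambda s: s.quantile(quantile)
    )
    raw = records["temperature_c"]
    adj = np.minimum(raw, cap)
    records["adj_temperature_c"] = adj
    records["capped"] = (raw > cap).fillna(False)
    report = {}
    for site, grp in records.groupby("site_id"):
        n_capped = int(grp["capped"].sum())
        mag = float((grp["temperature_c"] - grp["adj_temperature_c"]).sum())
        report[site] = {
            "n_records": int(len(grp)),
            "n_capped": n_capped,
            "total_capped_magnitude_c": round(mag, 4),
        }
    return records, report


def house_hourly_mean(records):
    """Hourly mean adjusted temperature per house.

    Two-hourly loggers simply contribute to the hours they report, so
    the averaging denominator varies with cadence; hours with no
    observation are absent from the output.
    """
    houses = records[records["placement"] == "house"]
    out = (
        houses.groupby(["site_id", "house_id", "timestamp"], as_index=False)[
            "adj_temperature_c"
        ]
        .mean()
        .rename(columns={"house_id": "unit_id"})
    )
    out["placement"] = "house"
    return out


def settlement_median_vp(records):
    """Per-settlement hourly median vapour pressure from outdoor RH loggers.

    Vapour pressure is computed per logger from its adjusted temperature
    and reported RH, then the median (midpoint convention for even
    counts, the numpy default) is taken across the settlement's loggers.
    """
    outdoor = records[(records["placement"] == "outdoor") & records["rh_pct"].notna()]
    outdoor = outdoor[outdoor["adj_temperature_c"].notna()]
    if len(outdoor) == 0:
        return pd.DataFrame(columns=["site_id", "timestamp", "vp_hpa"])
    vp = psychro.vapour_pressure(
        outdoor["adj_temperature_c"].to_numpy(), outdoor["rh_pct"].to_numpy()
    )
    tmp = outdoor[["site_id", "timestamp"]].copy()
    tmp["vp_hpa"] = vp
    return tmp.groupby(["site_id", "timestamp"], as_index=False)["vp_hpa"].median()


def reconstruct_humidity(units, settlement_vp):
    """Attach reconstructed RH and dew point to per-unit records.

    RH is recomputed from the settlement-hour median vapour pressure and
    each unit's own adjusted temperature (capped at 100 % where the
    homogenized vapour pressure exceeds saturation for a cool unit);
    dew point follows from the vapour pressure alone.  Units at hours
    with no settlement vapour pressure are dropped and counted.
    """
    merged = units.merge(settlement_vp, on=["site_id", "timestamp"], how="left")
    dropped = int(merged["vp_hpa"].isna().sum())
    merged = merged[merged["vp_hpa"].notna()].reset_index(drop=True)
    if len(merged):
        merged["rh_pct"] = psychro.relative_humidity_from_vp(
            merged["adj_temperature_c"].to_numpy(), merged["vp_hpa"].to_numpy()
        )
        merged["dew_point_c"] = psychro.dew_point(merged["vp_hpa"].to_numpy())
        merged["dew_point_c"] = np.minimum(
            merged["dew_point_c"], merged["adj_temperature_c"]
        )
    else:
        merged["rh_pct"] = pd.Series(dtype=float)
        merged["dew_point_c"] = pd.Series(dtype=float)
    return merged, {"dropped_no_vp": dropped}


def _zenith_series(timestamps, latitude, longitude):
    uniq = pd.DatetimeIndex(timestamps.unique())
    zen = {ts: wbgt.solar_position(latitude, longitude, ts) for ts in uniq}
    return timestamps.map(zen)


def build_thermal_records(units, config=None, wind_solar=None):
    """Attach TW and WBGT to reconstructed unit records.

    Parameters
    ----------
    units : pandas.DataFrame
        Output of :func:`reconstruct_humidity`.
    config : PipelineConfig, optional
    wind_solar : pandas.DataFrame, optional
        Hourly ``timestamp, wind_ms, solar_wm2`` series for the outdoor
        Liljegren computation; falls back to the config constants.

    Records whose inputs fall outside the Stull validity range carry a
    NaN ``tw_c`` and a ``flag`` — they are never silently dropped.
    """
    config = config or PipelineConfig()
    out = units.copy()
    t = out["adj_temperature_c"].to_numpy(dtype=float)
    rh = out["rh_pct"].to_numpy(dtype=float)
    out["tw_c"] = psychro.stull_wet_bulb(t, rh, out_of_range="nan")
    out["flag"] = np.where(np.isnan(out["tw_c"]), "tw_out_of_range", "")

    out["wbgt_c"] = np.nan
    house = out["placement"] == "house"
    if house.any():
        comp = wbgt.bernard_indoor_wbgt(
            out.loc[house, "adj_temperature_c"].to_numpy(),
            out.loc[house, "dew_point_c"].to_numpy(),
        )
        out.loc[house, "wbgt_c"] = comp.wbgt
    outdoor = ~house
    if outdoor.any():
        sub = out.loc[outdoor]
        if wind_solar is not None:
            sub = sub.merge(
                wind_solar[["timestamp", "wind_ms", "solar_wm2"]],
                on="timestamp",
                how="left",
            )
            wind = sub["wind_ms"].fillna(config.wind_ms).to_numpy()
            solar = sub["solar_wm2"].fillna(config.solar_wm2).to_numpy()
        else:
            wind = np.full(len(sub), config.wind_ms)
            solar = np.full(len(sub), config.solar_wm2)
        if np.any(solar > 0):
            zen = _zenith_series(
                out.loc[outdoor, "timestamp"], config.latitude, config.longitude
            ).to_numpy(dtype=float)
        else:
            zen = np.full(len(sub), 90.0)
        comp = wbgt.liljegren_wbgt(
            out.loc[outdoor, "adj_temperature_c"].to_numpy(),
            out.loc[outdoor, "dew_point_c"].to_numpy(),
            wind,
            solar,
            zen,
        )
        out.loc[outdoor, "wbgt_c"] = comp.wbgt
    return out


def process(records, config=None, wind_solar=None):
    """Run the full chain raw records -> thermal records + report."""
    config = config or PipelineConfig()
    report = {"config": {"quantile": config.quantile, "grouping": config.grouping}}
    filtered, cov = joint_validity_filter(records, config.validity_period)
    report["joint_validity"] = cov
    adjusted, adj_rep = percentile_adjust(filtered, config.quantile, config.grouping)
    report["percentile_adjust"] = adj_rep
    houses = house_hourly_mean(adjusted)
    outdoor = adjusted[adjusted["placement"] == "outdoor"].rename(
        columns={"logger_id": "unit_id"}
    )[["site_id", "unit_id", "timestamp", "adj_temperature_c"]]
    outdoor["placement"] = "outdoor"
    units = pd.concat([houses, outdoor], ignore_index=True)
    vp = settlement_median_vp(adjusted)
    units, drop_rep = reconstruct_humidity(units, vp)
    report["reconstruct_humidity"] = drop_rep
    thermal = build_thermal_records(units, config, wind_solar)
    report["n_thermal_records"] = int(len(thermal))
    report["n_flagged"] = int((thermal["flag"] != "").sum())
    return thermal, report
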