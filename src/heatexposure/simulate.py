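"""Synthetic logger-network and weather-station data with known truth.

The generator reproduces the *structure* of a tropical informal-settlement
sensor deployment — 12 settlements, five outdoor temperature+humidity
loggers each, ten houses each hosting three pairs of temperature-only
loggers (one member hourly, one two-hourly) — driven by a deliberately
simple process model: a settlement-level diurnal temperature sinusoid with
a mild seasonal drift, a shared smooth vapour-pressure series, and a
damped, lagged, warm-biased transform for house interiors (so houses are
cooler than outdoors by day and warmer by night).  Observations add
Gaussian sensor noise; a small fraction of outdoor daytime records receive
positive solar-inflation spikes; block-wise missingness emulates logger
attrition.

Everything is reproducible from a single integer seed, with independent
sub-streams per logger so adding a unit never perturbs the others.  The
accompanying :class:`TruthTable` carries the noiseless process evaluated
through the same index formulas as the pipeline, which is what parameter-
recovery tests compare against.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import exposure, pipeline, psychro, stations, wbgt

__all__ = [
    "Climate",
    "HouseModel",
    "Contamination",
    "Missingness",
    "StationModel",
    "SimulationConfig",
    "TruthTable",
    "simulate_network",
    "inject_contamination",
    "simulate_station",
    "write_fixtures",
]


@dataclass
class Climate:
    """Settlement-level climate of the process model (degC, hPa).

    Defaults emulate the Makassar wet season: mean air temperature 29
    with a 4-degree diurnal swing peaking at 14:00 local, vapour pressure
    around 32 hPa (dew point ~25.5) so relative humidity runs from ~65 %
    at midday to saturation on the coolest nights.
    """

    mean_t: float = 29.0
    diurnal_amplitude: float = 4.0
    seasonal_amplitude: float = 0.5
    mean_vp: float = 32.0
    vp_amplitude: float = 1.5
    vp_diurnal: float = 0.5
    settlement_spread: float = 1.0  # offsets span +- this value


@dataclass
class HouseModel:
    """Thermal transform from outdoor truth to house-interior truth."""

    amplitude_damping: float = 0.5
    phase_lag_h: float = 3.0
    warm_bias: float = 0.5


@dataclass
class Contamination:
    """Daytime solar-inflation spikes on outdoor records."""

    fraction: float = 0.02
    spike_mean: float = 3.0
    spike_sd: float = 1.0


@dataclass
class Missingness:
    """Block-wise dropout per logger (attrition / failed downloads)."""

    block_rate: float = 0.002  # probability a block starts at any hour
    block_length_h: int = 48


@dataclass
class StationModel:
    """Weather stations: cooler than the settlements by a fixed offset."""

    offset: float = 1.3
    cadence_h: int = 1
    noise_sd: float = 0.2
    qc_fail_fraction: float = 0.02
    ids: tuple = ("971800", "971840", "971820")


@dataclass
class SimulationConfig:
    n_settlements: int = 12
    outdoor_per_settlement: int = 5
    houses_per_settlement: int = 10
    pairs_per_house: int = 3
    start: str = "2018-11-01"
    end: str = "2019-05-31"
    seed: int = 0
    climate: Climate = field(default_factory=Climate)
    house: HouseModel = field(default_factory=HouseModel)
    noise_sd: float = 0.3
    contamination: Contamination = field(default_factory=Contamination)
    missingness: Missingness = field(default_factory=Missingness)
    station: StationModel = field(default_factory=StationModel)
    # constants used for the truth-table outdoor WBGT (must match the
    # pipeline configuration the recovery run uses)
    wbgt_wind_ms: float = 1.0
    wbgt_solar_wm2: float = 0.0

    def validate(self):
        if min(
            self.n_settlements,
            self.outdoor_per_settlement,
            self.houses_per_settlement,
            self.pairs_per_house,
        ) <= 0:
            raise ValueError("all network counts must be positive")
        if not 0.0 < self.house.amplitude_damping <= 1.0:
            raise ValueError("amplitude damping must lie in (0, 1]")
        if not 0.0 <= self.contamination.fraction <= 1.0:
            raise ValueError("contamination fraction must lie in [0, 1]")
        if self.contamination.fraction > 0.05:
            warnings.warn(
                "contamination fraction exceeds the 5% headroom of the "
                "95th-percentile adjustment; capping can no longer fully "
                "absorb it"
            )
        if self.noise_sd < 0 or self.missingness.block_rate < 0:
            raise ValueError("noise and missingness parameters must be >= 0")


@dataclass
class TruthTable:
    """Noiseless process truth, on the same index formulas as the pipeline."""

    records: pd.DataFrame  # site_id, unit_id, placement, timestamp,
    #                        t_true, vp_true, rh_true, tw_true, wbgt_true
    station_offset_c: float

    def fraction_at_or_above(self, threshold):
        """Per-settlement true fraction of records with WBGT >= threshold."""
        df = self.records.dropna(subset=["wbgt_true"])
        return df.groupby("site_id")["wbgt_true"].apply(
            lambda s: float((s >= threshold).mean())
        )

    def daily_max_tw(self):
        return exposure.daily_max_tw(
            self.records.rename(columns={"tw_true": "tw_c"}), value_col="tw_c"
        )


def _rng(seed, *key):
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _site_ids(n):
    return [f"S{i + 1:02d}" for i in range(n)]


def _truth_series(config, hours):
    """Per-settlement outdoor and house truth plus shared vapour pressure."""
    cl = config.climate
    h = hours.hour.to_numpy() + hours.minute.to_numpy() / 60.0
    doy = hours.dayofyear.to_numpy()
    seasonal = cl.seasonal_amplitude * np.sin(2 * np.pi * (doy - 1) / 365.0)
    diurnal = np.cos(2 * np.pi * (h - 14.0) / 24.0)
    lagged = np.cos(2 * np.pi * (h - 14.0 - config.house.phase_lag_h) / 24.0)
    offsets = (
        np.linspace(-cl.settlement_spread, cl.settlement_spread, config.n_settlements)
        if config.n_settlements > 1
        else np.zeros(1)
    )
    out = {}
    for site, off in zip(_site_ids(config.n_settlements), offsets):
        t_out = cl.mean_t + off + seasonal + cl.diurnal_amplitude * diurnal
        t_house = (
            cl.mean_t
            + off
            + config.house.warm_bias
            + seasonal
            + config.house.amplitude_damping * cl.diurnal_amplitude * lagged
        )
        vp = (
            cl.mean_vp
            + 0.2 * off
            + cl.vp_amplitude * np.sin(2 * np.pi * (doy - 1) / 365.0 + 1.0)
            + cl.vp_diurnal * np.sin(2 * np.pi * h / 24.0)
        )
        out[site] = (t_out, t_house, vp)
    return out


def _truth_indices(t_true, vp_true, placement, wind, solar):
    """RH / TW / WBGT from noiseless temperature and vapour pressure."""
    rh = psychro.relative_humidity_from_vp(t_true, vp_true)
    tw = psychro.stull_wet_bulb(t_true, rh, out_of_range="nan")
    vp_capped = np.minimum(vp_true, psychro.saturation_vapour_pressure(t_true))
    td = psychro.dew_point(vp_capped)
    if placement == "house":
        wbgt_v = wbgt.bernard_indoor_wbgt(t_true, td).wbgt
    else:
        wbgt_v = wbgt.liljegren_wbgt(
            t_true, td, wind, solar, np.full_like(t_true, 90.0)
        ).wbgt
    return rh, tw, wbgt_v


def _missing_mask(rng, n, miss):
    """Boolean mask of hours lost to block-wise dropout."""
    if miss.block_rate <= 0 or n == 0:
        return np.zeros(n, dtype=bool)
    starts = rng.random(n) < miss.block_rate
    mask = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(starts):
        mask[i : i + miss.block_length_h] = True
    return mask


def simulate_network(config=None):
    """Generate the logger network: (LoggerRecord frame, TruthTable).

    Contamination is *not* applied here — feed the records through
    :func:`inject_contamination` so the clean/contaminated pairing stays
    explicit for recovery tests.
    """
    config = config or SimulationConfig()
    config.validate()
    hours = pd.date_range(
        f"{config.start} 00:00", f"{config.end} 23:00", freq="h", tz=wbgt.LOCAL_TZ
    )
    truth_series = _truth_series(config, hours)
    rec_parts, truth_parts = [], []
    for si, site in enumerate(_site_ids(config.n_settlements)):
        t_out, t_house, vp = truth_series[site]
        # outdoor units: identical truth per settlement, five loggers
        rh_o, tw_o, wbgt_o = _truth_indices(
            t_out, vp, "outdoor", config.wbgt_wind_ms, config.wbgt_solar_wm2
        )
        rh_h, tw_h, wbgt_h = _truth_indices(t_house, vp, "house", 1.0, 0.0)
        for k in range(config.outdoor_per_settlement):
            lid = f"{site}_OUT{k + 1}"
            rng = _rng(config.seed, si, k)
            t_obs = t_out + rng.normal(0.0, config.noise_sd, len(hours))
            rh_obs = psychro.relative_humidity_from_vp(t_obs, vp)
            keep = ~_missing_mask(rng, len(hours), config.missingness)
            rec_parts.append(
                pd.DataFrame(
                    {
                        "logger_id": lid,
                        "site_id": site,
                        "placement": "outdoor",
                        "house_id": "",
                        "timestamp": hours[keep],
                        "temperature_c": t_obs[keep],
                        "rh_pct": rh_obs[keep],
                    }
                )
            )
            truth_parts.append(
                pd.DataFrame(
                    {
                        "site_id": site,
                        "unit_id": lid,
                        "placement": "outdoor",
                        "timestamp": hours,
                        "t_true": t_out,
                        "vp_true": vp,
                        "rh_true": rh_o,
                        "tw_true": tw_o,
                        "wbgt_true": wbgt_o,
                    }
                )
            )
        for k in range(config.houses_per_settlement):
            hid = f"{site}_H{k + 1:02d}"
            for p in range(config.pairs_per_house):
                for cadence, tag in ((1, "h"), (2, "2")):
                    lid = f"{hid}_L{p + 1}{tag}"
                    rng = _rng(config.seed, si, 100 + k * 10 + p * 2 + (cadence - 1))
                    t_obs = t_house + rng.normal(0.0, config.noise_sd, len(hours))
                    keep = ~_missing_mask(rng, len(hours), config.missingness)
                    if cadence == 2:
                        keep &= hours.hour % 2 == 0
                    rec_parts.append(
                        pd.DataFrame(
                            {
                                "logger_id": lid,
                                "site_id": site,
                                "placement": "house",
                                "house_id": hid,
                                "timestamp": hours[keep],
                                "temperature_c": t_obs[keep],
                                "rh_pct": np.nan,
                            }
                        )
                    )
            truth_parts.append(
                pd.DataFrame(
                    {
                        "site_id": site,
                        "unit_id": hid,
                        "placement": "house",
                        "timestamp": hours,
                        "t_true": t_house,
                        "vp_true": vp,
                        "rh_true": rh_h,
                        "tw_true": tw_h,
                        "wbgt_true": wbgt_h,
                    }
                )
            )
    records = pd.concat(rec_parts, ignore_index=True)
    truth = TruthTable(
        records=pd.concat(truth_parts, ignore_index=True),
        station_offset_c=config.station.offset,
    )
    return records, truth


def inject_contamination(records, config=None, day_start=6, day_end=18):
    """Add positive solar-inflation spikes to outdoor daytime records.

    Returns the contaminated records and a log of every spiked
    (logger, timestamp, magnitude).  With the default 2 % fraction the
    spikes stay within the headroom of the 95th-percentile adjustment.
    """
    config = config or SimulationConfig()
    cont = config.contamination
    out = records.copy()
    if cont.fraction <= 0:
        return out, pd.DataFrame(columns=["logger_id", "timestamp", "magnitude_c"])
    if cont.fraction > 0.05:
        warnings.warn("contamination exceeds the 95th-percentile headroom")
    rng = _rng(config.seed, 999_983)
    hours = out["timestamp"].dt.hour
    eligible = np.flatnonzero(
        (out["placement"] == "outdoor").to_numpy()
        & (hours >= day_start).to_numpy()
        & (hours < day_end).to_numpy()
    )
    n_spike = int(round(cont.fraction * len(eligible)))
    idx = rng.choice(eligible, size=n_spike, replace=False)
    spikes = np.abs(rng.normal(cont.spike_mean, cont.spike_sd, n_spike))
    spikes = np.maximum(spikes, 1e-3)
    out.loc[out.index[idx], "temperature_c"] += spikes
    log = pd.DataFrame(
        {
            "logger_id": out.loc[out.index[idx], "logger_id"].to_numpy(),
            "timestamp": out.loc[out.index[idx], "timestamp"].to_numpy(),
            "magnitude_c": spikes,
        }
    )
    return out, log


def simulate_station(config=None, truth=None):
    """Weather-station records on the ISD dialect, cooler by the offset.

    Station temperature and dew point equal the cross-settlement mean
    outdoor truth shifted down by ``config.station.offset`` (same shift on
    both, i.e. the station sits in a cooler but equally humid spot), plus
    Gaussian noise, emitted at the configured cadence.  A configurable
    fraction of records carries a failing QC code (code 3) to exercise
    the QC filter; those records are flagged in the returned generation
    log.
    """
    config = config or SimulationConfig()
    if truth is None:
        _, truth = simulate_network(config)
    st = config.station
    outdoor = truth.records[truth.records["placement"] == "outdoor"]
    base = outdoor.groupby("timestamp", as_index=False)[["t_true", "vp_true"]].mean()
    base = base.iloc[:: max(st.cadence_h, 1)].reset_index(drop=True)
    vp_capped = np.minimum(
        base["vp_true"].to_numpy(),
        psychro.saturation_vapour_pressure(base["t_true"].to_numpy()),
    )
    td_base = psychro.dew_point(vp_capped)
    parts = []
    for i, sid in enumerate(st.ids):
        rng = _rng(config.seed, 777_001, i)
        t = base["t_true"].to_numpy() - st.offset + rng.normal(0, st.noise_sd, len(base))
        td = np.minimum(td_base - st.offset + rng.normal(0, st.noise_sd, len(base)), t)
        fail = rng.random(len(base)) < st.qc_fail_fraction
        parts.append(
            pd.DataFrame(
                {
                    "station_id": sid,
                    "timestamp": base["timestamp"].dt.tz_convert("UTC"),
                    "temperature_c": np.round(t, 1),
                    "dew_point_c": np.round(td, 1),
                    "temperature_qc": np.where(fail, "3", "1"),
                    "dew_point_qc": "1",
                }
            )
        )
    records = pd.concat(parts, ignore_index=True)
    return records


def write_fixtures(records, station_records, out_dir, config=None, truth=None):
    """Write logger CSV, ISD station files, truth CSV and config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger_csv = records.copy()
    logger_csv["timestamp"] = logger_csv["timestamp"].map(
        lambda t: t.isoformat()
    )
    logger_csv.to_csv(out / "loggers.csv", index=False)
    for sid, grp in station_records.groupby("station_id"):
        stations.write_isd_lite(grp, out / f"{sid}.txt")
        stations.write_isd_full(grp, out / f"{sid}.isd")
    if truth is not None:
        truth.records.to_csv(out / "truth.csv", index=False)
    if config is not None:
        with open(out / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
    return out
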