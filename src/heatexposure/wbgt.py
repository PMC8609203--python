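"""Wet bulb globe temperature (WBGT) models.

Two complementary models are provided, matching how occupational heat
stress is assessed indoors and outdoors:

* :func:`bernard_indoor_wbgt` — Bernard's empirical indoor/shaded model.
  The natural wet bulb is obtained from the psychrometric wet bulb through
  a wind-speed correction, and ``WBGT = 0.67 Tnwb + 0.33 Ta`` (no globe
  term: in full shade the globe equilibrates with air temperature).
* :func:`liljegren_wbgt` — the Liljegren et al. (2008) physical model,
  which solves coupled energy balances for a 150 mm black globe and a
  wetted wick exposed to sun and wind, then combines
  ``WBGT = 0.7 Tnwb + 0.2 Tg + 0.1 Ta``.

Both are vectorized over numpy arrays.  :func:`solar_position` supplies
the solar zenith angle the outdoor model needs; the four standard
wind/solar exposure scenarios are applied with :func:`apply_scenarios`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import psychro

__all__ = [
    "Scenario",
    "DEFAULT_SCENARIOS",
    "WbgtComponents",
    "bernard_indoor_wbgt",
    "liljegren_wbgt",
    "solar_position",
    "apply_scenarios",
    "MAKASSAR_LAT",
    "MAKASSAR_LON",
    "LOCAL_TZ",
]

#: Mean coordinates of the studied settlements (Makassar, Indonesia).
MAKASSAR_LAT = -5.14
MAKASSAR_LON = 119.43

#: Fixed local offset (Makassar / WITA, UTC+8, no DST).
LOCAL_TZ = timezone(timedelta(hours=8))

# ------------------------------------------------------------------ types


@dataclass(frozen=True)
class Scenario:
    """A (solar, wind, shade) exposure scenario for outdoor records."""

    label: str
    solar: float  # global horizontal irradiance, W/m2 (ignored if shaded)
    wind: float  # m/s
    shaded: bool = False

    def __post_init__(self):
        if self.wind <= 0:
            raise ValueError("wind speed must be positive")
        if self.solar < 0:
            raise ValueError("solar irradiance must be non-negative")


#: The four standard scenarios, from low to high heat stress:
#: full shade with strong wind, moderate sun and wind, strong sun with
#: strong wind, strong sun with weak wind.
DEFAULT_SCENARIOS = (
    Scenario("shade_10ms", 0.0, 10.0, shaded=True),
    Scenario("400Wm2_3ms", 400.0, 3.0),
    Scenario("1000Wm2_10ms", 1000.0, 10.0),
    Scenario("1000Wm2_1ms", 1000.0, 1.0),
)


@dataclass(frozen=True)
class WbgtComponents:
    """Component temperatures of a WBGT evaluation (degC; arrays or scalars)."""

    natural_wet_bulb: object
    globe_temperature: object
    air_temperature: object
    wbgt: object


# ---------------------------------------------------------- Bernard model


def bernard_indoor_wbgt(temperature, dew_point, wind=1.0):
    """Indoor / fully-shaded WBGT from air temperature and dew point.

    The psychrometric wet bulb Tpwb is computed with the thermodynamic
    solver, then converted to the natural wet bulb with Bernard's
    empirical indoor relation::

        Tnwb = Ta - (Ta - Tpwb) * (0.96 + 0.069 log10(v))   0.3 <= v < 3 m/s
        Tnwb = Tpwb + 0.25                                  v >= 3 m/s

    and ``WBGT = 0.67 Tnwb + 0.33 Ta``.  The default wind speed is 1 m/s,
    the standard assumption for indoor conditions.
    """
    t = np.asarray(temperature, dtype=float)
    td = np.asarray(dew_point, dtype=float)
    scalar = t.ndim == 0 and td.ndim == 0
    t, td = np.atleast_1d(*np.broadcast_arrays(t, td))
    if np.any(td > t + 1e-9):
        raise psychro.DomainError("dew point exceeds air temperature")
    td = np.minimum(td, t)
    vp = psychro.saturation_vapour_pressure(td)
    rh = psychro.relative_humidity_from_vp(t, vp)
    tpwb = psychro.thermodynamic_wet_bulb(t, rh)
    v = max(float(wind), 0.1)
    if v >= 3.0:
        tnwb = tpwb + 0.25
    else:
        tnwb = t - (t - tpwb) * (0.96 + 0.069 * math.log10(v))
    tnwb = np.minimum(tnwb, t)  # correction cannot push Tnwb above Ta
    wbgt = 0.67 * tnwb + 0.33 * t
    if scalar:
        return WbgtComponents(float(tnwb[0]), float(t[0]), float(t[0]), float(wbgt[0]))
    return WbgtComponents(tnwb, t.copy(), t, wbgt)


# --------------------------------------------------------- Liljegren model
# Physical constants and instrument geometry from Liljegren et al. (2008).

_STEFANB = 5.6696e-8
_CP = 1003.5  # J/kg/K dry air
_M_AIR = 28.97
_M_H2O = 18.015
_R_GAS = 8314.34
_R_AIR = _R_GAS / _M_AIR
_PR = _CP / (_CP + 1.25 * _R_AIR)  # Prandtl number
_RATIO = _CP * _M_AIR / _M_H2O
_SOLAR_CONST = 1367.0

_EMIS_GLOBE = 0.95
_ALB_GLOBE = 0.05
_DIAM_GLOBE = 0.0508  # m
_EMIS_WICK = 0.95
_ALB_WICK = 0.4
_DIAM_WICK = 0.007  # m
_LEN_WICK = 0.0254  # m
_EMIS_SFC = 0.999
_ALB_SFC = 0.45

_CONVERGENCE = 0.02  # degC
_MAX_ITER = 50
_CZA_MIN = 0.00873  # cos(89.5 deg)


def _viscosity(tk):
    """Dynamic viscosity of air, kg/(m s); tk in K."""
    sigma = 3.617
    eps_kappa = 97.0
    tr = tk / eps_kappa
    omega = (tr - 2.9) / 0.4 * (-0.034) + 1.048
    return 2.6693e-6 * np.sqrt(_M_AIR * tk) / (sigma * sigma * omega)


def _thermal_cond(tk):
    return (_CP + 1.25 * _R_AIR) * _viscosity(tk)


def _diffusivity(tk, p_hpa):
    """Water vapour diffusivity in air, m2/s."""
    pcrit13 = (36.4 * 218.0) ** (1.0 / 3.0)
    tcrit512 = (132.0 * 647.3) ** (5.0 / 12.0)
    tcrit12 = math.sqrt(132.0 * 647.3)
    mmix = math.sqrt(1.0 / _M_AIR + 1.0 / _M_H2O)
    patm = p_hpa / 1013.25
    return (
        0.000364 * (tk / tcrit12) ** 2.334 * pcrit13 * tcrit512 * mmix / patm * 1e-4
    )


def _esat_hpa(tk):
    """Saturation vapour pressure (hPa) at tk (K), same Magnus curve as psychro."""
    return psychro.saturation_vapour_pressure(tk - 273.15)


def _evap(tk):
    """Latent heat of vaporization, J/kg."""
    return (313.15 - tk) / 30.0 * (-71100.0) + 2.4073e6


def _emis_atm(tk, e_hpa):
    """Atmospheric broadband emissivity from vapour pressure (hPa)."""
    return 0.575 * np.maximum(e_hpa, 1e-6) ** (1.0 / 7.0)


def _h_sphere(diam, tk, p_hpa, speed):
    density = p_hpa * 100.0 / (_R_AIR * tk)
    re = np.maximum(speed, 0.1) * density * diam / _viscosity(tk)
    nu = 2.0 + 0.6 * np.sqrt(re) * _PR ** (1.0 / 3.0)
    return nu * _thermal_cond(tk) / diam


def _h_cylinder(diam, tk, p_hpa, speed):
    a, b = 0.56, 0.281
    density = p_hpa * 100.0 / (_R_AIR * tk)
    re = np.maximum(speed, 0.1) * density * diam / _viscosity(tk)
    nu = a * re ** b * _PR ** (1.0 / 3.0)
    return nu * _thermal_cond(tk) / diam


def _solar_parameters(solar, zenith_deg):
    """Clip irradiance to top-of-atmosphere and split into direct fraction.

    When only global horizontal irradiance is known, the direct-beam
    fraction is estimated from the clearness index with Liljegren's
    empirical parameterization ``fdir = exp(3 - 1.34 k - 1.65 / k)``.
    Sun below (or within 0.5 deg of) the horizon zeroes the solar input.
    """
    cza = np.cos(np.radians(np.asarray(zenith_deg, dtype=float)))
    solar = np.asarray(solar, dtype=float).copy()
    toa = _SOLAR_CONST * np.maximum(cza, 0.0)
    up = (cza > _CZA_MIN) & (solar > 0.0)
    solar = np.where(up, np.minimum(solar, toa), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(up, solar / np.where(toa > 0, toa, 1.0), 0.0)
        fdir = np.where(
            k > 0, np.exp(3.0 - 1.34 * k - 1.65 / np.maximum(k, 1e-9)), 0.0
        )
    fdir = np.clip(fdir, 0.0, 0.9)
    cza = np.maximum(cza, _CZA_MIN)
    return solar, fdir, cza


def _globe_temperature(tk, e_hpa, p_hpa, speed, solar, fdir, cza):
    """Fixed-point solution of the black-globe energy balance (K)."""
    tsfc = tk
    ea = _emis_atm(tk, e_hpa)
    tg = tk.copy()
    active = np.ones(tk.shape, dtype=bool)
    for _ in range(_MAX_ITER):
        tref = 0.5 * (tg + tk)
        h = _h_sphere(_DIAM_GLOBE, tref, p_hpa, speed)
        tg_new = (
            0.5 * (ea * tk ** 4 + _EMIS_SFC * tsfc ** 4)
            - h / (_STEFANB * _EMIS_GLOBE) * (tg - tk)
            + solar
            / (2.0 * _STEFANB * _EMIS_GLOBE)
            * (1.0 - _ALB_GLOBE)
            * (fdir * (1.0 / (2.0 * cza) - 1.0) + 1.0 + _ALB_SFC)
        ) ** 0.25
        done = np.abs(tg_new - tg) < _CONVERGENCE
        active &= ~done
        tg = np.where(active, 0.9 * tg + 0.1 * tg_new, np.where(done, tg_new, tg))
        if not active.any():
            return tg
    raise psychro.ConvergenceError(
        f"globe temperature did not converge for {int(active.sum())} records "
        f"(e.g. Ta={float(tk[active][0]) - 273.15:.2f} degC, "
        f"wind={float(np.atleast_1d(speed)[0]):.2f} m/s)"
    )


def _natural_wet_bulb(tk, e_hpa, p_hpa, speed, solar, fdir, cza):
    """Fixed-point solution of the wetted-wick energy balance (K)."""
    tsfc = tk
    ea = _emis_atm(tk, e_hpa)
    sza = np.arccos(np.clip(cza, -1.0, 1.0))
    td = psychro.dew_point(np.maximum(e_hpa, 1e-6)) + 273.15
    tw = np.minimum(td, tk).copy()
    active = np.ones(tk.shape, dtype=bool)
    for _ in range(_MAX_ITER):
        tref = 0.5 * (tw + tk)
        h = _h_cylinder(_DIAM_WICK, tref, p_hpa, speed)
        fatm = _STEFANB * _EMIS_WICK * (
            0.5 * (ea * tk ** 4 + _EMIS_SFC * tsfc ** 4) - tw ** 4
        ) + (1.0 - _ALB_WICK) * solar * (
            (1.0 - fdir) * (1.0 + 0.25 * _DIAM_WICK / _LEN_WICK)
            + fdir * (np.tan(sza) / np.pi + 0.25 * _DIAM_WICK / _LEN_WICK)
            + _ALB_SFC
        )
        ewick = _esat_hpa(tw)
        density = p_hpa * 100.0 / (_R_AIR * tref)
        sc = _viscosity(tref) / (density * _diffusivity(tref, p_hpa))
        tw_new = tk - _evap(tref) / _RATIO * (ewick - e_hpa) / (
            p_hpa - ewick
        ) * (_PR / sc) ** 0.56 + fatm / h
        done = np.abs(tw_new - tw) < _CONVERGENCE
        active &= ~done
        tw = np.where(active, 0.9 * tw + 0.1 * tw_new, np.where(done, tw_new, tw))
        if not active.any():
            return tw
    raise psychro.ConvergenceError(
        f"natural wet bulb did not converge for {int(active.sum())} records"
    )


def liljegren_wbgt(
    temperature,
    dew_point,
    wind,
    solar,
    zenith,
    pressure=psychro.STANDARD_PRESSURE_HPA,
):
    """Outdoor WBGT from the Liljegren et al. (2008) energy-balance model.

    Parameters
    ----------
    temperature, dew_point : array_like, degC
    wind : array_like, m/s (strictly positive)
    solar : array_like
        Global horizontal irradiance, W/m2.  The direct-beam fraction is
        derived internally from the clearness index.
    zenith : array_like, degrees
        Solar zenith angle.  Values > 90 (sun below horizon) force the
        solar input to zero, so continuous night-time series are fine.
    pressure : array_like, hPa

    Returns
    -------
    WbgtComponents
        With ``wbgt = 0.7 Tnwb + 0.2 Tg + 0.1 Ta``.
    """
    arrs = [np.asarray(a, dtype=float) for a in (temperature, dew_point, wind, solar, zenith, pressure)]
    scalar = all(a.ndim == 0 for a in arrs)
    t, td, v, s, z, p = (np.atleast_1d(a) for a in np.broadcast_arrays(*arrs))
    if np.any(v <= 0):
        raise psychro.DomainError("wind speed must be positive")
    if np.any(s < 0):
        raise psychro.DomainError("solar irradiance must be non-negative")
    if np.any(td > t + 1e-9):
        raise psychro.DomainError("dew point exceeds air temperature")
    td = np.minimum(td, t)
    solar_c, fdir, cza = _solar_parameters(s, z)
    tk = t + 273.15
    e_hpa = psychro.saturation_vapour_pressure(td)
    tg = _globe_temperature(tk, e_hpa, p, v, solar_c, fdir, cza) - 273.15
    tnwb = _natural_wet_bulb(tk, e_hpa, p, v, solar_c, fdir, cza) - 273.15
    wbgt = 0.7 * tnwb + 0.2 * tg + 0.1 * t
    if scalar:
        return WbgtComponents(float(tnwb[0]), float(tg[0]), float(t[0]), float(wbgt[0]))
    return WbgtComponents(tnwb, tg, t, wbgt)


# ---------------------------------------------------------- solar geometry


def solar_position(latitude, longitude, timestamp):
    """Solar zenith angle (degrees) at a timezone-aware local timestamp.

    Uses the NOAA general solar-position equations (fractional-year
    Fourier series for declination and the equation of time), accurate to
    well under half a degree — ample for the globe-model's direct-beam
    geometry.

    Returns values in [0, 180]; zenith > 90 means the sun is below the
    horizon.
    """
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    utc = ts.tz_convert(timezone.utc)
    doy = utc.dayofyear
    hour = utc.hour + utc.minute / 60.0 + utc.second / 3600.0
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    time_offset = eqtime + 4.0 * longitude  # minutes, relative to UTC
    tst = hour * 60.0 + time_offset
    ha = math.radians(tst / 4.0 - 180.0)
    lat = math.radians(latitude)
    cos_zen = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(ha)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_zen))))


def midday_zenith(
    latitude=MAKASSAR_LAT,
    longitude=MAKASSAR_LON,
    reference_date="2019-03-01",
):
    """Zenith at 12:00 local time on a fixed reference date (mid wet season)."""
    ts = pd.Timestamp(f"{reference_date} 12:00").tz_localize(LOCAL_TZ)
    return solar_position(latitude, longitude, ts)


# -------------------------------------------------------------- scenarios


def apply_scenarios(
    records,
    scenarios=DEFAULT_SCENARIOS,
    latitude=MAKASSAR_LAT,
    longitude=MAKASSAR_LON,
    reference_date="2019-03-01",
):
    """Recompute WBGT for daytime outdoor records under fixed scenarios.

    Parameters
    ----------
    records : pandas.DataFrame
        Daytime outdoor thermal records with columns ``adj_temperature_c``
        and ``dew_point_c`` (as produced by the sensor pipeline).
    scenarios : iterable of Scenario
    latitude, longitude, reference_date
        Define the fixed midday solar zenith used for all sunny
        scenarios, evaluated at the mean settlement coordinates.

    Returns
    -------
    pandas.DataFrame
        ``records`` with one extra WBGT column per scenario, named
        ``wbgt_<label>``.
    """
    import warnings

    out = records.copy()
    if len(records) == 0:
        warnings.warn("apply_scenarios called with an empty record set")
        for sc in scenarios:
            out[f"wbgt_{sc.label}"] = pd.Series(dtype=float)
        return out
    zen = midday_zenith(latitude, longitude, reference_date)
    t = records["adj_temperature_c"].to_numpy(dtype=float)
    td = records["dew_point_c"].to_numpy(dtype=float)
    for sc in scenarios:
        if sc.shaded:
            comp = bernard_indoor_wbgt(t, td, wind=sc.wind)
        else:
            comp = liljegren_wbgt(t, td, sc.wind, sc.solar, zen)
        out[f"wbgt_{sc.label}"] = comp.wbgt
    return out
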