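"""Psychrometric primitives and wet-bulb temperature.

All functions are pure and vectorized: scalars in, scalar out; array-likes
in, :class:`numpy.ndarray` out.  Two independent wet-bulb routes are
provided:

* :func:`stull_wet_bulb` — the closed-form approximation of Stull (2011),
  a function of dry-bulb temperature and relative humidity only, valid for
  T in [-20, 50] degC and RH in [5, 99] %.
* :func:`thermodynamic_wet_bulb` — a bisection solver of the psychrometric
  balance ``es(Tw) - e = gamma * P * (T - Tw)``, used as the accuracy
  oracle for the approximation.

Saturation vapour pressure uses the Magnus form with Alduchov-Eskridge
coefficients, ``es = 6.1094 * exp(17.625 T / (243.04 + T))`` hPa, which is
accurate to well under 0.1 % over liquid water between 0 and 50 degC and
inverts in closed form for the dew point.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DomainError",
    "ConvergenceError",
    "saturation_vapour_pressure",
    "vapour_pressure",
    "relative_humidity_from_vp",
    "dew_point",
    "stull_wet_bulb",
    "thermodynamic_wet_bulb",
    "MAGNUS_A",
    "MAGNUS_B",
    "MAGNUS_C",
    "PSYCHROMETER_GAMMA",
    "STANDARD_PRESSURE_HPA",
]

# Magnus / Alduchov-Eskridge coefficients (hPa, degC)
MAGNUS_A = 6.1094
MAGNUS_B = 17.625
MAGNUS_C = 243.04

#: Assmann psychrometer constant, K^-1 (multiplies pressure in hPa).
PSYCHROMETER_GAMMA = 6.66e-4

#: Standard sea-level barometric pressure, hPa.
STANDARD_PRESSURE_HPA = 1013.0

# Validity rectangle of the Stull approximation.
STULL_T_MIN, STULL_T_MAX = -20.0, 50.0
STULL_RH_MIN, STULL_RH_MAX = 5.0, 99.0


class DomainError(ValueError):
    """An input lies outside a function's physical/validity domain."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge within its iteration cap."""


def _prepare(*values):
    """Broadcast inputs to float arrays; remember whether all were scalar."""
    arrays = [np.asarray(v, dtype=float) for v in values]
    scalar = all(a.ndim == 0 for a in arrays)
    arrays = np.broadcast_arrays(*arrays) if len(arrays) > 1 else arrays
    return arrays, scalar


def _ret(value, scalar):
    return float(value) if scalar else value


def saturation_vapour_pressure(temperature):
    """Saturation vapour pressure over liquid water, hPa.

    Parameters
    ----------
    temperature : array_like
        Dry-bulb temperature in degC, within [-40, 60].
    """
    (t,), scalar = _prepare(temperature)
    if np.any((t < -40.0) | (t > 60.0)):
        raise DomainError("temperature outside [-40, 60] degC")
    es = MAGNUS_A * np.exp(MAGNUS_B * t / (MAGNUS_C + t))
    return _ret(es, scalar)


def vapour_pressure(temperature, relative_humidity):
    """Actual vapour pressure (hPa) from temperature (degC) and RH (%)."""
    (t, rh), scalar = _prepare(temperature, relative_humidity)
    if np.any((rh <= 0.0) | (rh > 100.0)):
        raise DomainError("relative humidity must lie in (0, 100] %")
    vp = rh / 100.0 * saturation_vapour_pressure(t)
    return _ret(vp, scalar)


def relative_humidity_from_vp(temperature, vapour_pressure_hpa):
    """Relative humidity (%) from temperature and vapour pressure.

    Supersaturated inputs (vp above saturation, which the settlement-level
    vapour-pressure homogenization can produce for the coolest unit) are
    clipped to 100 %.
    """
    (t, vp), scalar = _prepare(temperature, vapour_pressure_hpa)
    if np.any(vp <= 0.0):
        raise DomainError("vapour pressure must be positive")
    rh = np.minimum(100.0 * vp / saturation_vapour_pressure(t), 100.0)
    return _ret(rh, scalar)


def dew_point(vapour_pressure_hpa):
    """Dew point (degC) — closed-form inverse of the Magnus saturation curve."""
    (vp,), scalar = _prepare(vapour_pressure_hpa)
    if np.any(vp <= 0.0):
        raise DomainError("vapour pressure must be positive")
    ln = np.log(vp / MAGNUS_A)
    return _ret(MAGNUS_C * ln / (MAGNUS_B - ln), scalar)


def stull_wet_bulb(temperature, relative_humidity, *, out_of_range="raise"):
    """Closed-form wet-bulb temperature (degC), Stull (2011).

    ``TW = T atan(0.151977 (RH + 8.313659)^1/2) + atan(T + RH)
    - atan(RH - 1.676331) + 0.00391838 RH^(3/2) atan(0.023101 RH)
    - 4.686035``

    Valid for T in [-20, 50] degC and RH in [5, 99] %.  For RH above 99 %
    the air is treated as saturated and the dry-bulb temperature is
    returned.  The result is capped at the dry-bulb temperature, which the
    raw polynomial can exceed by a few hundredths of a degree at the very
    humid edge of its fitting range.

    Parameters
    ----------
    out_of_range : {"raise", "nan"}
        Whether inputs outside the validity rectangle (and not covered by
        the saturation rule) raise :class:`DomainError` or yield NaN.
    """
    (t, rh), scalar = _prepare(temperature, relative_humidity)
    saturated = rh > STULL_RH_MAX
    invalid = (
        (t < STULL_T_MIN)
        | (t > STULL_T_MAX)
        | (rh < STULL_RH_MIN)
        | (rh > 100.0)
    )
    if np.any(invalid):
        if out_of_range == "raise":
            raise DomainError(
                "inputs outside Stull validity range T in [-20, 50] degC, "
                "RH in [5, 100] %"
            )
        if out_of_range != "nan":
            raise ValueError("out_of_range must be 'raise' or 'nan'")
    tw = (
        t * np.arctan(0.151977 * np.sqrt(rh + 8.313659))
        + np.arctan(t + rh)
        - np.arctan(rh - 1.676331)
        + 0.00391838 * rh ** 1.5 * np.arctan(0.023101 * rh)
        - 4.686035
    )
    tw = np.minimum(tw, t)
    tw = np.where(saturated & ~invalid, t, tw)
    tw = np.where(invalid, np.nan, tw)
    return _ret(tw, scalar)


def thermodynamic_wet_bulb(
    temperature,
    relative_humidity,
    pressure=STANDARD_PRESSURE_HPA,
    *,
    gamma=PSYCHROMETER_GAMMA,
    tol=1e-3,
    max_iter=100,
):
    """Psychrometric (aspirated) wet-bulb temperature by bisection, degC.

    Solves ``es(Tw) - e = gamma * P * (T - Tw)`` for Tw on the bracket
    [dew point, T], on which the residual changes sign monotonically, so
    bisection is guaranteed.  Independent of :func:`stull_wet_bulb` and
    used as its accuracy oracle.

    Parameters
    ----------
    pressure : array_like
        Barometric pressure in hPa (default 1013, sea level).
    gamma : float
        Psychrometer constant in K^-1 (default 6.66e-4, Assmann value).
    tol : float
        Bracket half-width at which iteration stops, degC.
    """
    (t, rh, p), scalar = _prepare(temperature, relative_humidity, pressure)
    if np.any((rh <= 0.0) | (rh > 100.0)):
        raise DomainError("relative humidity must lie in (0, 100] %")
    vp = rh / 100.0 * saturation_vapour_pressure(t)
    lo = dew_point(vp) * np.ones_like(t)
    hi = t.copy() if t.ndim else np.array(t, dtype=float)
    lo, hi = np.atleast_1d(lo), np.atleast_1d(hi)
    tt, vv, pp = np.atleast_1d(t), np.atleast_1d(vp), np.atleast_1d(p)

    def residual(tw):
        return (
            saturation_vapour_pressure(tw) - vv - gamma * pp * (tt - tw)
        )

    for _ in range(max_iter):
        if np.all(hi - lo < tol):
            break
        mid = 0.5 * (lo + hi)
        pos = residual(mid) > 0.0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    else:
        if np.any(hi - lo >= tol):
            worst = float(np.max(hi - lo))
            raise ConvergenceError(
                f"wet-bulb bisection did not reach tol={tol} within "
                f"{max_iter} iterations (worst bracket width {worst:.3g} degC)"
            )
    tw = 0.5 * (lo + hi)
    return _ret(tw[0] if scalar else tw.reshape(np.shape(t)), scalar)
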