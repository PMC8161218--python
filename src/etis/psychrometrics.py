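"""Moist-air conversions: saturation vapor pressure, dew point, wet bulb.

The comparison indices consume wet-bulb and dew-point temperatures that barn
sensor loggers do not record directly; this module derives them from dry-bulb
temperature and relative humidity.

Conventions
-----------
* Temperatures in degrees Celsius, vapor pressures in hPa, barometric
  pressure in kPa (default one standard atmosphere).
* Saturation vapor pressure over liquid water uses the Magnus-Tetens form
  ``e_s(T) = 6.1078 * 10^(7.5 T / (237.3 + T))`` — the same constant set that
  appears inside the moist-air enthalpy index, so the two stay consistent.
* The declared validity window is -20..60 degC; outside it the Magnus fit
  degrades and a ``ValueError`` is raised rather than extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MoistAirState",
    "MAGNUS_A",
    "MAGNUS_B",
    "MAGNUS_C",
    "STANDARD_PRESSURE_KPA",
    "saturation_vapor_pressure",
    "vapor_pressure",
    "dew_point",
    "wet_bulb",
]

# Magnus-Tetens constants (hPa / dimensionless / degC), liquid-water branch.
MAGNUS_A = 6.1078
MAGNUS_B = 7.5
MAGNUS_C = 237.3

#: One standard atmosphere, kPa.
STANDARD_PRESSURE_KPA = 101.325

#: Validity window for sensor dry-bulb readings, degC.
T_VALID_MIN = -20.0
T_VALID_MAX = 60.0

#: Wider window for the Magnus curve itself: derived quantities (dew points
#: of very dry air) can fall far below any plausible dry-bulb reading. The
#: curve stays positive and monotone there; -100 degC covers the dew point
#: of every valid state while still rejecting nonsense inputs.
SVP_T_MIN = -100.0
SVP_T_MAX = 60.0

#: Psychrometer coefficient for an unaspirated screen thermometer,
#: degC^-1 (applied to pressure in hPa inside the psychrometer equation).
PSYCHROMETER_COEF = 6.62e-4


@dataclass(frozen=True)
class MoistAirState:
    """A moist-air state point: dry-bulb temperature, RH, pressure.

    Parameters
    ----------
    dry_bulb : float
        Dry-bulb air temperature, degC. Must lie in [-20, 60].
    relative_humidity : float
        Relative humidity in percent, (0, 100].
    pressure_kpa : float
        Barometric pressure, kPa. Defaults to one standard atmosphere.
    """

    dry_bulb: float
    relative_humidity: float
    pressure_kpa: float = field(default=STANDARD_PRESSURE_KPA)

    def __post_init__(self) -> None:
        if not (T_VALID_MIN <= self.dry_bulb <= T_VALID_MAX):
            raise ValueError(
                f"dry_bulb {self.dry_bulb!r} outside validity window "
                f"[{T_VALID_MIN}, {T_VALID_MAX}] degC"
            )
        if not (0.0 < self.relative_humidity <= 100.0):
            raise ValueError(
                f"relative_humidity must be in (0, 100], got {self.relative_humidity!r}"
            )
        if self.pressure_kpa <= 0:
            raise ValueError(f"pressure must be positive, got {self.pressure_kpa!r}")

    @property
    def pressure_hpa(self) -> float:
        return self.pressure_kpa * 10.0

    @property
    def pressure_mmhg(self) -> float:
        """Pressure in mmHg, as consumed by the enthalpy index."""
        return self.pressure_kpa * 760.0 / STANDARD_PRESSURE_KPA


def saturation_vapor_pressure(t):
    """Saturation vapor pressure over liquid water, hPa.

    Magnus-Tetens form; strictly positive and strictly increasing on the
    validity window. Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < SVP_T_MIN) or np.any(t > SVP_T_MAX):
        raise ValueError(
            f"temperature outside Magnus validity window [{SVP_T_MIN}, {SVP_T_MAX}] degC"
        )
    out = MAGNUS_A * 10.0 ** (MAGNUS_B * t / (MAGNUS_C + t))
    return out.item() if out.ndim == 0 else out


def vapor_pressure(t, rh):
    """Actual vapor pressure e = (RH/100) * e_s(T), hPa."""
    rh = np.asarray(rh, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be in (0, 100]")
    e = rh / 100.0 * saturation_vapor_pressure(t)
    return e.item() if np.ndim(e) == 0 else e


def dew_point(state=None, *, t=None, rh=None):
    """Dew-point temperature, degC.

    Analytic inversion of the Magnus curve at the actual vapor pressure:
    ``T_dp = C * g / (B - g)`` with ``g = log10(e / A)``. Satisfies
    ``T_dp <= T`` with equality exactly at RH = 100.

    Accepts either a :class:`MoistAirState` or keyword arrays ``t``/``rh``.
    """
    if state is not None:
        t, rh = state.dry_bulb, state.relative_humidity
    e = np.asarray(vapor_pressure(t, rh), dtype=float)
    g = np.log10(e / MAGNUS_A)
    tdp = MAGNUS_C * g / (MAGNUS_B - g)
    # guard against roundoff pushing T_dp a hair above T at saturation
    tdp = np.minimum(tdp, np.asarray(t, dtype=float))
    return tdp.item() if tdp.ndim == 0 else tdp


def _wet_bulb_psychrometer(t, e, p_hpa, tol=1e-10, max_iter=60):
    """Newton solve of e_s(Tw) - A_psy * p * (T - Tw) = e for Tw.

    The left side is strictly increasing in Tw, so the root is unique and
    bracketed by [T_dp, T]; Newton from T converges in a handful of steps.
    """
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=float)
    tw = t.copy()
    gamma = PSYCHROMETER_COEF * p_hpa
    ln10 = np.log(10.0)
    for _ in range(max_iter):
        es = MAGNUS_A * 10.0 ** (MAGNUS_B * tw / (MAGNUS_C + tw))
        f = es - gamma * (t - tw) - e
        des = es * ln10 * MAGNUS_B * MAGNUS_C / (MAGNUS_C + tw) ** 2
        step = f / (des + gamma)
        tw = tw - step
        if np.max(np.abs(step)) < tol:
            break
    return tw


def _wet_bulb_stull(t, rh):
    """Stull (2011) closed-form wet-bulb approximation (sea level)."""
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    return (
        t * np.arctan(0.151977 * np.sqrt(rh + 8.313659))
        + np.arctan(t + rh)
        - np.arctan(rh - 1.676331)
        + 0.00391838 * rh**1.5 * np.arctan(0.023101 * rh)
        - 4.686035
    )


def wet_bulb(state=None, *, t=None, rh=None, pressure_kpa=STANDARD_PRESSURE_KPA,
             method="psychrometer"):
    """Wet-bulb temperature, degC.

    The default solves the psychrometer equation
    ``e_s(Tw) - gamma * P * (T - Tw) = e`` by vectorized Newton iteration,
    which respects the thermodynamic ordering ``T_dp <= T_wb <= T`` (equality
    at RH = 100) by construction. ``method="stull"`` evaluates the Stull
    (2011) closed-form fit instead — faster but up to ~0.7 degC off the
    psychrometer solution at hot, dry states; its output is clipped into
    [T_dp, T] so the ordering still holds.
    """
    if state is not None:
        t, rh, pressure_kpa = state.dry_bulb, state.relative_humidity, state.pressure_kpa
    t_arr = np.asarray(t, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    e = np.asarray(vapor_pressure(t_arr, rh_arr), dtype=float)
    if method == "psychrometer":
        tw = _wet_bulb_psychrometer(t_arr, e, pressure_kpa * 10.0)
    elif method == "stull":
        tw = _wet_bulb_stull(t_arr, rh_arr)
    else:
        raise ValueError(f"unknown wet-bulb method {method!r}")
    tdp = np.asarray(dew_point(t=t_arr, rh=rh_arr), dtype=float)
    tw = np.clip(tw, tdp, t_arr)
    tw = np.where(rh_arr >= 100.0, t_arr, tw)
    return tw.item() if tw.ndim == 0 else tw
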