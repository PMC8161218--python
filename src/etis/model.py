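"""The equivalent temperature index for sows (ETIS).

ETIS expresses the heat load on a recumbent sow as the dry-bulb air
temperature plus four *equivalent temperatures* — the air-temperature
increments that would produce the same thermal effect as humidity, air
movement, conductive exchange with the floor, and long-wave radiation:

    ETIS = T + T_rh + T_u + T_f + T_r

with

    T_rh = a * (RH - 50) * T
    T_u  = e * u^c * (Ts - T)
    T_f  = D * (Ts - T)                      (floor temperature ~ air temperature)
    T_r  = R_rad * ((Ts + 273.15)^4 - (T + 273.15)^4)

where ``Ts`` is a fixed reference skin temperature (38 degC) and ``c`` is the
convective velocity exponent for a lying sow (0.6827). The fitted index uses
the calibrated coefficient set below, whose conduction term carries a
reference factor: ``T_f = -4.79 * (1.0086 * 38 - T)``.

All temperatures are degC; the Kelvin shift (+273.15) appears only inside the
radiation term. Term functions accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "EnvObservation",
    "ETISParameters",
    "EquivalentTemperatures",
    "FITTED_PARAMETERS",
    "equivalent_temp_humidity",
    "equivalent_temp_velocity",
    "equivalent_temp_conduction",
    "equivalent_temp_radiation",
    "etis_general",
    "etis_fitted",
    "etis_values",
]

KELVIN = 273.15

#: Convective velocity exponent for a recumbent sow.
VELOCITY_EXPONENT = 0.6827

#: Reference skin temperature fixed inside the index, degC.
REFERENCE_SKIN_TEMP = 38.0


@dataclass(frozen=True)
class EnvObservation:
    """One barn climate reading.

    ``floor_temperature`` and ``mean_radiant_temperature`` are optional; when
    absent the air temperature stands in for both, the usual indoor-climate
    assumption for a mechanically ventilated barn.
    """

    air_temperature: float
    relative_humidity: float
    air_velocity: float
    floor_temperature: Optional[float] = None
    mean_radiant_temperature: Optional[float] = None

    def __post_init__(self) -> None:
        if self.air_velocity < 0:
            raise ValueError(f"air_velocity must be >= 0, got {self.air_velocity!r}")
        if not (0.0 <= self.relative_humidity <= 100.0):
            raise ValueError(
                f"relative_humidity must be in [0, 100], got {self.relative_humidity!r}"
            )


@dataclass(frozen=True)
class ETISParameters:
    """Coefficient set defining an ETIS instance.

    Defaults are the fitted index. ``conduction_reference_factor`` multiplies
    the reference skin temperature inside the conduction term only (the fitted
    index uses 1.0086; the general structural form uses 1.0).
    ``radiation_coef_skin`` enables the two-coefficient radiation variant in
    which the skin-side and air-side fourth-power terms carry distinct
    coefficients; when ``None`` a single coefficient applies to both.
    """

    humidity_coef: float = 0.0006
    velocity_coef: float = -0.3132
    velocity_exponent: float = VELOCITY_EXPONENT
    conduction_coef: float = -4.79
    conduction_reference_factor: float = 1.0086
    radiation_coef: float = 4.8957e-8
    radiation_coef_skin: Optional[float] = None
    reference_skin_temp: float = REFERENCE_SKIN_TEMP

    def __post_init__(self) -> None:
        if self.velocity_exponent <= 0:
            raise ValueError("velocity_exponent must be positive")
        if not (30.0 < self.reference_skin_temp < 42.0):
            raise ValueError("reference_skin_temp must lie in (30, 42) degC")


#: The calibrated coefficient set of the final fitted index.
FITTED_PARAMETERS = ETISParameters()


@dataclass(frozen=True)
class EquivalentTemperatures:
    """Decomposition of one ETIS evaluation into its additive terms (degC)."""

    base_t: float
    t_rh: float
    t_u: float
    t_f: float
    t_r: float
    etis: float


def equivalent_temp_humidity(t, rh, a):
    """Humidity equivalent temperature ``a * (RH - 50) * T``.

    Zero at RH = 50; above 50 % humidity adds to the heat load (for a > 0,
    T > 0), below it subtracts.
    """
    t = np.asarray(t, dtype=float)
    out = a * (np.asarray(rh, dtype=float) - 50.0) * t
    return out.item() if out.ndim == 0 else out


def equivalent_temp_velocity(t, u, ts, e, c=VELOCITY_EXPONENT):
    """Air-velocity equivalent temperature ``e * u^c * (Ts - T)``.

    Zero at u = 0 or T = Ts. With e < 0 and air cooler than skin, faster air
    removes more convective heat and the term grows more negative in u.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("air velocity must be >= 0")
    out = e * u**c * (ts - np.asarray(t, dtype=float))
    return out.item() if out.ndim == 0 else out


def equivalent_temp_conduction(t, ts, d, reference_factor=1.0):
    """Floor-conduction equivalent temperature ``D * (factor * Ts - T)``.

    With ``reference_factor=1`` this is the structural form ``D * (Ts - T)``
    (zero at T = Ts); the fitted index uses factor 1.0086.
    """
    out = d * (reference_factor * ts - np.asarray(t, dtype=float))
    return out.item() if out.ndim == 0 else out


def equivalent_temp_radiation(t, ts, r_rad, r_rad_skin=None):
    """Long-wave radiation equivalent temperature.

    Single-coefficient form ``R_rad * ((Ts + 273.15)^4 - (T + 273.15)^4)``;
    odd in the exchange of t and ts, zero at t = ts. If ``r_rad_skin`` is
    given, the skin-side term uses it instead:
    ``r_rad_skin * (Ts + 273.15)^4 - r_rad * (T + 273.15)^4``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= -KELVIN) or ts <= -KELVIN:
        raise ValueError("temperatures must exceed absolute zero")
    skin4 = (ts + KELVIN) ** 4
    air4 = (t + KELVIN) ** 4
    if r_rad_skin is None:
        out = r_rad * (skin4 - air4)
    else:
        out = r_rad_skin * skin4 - r_rad * air4
    return out.item() if out.ndim == 0 else out


def etis_general(obs: EnvObservation, params: ETISParameters) -> EquivalentTemperatures:
    """Evaluate the parameterized index for one observation, term by term.

    Optional floor / mean-radiant temperatures replace the air temperature
    inside the conduction and radiation terms respectively; otherwise the
    air-temperature substitution convention applies. The returned record
    satisfies ``etis = base_t + t_rh + t_u + t_f + t_r`` exactly.
    """
    t = obs.air_temperature
    ts = params.reference_skin_temp
    t_floor = obs.floor_temperature if obs.floor_temperature is not None else t
    t_rad = obs.mean_radiant_temperature if obs.mean_radiant_temperature is not None else t

    t_rh = equivalent_temp_humidity(t, obs.relative_humidity, params.humidity_coef)
    t_u = equivalent_temp_velocity(
        t, obs.air_velocity, ts, params.velocity_coef, params.velocity_exponent
    )
    t_f = equivalent_temp_conduction(
        t_floor, ts, params.conduction_coef, params.conduction_reference_factor
    )
    t_r = equivalent_temp_radiation(
        t_rad, ts, params.radiation_coef, params.radiation_coef_skin
    )
    return EquivalentTemperatures(
        base_t=t, t_rh=t_rh, t_u=t_u, t_f=t_f, t_r=t_r,
        etis=t + t_rh + t_u + t_f + t_r,
    )


def etis_values(t, rh, u, params: ETISParameters = FITTED_PARAMETERS,
                floor_temperature=None, mean_radiant_temperature=None):
    """Vectorized ETIS over arrays of air temperature, RH, and velocity."""
    t = np.asarray(t, dtype=float)
    ts = params.reference_skin_temp
    tf_src = t if floor_temperature is None else np.asarray(floor_temperature, dtype=float)
    tr_src = t if mean_radiant_temperature is None else np.asarray(
        mean_radiant_temperature, dtype=float
    )
    out = (
        t
        + equivalent_temp_humidity(t, rh, params.humidity_coef)
        + equivalent_temp_velocity(t, u, ts, params.velocity_coef, params.velocity_exponent)
        + equivalent_temp_conduction(
            tf_src, ts, params.conduction_coef, params.conduction_reference_factor
        )
        + equivalent_temp_radiation(
            tr_src, ts, params.radiation_coef, params.radiation_coef_skin
        )
    )
    return out.item() if np.ndim(out) == 0 else out


def etis_fitted(obs=None, *, t=None, rh=None, u=None):
    """The fitted index:

    ``ETIS = T + 0.0006 (RH-50) T - 0.3132 u^0.6827 (38 - T)
      - 4.79 (1.0086*38 - T) + 4.8957e-8 ((38+273.15)^4 - (T+273.15)^4)``

    Accepts an :class:`EnvObservation` or keyword scalars/arrays. Identical to
    :func:`etis_general` / :func:`etis_values` with the default parameter set.
    """
    if obs is not None:
        t, rh, u = obs.air_temperature, obs.relative_humidity, obs.air_velocity
    return etis_values(t, rh, u, FITTED_PARAMETERS)
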