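"""Literature thermal indices used to benchmark ETIS.

Eleven published indices — eight temperature-humidity index (THI) variants,
the black-globe humidity index (BGHI), the effective temperature for pigs
(ET), and the moist-air enthalpy (H) — evaluated from the same climate
records as ETIS. Each is computed exactly as its source defines it and
reported on its native scale; Fahrenheit-based variants convert internally
and are never silently rescaled, since their published thresholds (e.g.
THI 74) are scale-specific.

Two rows are typographically corrupt in common reprints and are implemented
in their reconstructed form by default, with a ``strict_paper`` toggle that
evaluates the printed text verbatim:

* ET: default grouping ``T + 0.0015 (RH-50) T - (42 - T) (u^0.66 - 0.2^0.66)``
  (the velocity correction vanishes at the 0.2 m/s reference speed).
* H: default Magnus denominator 237.3 in ``10^(7.5 T / (237.3 + T))``;
  strict mode uses the printed 273.3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import etis_values
from .psychrometrics import STANDARD_PRESSURE_KPA, dew_point, wet_bulb

__all__ = [
    "IndexSpec",
    "REGISTRY",
    "evaluate_index",
    "thi_variant",
    "bghi",
    "effective_temperature",
    "enthalpy_index",
    "list_indices",
]

ET_REFERENCE_VELOCITY = 0.2  # m/s, speed at which the ET wind correction is zero


def _c_to_f(t):
    return 1.8 * np.asarray(t, dtype=float) + 32.0


# --- THI variants (named a..h in the conventional comparison-table order) ---

def _thi_a(t, rh, u, globe, p_kpa, strict):
    return t + 0.36 * wet_bulb(t=t, rh=rh, pressure_kpa=p_kpa) + 41.5


def _thi_b(t, rh, u, globe, p_kpa, strict):
    return 0.8 * t + rh * (t - 14.4) / 100.0 + 46.4


def _thi_c(t, rh, u, globe, p_kpa, strict):
    return 0.65 * t + 0.35 * wet_bulb(t=t, rh=rh, pressure_kpa=p_kpa)


def _thi_d(t, rh, u, globe, p_kpa, strict):
    tf = _c_to_f(t)
    return tf - (0.55 - 0.0055 * rh) * (tf - 58.0)


def _thi_e(t, rh, u, globe, p_kpa, strict):
    return 0.72 * t + 0.72 * wet_bulb(t=t, rh=rh, pressure_kpa=p_kpa) + 40.6


def _thi_f(t, rh, u, globe, p_kpa, strict):
    tf = _c_to_f(t)
    return tf - 0.55 * (rh / 100.0) * (tf - 58.0)


def _thi_g(t, rh, u, globe, p_kpa, strict):
    return t - (0.55 - 0.0055 * rh) * (t - 14.5)


def _thi_h(t, rh, u, globe, p_kpa, strict):
    return 0.27 * t + 1.35 * wet_bulb(t=t, rh=rh, pressure_kpa=p_kpa) + 34.07


def _bghi(t, rh, u, globe, p_kpa, strict):
    tg = t if globe is None else globe
    return np.asarray(tg, dtype=float) + 0.36 * dew_point(t=t, rh=rh) + 41.5


def _et(t, rh, u, globe, p_kpa, strict):
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    u = np.asarray(u, dtype=float)
    wind = u**0.66 - ET_REFERENCE_VELOCITY**0.66
    if strict:
        # printed grouping: + [-1.0*42 - T*(u^0.66 - 0.2^0.66)]
        correction = -1.0 * 42.0 - t * wind
    else:
        correction = -1.0 * (42.0 - t) * wind
    return t + 0.0015 * (rh - 50.0) * t + correction


def _enthalpy(t, rh, u, globe, p_kpa, strict):
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    p_mmhg = np.asarray(p_kpa, dtype=float) * 760.0 / STANDARD_PRESSURE_KPA
    denom = 273.3 if strict else 237.3
    return 1.006 * t + (rh / p_mmhg) * 10.0 ** (7.5 * t / (denom + t)) * (
        71.28 + 0.052 * t
    )


def _etis(t, rh, u, globe, p_kpa, strict):
    return etis_values(t, rh, u)


@dataclass(frozen=True)
class IndexSpec:
    """Registry entry: formula, required inputs, native output scale."""

    name: str
    formula: str
    requires: tuple
    scale: str  # "degC", "degF", "kJ/kg", or "dimensionless"
    fn: Callable


REGISTRY: dict[str, IndexSpec] = {
    spec.name: spec
    for spec in [
        IndexSpec("thi_a", "T + 0.36*Twb + 41.5", ("T", "RH"), "dimensionless", _thi_a),
        IndexSpec(
            "thi_b", "0.8*T + RH*(T - 14.4)/100 + 46.4", ("T", "RH"), "dimensionless", _thi_b
        ),
        IndexSpec("thi_c", "0.65*T + 0.35*Twb", ("T", "RH"), "degC", _thi_c),
        IndexSpec(
            "thi_d",
            "Tf - (0.55 - 0.0055*RH)*(Tf - 58), Tf in degF",
            ("T", "RH"),
            "degF",
            _thi_d,
        ),
        IndexSpec("thi_e", "0.72*T + 0.72*Twb + 40.6", ("T", "RH"), "dimensionless", _thi_e),
        IndexSpec(
            "thi_f",
            "Tf - 0.55*(RH/100)*(Tf - 58), Tf in degF",
            ("T", "RH"),
            "degF",
            _thi_f,
        ),
        IndexSpec(
            "thi_g", "T - (0.55 - 0.0055*RH)*(T - 14.5)", ("T", "RH"), "degC", _thi_g
        ),
        IndexSpec("thi_h", "0.27*T + 1.35*Twb + 34.07", ("T", "RH"), "degC", _thi_h),
        IndexSpec("bghi", "Tg + 0.36*Tdp + 41.5", ("T", "RH", "Tg"), "dimensionless", _bghi),
        IndexSpec(
            "et",
            "T + 0.0015*(RH - 50)*T - (42 - T)*(u^0.66 - 0.2^0.66)",
            ("T", "RH", "u"),
            "degC",
            _et,
        ),
        IndexSpec(
            "h",
            "1.006*T + (RH/Pm)*10^(7.5*T/(237.3 + T))*(71.28 + 0.052*T)",
            ("T", "RH", "P"),
            "kJ/kg",
            _enthalpy,
        ),
        IndexSpec(
            "etis",
            "T + 0.0006*(RH-50)*T - 0.3132*u^0.6827*(38-T) - 4.79*(1.0086*38-T)"
            " + 4.8957e-8*((38+273.15)^4 - (T+273.15)^4)",
            ("T", "RH", "u"),
            "degC",
            _etis,
        ),
    ]
}


def evaluate_index(name, t, rh, u=0.0, globe_temp=None,
                   pressure_kpa=STANDARD_PRESSURE_KPA, strict_paper=False):
    """Evaluate a registered index over scalars or arrays.

    Wet-bulb / dew-point inputs are derived via :mod:`etis.psychrometrics`
    where a variant needs them; the black-globe temperature defaults to the
    dry bulb (indoor mean-radiant assumption) when not supplied.
    """
    try:
        spec = REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; registered: {sorted(REGISTRY)}"
        ) from None
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if "u" in spec.requires and u is None:
        raise ValueError(f"index {name!r} requires air velocity")
    out = spec.fn(t, rh, u, globe_temp, pressure_kpa, strict_paper)
    out = np.asarray(out, dtype=float)
    return out.item() if out.ndim == 0 else out


def thi_variant(name, state):
    """Evaluate one THI variant from a :class:`MoistAirState`."""
    if not (name in REGISTRY and name.startswith("thi")):
        raise KeyError(f"unknown THI variant {name!r}")
    return evaluate_index(
        name, state.dry_bulb, state.relative_humidity, pressure_kpa=state.pressure_kpa
    )


def bghi(state, globe_temp=None):
    """Black-globe humidity index; dry bulb stands in for the globe if absent."""
    return evaluate_index(
        "bghi",
        state.dry_bulb,
        state.relative_humidity,
        globe_temp=globe_temp,
        pressure_kpa=state.pressure_kpa,
    )


def effective_temperature(obs, strict_paper=False):
    """Effective temperature for pigs from an :class:`EnvObservation`."""
    return evaluate_index(
        "et",
        obs.air_temperature,
        obs.relative_humidity,
        u=obs.air_velocity,
        strict_paper=strict_paper,
    )


def enthalpy_index(state, strict_paper=False):
    """Moist-air enthalpy, kJ per kg dry air, from a :class:`MoistAirState`."""
    return evaluate_index(
        "h",
        state.dry_bulb,
        state.relative_humidity,
        pressure_kpa=state.pressure_kpa,
        strict_paper=strict_paper,
    )


def list_indices():
    """Registry summary: name, required inputs, native scale, formula."""
    return [
        {
            "name": s.name,
            "requires": list(s.requires),
            "scale": s.scale,
            "formula": s.formula,
        }
        for s in REGISTRY.values()
    ]
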