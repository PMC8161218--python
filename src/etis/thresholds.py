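"""Heat-stress categories for ETIS, anchored to published THI thresholds.

Sow-pregnancy studies attach heat-stress categories to the
temperature-humidity index: suitable below THI 74, mild 74-78, moderate
78-82, severe above 82. Because ETIS correlates tightly and linearly with
THI on barn data, those breakpoints transfer to the ETIS scale through the
fitted line ``ETIS = 0.3533 * THI + 6.9249``, giving category boundaries
33.1 / 34.5 / 35.9 degC after rounding to one decimal. Intervals are
lower-inclusive: a reading exactly on a boundary belongs to the hotter
category.

Breakpoints and the mapping line are configuration, not constants — genotype
and region shift the THI thresholds, and any (thi, etis) sample can refit
the map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np
from scipy import stats

__all__ = [
    "StressCategory",
    "ThresholdMap",
    "PAPER_THRESHOLD_MAP",
    "DEFAULT_THI_BREAKPOINTS",
    "fit_thi_etis_map",
    "map_thi_to_etis",
    "derive_thresholds",
    "classify",
    "classify_series",
]

DEFAULT_THI_BREAKPOINTS = (74.0, 78.0, 82.0)


class StressCategory(IntEnum):
    """Ordered heat-stress levels."""

    SUITABLE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass(frozen=True)
class ThresholdMap:
    """Affine THI-to-ETIS map plus category breakpoints on both scales."""

    slope: float
    intercept: float
    thi_breakpoints: tuple = DEFAULT_THI_BREAKPOINTS
    etis_breakpoints: tuple | None = None
    rounding: int = 1
    r_squared: float | None = None

    def __post_init__(self) -> None:
        for bps in (self.thi_breakpoints, self.etis_breakpoints):
            if bps is not None and not all(x < y for x, y in zip(bps, bps[1:])):
                raise ValueError(f"breakpoints must be strictly increasing: {bps}")


#: The published THI-to-ETIS line (Fig.-scale slope/intercept).
PAPER_THRESHOLD_MAP = ThresholdMap(slope=0.3533, intercept=6.9249)


def fit_thi_etis_map(thi, etis) -> ThresholdMap:
    """Ordinary least-squares line of ETIS on THI."""
    thi = np.asarray(thi, dtype=float)
    etis = np.asarray(etis, dtype=float)
    if thi.shape != etis.shape or thi.size < 3:
        raise ValueError("need aligned series with at least 3 points")
    if np.std(thi) == 0:
        raise ValueError("THI series has zero variance; line is undefined")
    res = stats.linregress(thi, etis)
    return ThresholdMap(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def map_thi_to_etis(thi, threshold_map: ThresholdMap = PAPER_THRESHOLD_MAP):
    """Apply the affine THI-to-ETIS map (no rounding)."""
    out = threshold_map.slope * np.asarray(thi, dtype=float) + threshold_map.intercept
    return out.item() if out.ndim == 0 else out


def derive_thresholds(threshold_map: ThresholdMap = PAPER_THRESHOLD_MAP) -> ThresholdMap:
    """Map the THI breakpoints through the line and round to the configured
    decimal, yielding the ETIS-scale category boundaries."""
    mapped = tuple(
        round(float(map_thi_to_etis(bp, threshold_map)), threshold_map.rounding)
        for bp in threshold_map.thi_breakpoints
    )
    return replace(threshold_map, etis_breakpoints=mapped)


def classify(etis_value: float, threshold_map: ThresholdMap) -> StressCategory:
    """Assign one ETIS reading to a stress category.

    Boundaries are lower-inclusive: ``etis == breakpoint`` falls in the hotter
    category, matching the published interval notation.
    """
    if threshold_map.etis_breakpoints is None:
        raise ValueError("threshold map has no ETIS breakpoints; run derive_thresholds")
    if not np.isfinite(etis_value):
        raise ValueError(f"cannot classify non-finite value {etis_value!r}")
    b1, b2, b3 = threshold_map.etis_breakpoints
    if etis_value < b1:
        return StressCategory.SUITABLE
    if etis_value < b2:
        return StressCategory.MILD
    if etis_value < b3:
        return StressCategory.MODERATE
    return StressCategory.SEVERE


def classify_series(etis, threshold_map: ThresholdMap) -> np.ndarray:
    """Vectorized :func:`classify`; returns an array of category names."""
    etis = np.asarray(etis, dtype=float)
    if not np.all(np.isfinite(etis)):
        raise ValueError("cannot classify non-finite values")
    if threshold_map.etis_breakpoints is None:
        raise ValueError("threshold map has no ETIS breakpoints; run derive_thresholds")
    level = np.searchsorted(np.asarray(threshold_map.etis_breakpoints), etis, side="right")
    names = np.array([c.name.lower() for c in StressCategory])
    return names[level]
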