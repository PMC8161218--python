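"""Calibration of the index coefficients against skin temperature.

The coefficients of the equivalent-temperature terms are estimated by linear
regression of observed skin temperature on the transformed climate features

    y = b0 + b1*T + b2*(50*T) + b3*(RH*T) + b4*u^0.6827*(38 - T)
        + b5*38 + b6*T + b7*(38 + 273.15)^4 + b8*(T + 273.15)^4

with the reference skin temperature fixed at 38 degC. This design is
rank-deficient *by construction*: the two T columns are identical, 50*T is
proportional to T, and two columns are constants alongside the intercept.
The solver therefore uses a minimum-norm SVD least-squares contract —
individual coefficients are not unique, but fitted values are, and the
identifiable coefficient combinations (the RH*T, velocity, and air-side
radiation columns, plus the pooled T-linear and constant masses) are what
:func:`assemble_etis_from_fit` maps back onto index parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import REGISTRY, evaluate_index
from .model import ETISParameters, FITTED_PARAMETERS, KELVIN, VELOCITY_EXPONENT

__all__ = [
    "DESIGN_COLUMNS",
    "RegressionFit",
    "build_design_matrix",
    "split_train_test",
    "fit_least_squares",
    "assemble_etis_from_fit",
    "pearson_r",
    "compare_indices",
]

TS_REF = 38.0

DESIGN_COLUMNS = [
    "intercept",
    "T",
    "50T",
    "RH_T",
    "u_pow_Ts_minus_T",
    "const_Ts",
    "T_dup",
    "const_Ts_K4",
    "T_K4",
]


def build_design_matrix(t, rh=None, u=None, ts: float = TS_REF) -> pd.DataFrame:
    """Assemble the nine-column regression design from climate arrays.

    Column order is fixed: [1, T, 50*T, RH*T, u^0.6827*(Ts - T), Ts, T,
    (Ts + 273.15)^4, (T + 273.15)^4]. Accepts equal-length arrays (or a
    DataFrame with air_temperature_C / relative_humidity_pct /
    air_velocity_ms columns).
    """
    if isinstance(t, pd.DataFrame):
        df = t
        t = df["air_temperature_C"].to_numpy()
        rh = df["relative_humidity_pct"].to_numpy()
        u = df["air_velocity_ms"].to_numpy()
    t = np.atleast_1d(np.asarray(t, dtype=float))
    rh = np.atleast_1d(np.asarray(rh, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if t.size == 0:
        raise ValueError("empty observation collection")
    if not (t.shape == rh.shape == u.shape):
        raise ValueError("t, rh, u must have equal lengths")
    n = t.size
    cols = np.column_stack(
        [
            np.ones(n),
            t,
            50.0 * t,
            rh * t,
            u**VELOCITY_EXPONENT * (ts - t),
            np.full(n, ts),
            t,
            np.full(n, (ts + KELVIN) ** 4),
            (t + KELVIN) ** 4,
        ]
    )
    return pd.DataFrame(cols, columns=DESIGN_COLUMNS)


def split_train_test(records, fraction: float = 0.7, seed: int = 0):
    """Random, seeded, disjoint-and-exhaustive train/test partition.

    Training size is ``round(n * fraction)`` — 1029 records at 0.7 give the
    720 / 309 partition. Works on a DataFrame (rows) or an integer-indexable
    array; refuses datasets smaller than 10 records.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    n_train = int(round(n * fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if isinstance(records, pd.DataFrame):
        return records.iloc[train_idx], records.iloc[test_idx]
    records = np.asarray(records)
    return records[train_idx], records[test_idx]


@dataclass
class RegressionFit:
    """Minimum-norm least-squares fit of the rank-deficient design.

    ``coefficients`` is the minimum-norm solution in the *column-scaled*
    problem mapped back to original units: one valid solution among the
    infinitely many that share identical fitted values.
    """

    coefficients: pd.Series
    rank: int
    singular_values: np.ndarray
    condition: float
    n_train: int
    column_scale: np.ndarray = field(repr=False)
    split_seed: int | None = None
    n_test: int | None = None

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        return x.to_numpy(dtype=float) @ self.coefficients.to_numpy()

    def r_squared(self, x: pd.DataFrame, y) -> float:
        """Squared Pearson correlation of observed vs predicted."""
        y = np.asarray(y, dtype=float)
        yhat = self.predict(x)
        if np.std(y) == 0 or np.std(yhat) == 0:
            raise ValueError("R^2 undefined: constant observed or predicted series")
        return float(stats.pearsonr(y, yhat).statistic ** 2)


def fit_least_squares(x: pd.DataFrame, y, split_seed=None, n_test=None) -> RegressionFit:
    """Minimum-norm least squares of a response on the design matrix.

    Columns are scaled to unit norm before the SVD solve (the raw design mixes
    scales from 1 to ~1e10, which would otherwise swamp the small-singular-
    value cutoff); coefficients are mapped back afterwards. Exact collinearity
    is absorbed into the reported rank rather than raised as an error.
    """
    a = x.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if a.shape[0] != y.shape[0]:
        raise ValueError("design and response lengths differ")
    if a.shape[0] <= a.shape[1]:
        raise ValueError("need more rows than columns")
    scale = np.linalg.norm(a, axis=0)
    scale[scale == 0] = 1.0
    beta_s, _, rank, sv = np.linalg.lstsq(a / scale, y, rcond=1e-10)
    beta = beta_s / scale
    nonzero = sv[sv > 0]
    cond = float(nonzero[0] / nonzero[-1]) if nonzero.size else np.inf
    return RegressionFit(
        coefficients=pd.Series(beta, index=list(x.columns)),
        rank=int(rank),
        singular_values=sv,
        condition=cond,
        n_train=a.shape[0],
        column_scale=scale,
        split_seed=split_seed,
        n_test=n_test,
    )


def assemble_etis_from_fit(fit: RegressionFit, convention: str = "paper"):
    """Turn a regression fit into an :class:`ETISParameters` set.

    convention="paper"
        Return the canonical fitted constant set verbatim (the published
        final index; its conduction constants are not reconstructable from
        any coefficient ratio rule).
    convention="direct"
        Map the identifiable coefficient combinations onto parameters:
        ``a = b3``, ``e = b4``, ``R_rad = -b8``, pooled T-linear mass
        ``b1 + 50*b2 + b6 = 1 - 50a - D`` giving ``D``, and the pooled
        constant mass giving the conduction reference factor. Returns
        ``(params, mapping)`` where ``mapping`` documents the rule. The
        assembled index reproduces the fit's predictions whenever the
        generating response is itself index-structured.
    """
    if convention == "paper":
        return FITTED_PARAMETERS
    if convention != "direct":
        raise ValueError(f"unknown convention {convention!r}")
    b = fit.coefficients
    a = float(b["RH_T"])
    e = float(b["u_pow_Ts_minus_T"])
    r_rad = float(-b["T_K4"])
    r_rad_skin = float(b["const_Ts_K4"])
    beta_t = float(b["T"] + 50.0 * b["50T"] + b["T_dup"])
    d = 1.0 - 50.0 * a - beta_t
    beta_0 = float(
        b["intercept"] + TS_REF * b["const_Ts"] + b["const_Ts_K4"] * (TS_REF + KELVIN) ** 4
    )
    conduction_const = beta_0 - r_rad * (TS_REF + KELVIN) ** 4
    factor = conduction_const / (d * TS_REF) if abs(d) > 1e-12 else 1.0
    params = ETISParameters(
        humidity_coef=a,
        velocity_coef=e,
        conduction_coef=d,
        conduction_reference_factor=factor,
        radiation_coef=r_rad,
    )
    mapping = {
        "a": "b[RH_T]",
        "e": "b[u_pow_Ts_minus_T]",
        "R_rad": "-b[T_K4]",
        "D": "1 - 50a - (b[T] + 50 b[50T] + b[T_dup])",
        "reference_factor": "(pooled constant - R_rad*(Ts+273.15)^4) / (D*Ts)",
        "b7_skin_side": r_rad_skin,
    }
    return params, mapping


def pearson_r(a, b) -> float:
    """Pearson correlation; refuses series shorter than 3 or of zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson r undefined for zero-variance series")
    return float(stats.pearsonr(a, b).statistic)


def compare_indices(env: pd.DataFrame, physio, registry=None,
                    strict_paper=False) -> pd.DataFrame:
    """Pearson correlation of every registered index against a physiological
    series, sorted descending — the index-benchmarking table.

    ``env`` must carry air_temperature_C, relative_humidity_pct,
    air_velocity_ms columns aligned with ``physio``.
    """
    registry = REGISTRY if registry is None else registry
    physio = np.asarray(physio, dtype=float)
    if len(env) != physio.size:
        raise ValueError("environment and physiology records are not aligned")
    t = env["air_temperature_C"].to_numpy(dtype=float)
    rh = env["relative_humidity_pct"].to_numpy(dtype=float)
    u = env["air_velocity_ms"].to_numpy(dtype=float)
    rows = []
    for name, spec in registry.items():
        values = evaluate_index(name, t, rh, u=u, strict_paper=strict_paper)
        rows.append(
            {
                "index": name,
                "pearson_r": pearson_r(values, physio),
                "n": physio.size,
                "scale": spec.scale,
            }
        )
    report = pd.DataFrame(rows).sort_values("pearson_r", ascending=False)
    return report.reset_index(drop=True)
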