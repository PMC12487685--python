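"""Protein turnover from cycloheximide-chase densitometry.

Band intensities are normalized to a loading control (GAPDH by default)
and expressed as percent of the time-0 value; an optional exponential
decay fit summarizes the series as a degradation rate / half-life.
Proteasome-inhibitor experiments are reported as fold changes of
normalized intensity over the vehicle condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["DecayFit", "percent_remaining", "fit_decay", "inhibitor_fold_change"]

#: below this fitted rate (per hour) a series is reported as non-decaying
_ZERO_RATE = 1e-9


@dataclass(frozen=True)
class DecayFit:
    rate_per_h: float
    half_life_h: float
    residual_norm: float

    @property
    def decaying(self) -> bool:
        return self.rate_per_h > _ZERO_RATE


def percent_remaining(
    series: pd.DataFrame,
    time_col: str = "time_h",
    band_col: str = "band",
    control_col: str = "control",
) -> pd.DataFrame:
    """Loading-control-normalized intensities as percent of time 0.

    normalized = band / control; percent(t) = 100 * normalized(t) /
    normalized(0). Invariant to any common rescaling of the band and
    control lanes (exposure, gain).
    """
    t = series[time_col].to_numpy(dtype=float)
    band = series[band_col].to_numpy(dtype=float)
    ctrl = series[control_col].to_numpy(dtype=float)
    if np.any(ctrl <= 0):
        raise ValueError("loading-control intensities must be strictly positive")
    norm = band / ctrl
    at_zero = norm[t == 0]
    if at_zero.size == 0:
        raise ValueError("series must contain a time-0 measurement")
    baseline = float(at_zero.mean())
    if baseline <= 0:
        raise ValueError("time-0 normalized intensity must be positive")
    out = series.copy()
    out["normalized"] = norm
    out["percent_remaining"] = 100.0 * norm / baseline
    return out


def average_technical_replicates(
    table: pd.DataFrame,
    by: tuple[str, ...] = ("replicate", "species", "time_h"),
    value_cols: tuple[str, ...] = ("band", "control"),
) -> pd.DataFrame:
    """Collapse technical replicates to their mean before statistics."""
    return table.groupby(list(by), as_index=False)[list(value_cols)].mean()


def fit_decay(time_h: np.ndarray, percent: np.ndarray) -> DecayFit:
    """Least-squares fit of a single-exponential decay to a percent series.

    Model: ``100 * 2**(-t / half_life)``, i.e. ``100 * exp(-k t)`` with
    ``k = ln2 / half_life >= 0``. A flat series returns rate 0 and an
    infinite half-life. Deterministic given the data.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(percent, dtype=float)
    if t.size < 3:
        raise ValueError("decay fit needs at least 3 time points")

    def model(tt: np.ndarray, k: float) -> np.ndarray:
        return 100.0 * np.exp(-k * tt)

    # linearized initial guess on positive values
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        k0 = max(0.0, float(-np.polyfit(t[pos], np.log(y[pos] / 100.0), 1)[0]))
    else:
        k0 = 0.0
    (k,), _ = curve_fit(model, t, y, p0=[k0], bounds=(0.0, np.inf), maxfev=10000)
    resid = float(np.linalg.norm(y - model(t, k)))
    if k <= _ZERO_RATE:
        return DecayFit(0.0, float("inf"), resid)
    return DecayFit(float(k), float(np.log(2.0) / k), resid)


def inhibitor_fold_change(treated_normalized: float, vehicle_normalized: float):
    """Fold change of normalized band intensity over the vehicle condition."""
    treated = np.asarray(treated_normalized, dtype=float)
    vehicle = np.asarray(vehicle_normalized, dtype=float)
    if np.any(vehicle <= 0):
        raise ValueError("vehicle normalized intensity must be strictly positive")
    fold = treated / vehicle
    return float(fold) if fold.ndim == 0 else fold
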