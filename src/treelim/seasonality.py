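"""Rainfall-seasonality metrics computed from daily or monthly precipitation.

Four proxies for how concentrated rainfall is within the year, each on
[0, 1]:

* ``madd``  — fractional mean annual dry days (daily input);
* ``mddm``  — dry-day fraction of the driest month (daily input);
* ``madm``  — minimum monthly precipitation normalised by the monthly mean
  (1 means perfectly uniform months, so the *seasonality* driver is usually
  taken as ``1 - madm``; the raw metric is returned here);
* ``mconc`` — seasonal concentration index: the length of the vector sum of
  monthly totals placed around the annual cycle, normalised by total
  rainfall (0 for uniform rain, 1 when all rain falls in one month).

All functions are vectorised over trailing axes: the leading axis is time
(days or months) and any remaining axes index cells.
"""

from __future__ import annotations

import numpy as np

from .grids import GriddedField

__all__ = [
    "MONTH_LENGTHS",
    "month_angles",
    "madd",
    "mddm",
    "madm",
    "mconc",
    "metric_field",
]

#: days per calendar month of a 365-day year
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

DEFAULT_WET_DAY_THRESHOLD = 0.1  # mm/day


def month_angles() -> np.ndarray:
    """Direction of each month on the annual cycle, at month mid-points.

    Month m (1-based) maps to 2*pi*(m - 0.5)/12.  Any fixed convention
    leaves the concentration index invariant to rotation of the year.
    """
    m = np.arange(1, 13)
    return 2.0 * np.pi * (m - 0.5) / 12.0


def _validate_precip(pr: np.ndarray, what: str) -> np.ndarray:
    pr = np.asarray(pr, dtype=float)
    if np.any(pr < 0):
        raise ValueError(f"{what} precipitation contains negative values")
    return pr


def madd(pr_daily: np.ndarray, threshold: float = DEFAULT_WET_DAY_THRESHOLD) -> np.ndarray:
    """Fraction of days with precipitation below the wet-day threshold."""
    pr = _validate_precip(pr_daily, "daily")
    if pr.shape[0] < 1:
        raise ValueError("need at least one day")
    return np.mean(pr < threshold, axis=0)


def mddm(pr_daily: np.ndarray, threshold: float = DEFAULT_WET_DAY_THRESHOLD,
         driest: bool = True) -> np.ndarray:
    """Dry-day fraction of the driest month.

    Days are assigned to calendar months of a 365-day year.  ``driest=True``
    picks the month with the largest dry-day fraction (fewest wet days);
    ``driest=False`` keeps the literal smallest-dry-day-count month for
    comparison.
    """
    pr = _validate_precip(pr_daily, "daily")
    ndays = pr.shape[0]
    if ndays % 365 != 0:
        raise ValueError("daily series length must be a multiple of 365")
    doy_month = np.repeat(np.arange(12), MONTH_LENGTHS)
    dry = (pr < threshold).reshape(ndays // 365, 365, *pr.shape[1:])
    monthly = np.empty((12, *pr.shape[1:]))
    for m in range(12):
        monthly[m] = dry[:, doy_month == m].mean(axis=(0, 1))
    return monthly.max(axis=0) if driest else monthly.min(axis=0)


def madm(pr_monthly: np.ndarray) -> np.ndarray:
    """Minimum monthly precipitation times 12 over annual precipitation.

    Cells with zero annual precipitation return 0 by convention (the MAP
    control already drives tree cover to zero there).
    """
    pr = _validate_precip(pr_monthly, "monthly")
    if pr.shape[0] != 12:
        raise ValueError("monthly climatology must have 12 entries on the leading axis")
    total = pr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, pr.min(axis=0) * 12.0 / np.where(total > 0, total, 1.0), 0.0)
    return out


def mconc(pr_monthly: np.ndarray) -> np.ndarray:
    """Seasonal concentration of precipitation.

    Each month's total is a vector with direction theta_m on the annual
    circle; the index is the magnitude of the vector sum divided by total
    rainfall.  Zero-rain cells return 0 by convention.
    """
    pr = _validate_precip(pr_monthly, "monthly")
    if pr.shape[0] != 12:
        raise ValueError("monthly climatology must have 12 entries on the leading axis")
    theta = month_angles().reshape((12,) + (1,) * (pr.ndim - 1))
    lx = np.sum(pr * np.cos(theta), axis=0)
    ly = np.sum(pr * np.sin(theta), axis=0)
    total = pr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, np.hypot(lx, ly) / np.where(total > 0, total, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0)


def metric_field(metric: str, pr: np.ndarray, template: GriddedField,
                 **kwargs) -> GriddedField:
    """Compute a named metric on a (time, lat, lon) stack as a GriddedField.

    ``metric`` is one of ``madd``, ``mddm``, ``madm``, ``mconc``; the
    template supplies the grid and mask.
    """
    funcs = {"madd": madd, "mddm": mddm, "madm": madm, "mconc": mconc}
    if metric not in funcs:
        raise ValueError(f"unknown seasonality metric {metric!r}")
    values = funcs[metric](pr, **kwargs)
    if values.shape != template.shape:
        raise ValueError("metric output does not match the template grid")
    return template.with_values(values, name=metric, units="1")
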