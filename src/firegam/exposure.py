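"""Exposure construction: distributed-lag smoothing of fire PM, spatial
interpolation of station weather, population-weighted aggregation, and the
concurvity screen that collapses the two fire-PM size classes.

The cumulative-exposure model is a truncated half-Gaussian kernel over the
current and previous days: weight at lag k is proportional to
``exp(-k^2 / (2 * scale^2))``, truncated at ``max_lag`` and normalized to sum
to one.  Lag 0 (the day itself) always carries the largest weight, and weights
decay monotonically, encoding both cumulative dose and delay in seeking care.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LagKernel",
    "half_gaussian_kernel",
    "apply_lag_kernel",
    "haversine_m",
    "idw_interpolate",
    "population_weighted_aggregate",
    "merge_pm_classes",
    "MergeReport",
]

_EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class LagKernel:
    """Nonnegative, normalized, nonincreasing lag weights."""

    scale: float
    max_lag: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != self.max_lag + 1:
            raise ValueError("weights must have length max_lag + 1")
        if np.any(w < 0):
            raise ValueError("kernel weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("kernel weights must sum to 1")
        if np.any(np.diff(w) > 1e-12):
            raise ValueError("kernel weights must be nonincreasing in lag")
        object.__setattr__(self, "weights", w)


def half_gaussian_kernel(scale: float = 1.0, max_lag: int = 3) -> LagKernel:
    """Truncated half-Gaussian lag kernel with its mode at lag 0.

    Parameters
    ----------
    scale
        Standard deviation of the Gaussian, in days.  ``scale=0`` is the
        degenerate kernel placing all weight on the current day.
    max_lag
        Truncation lag L; weights cover lags 0..L.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    lags = np.arange(max_lag + 1, dtype=float)
    if scale == 0:
        w = np.zeros(max_lag + 1)
        w[0] = 1.0
    else:
        w = np.exp(-(lags**2) / (2.0 * scale**2))
        w = w / w.sum()
    return LagKernel(scale=scale, max_lag=max_lag, weights=w)


def apply_lag_kernel(values: np.ndarray, kernel: LagKernel) -> np.ndarray:
    """Convolve a daily series with the lag kernel.

    ``exposure[t] = sum_k w_k * values[t-k]``.  For the first ``max_lag`` days,
    where not all lags exist yet, the available weights are renormalized to sum
    to one so a constant series maps to itself everywhere (unbiased edge rule).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("series must be a nonempty 1-d array")
    w = kernel.weights
    L = kernel.max_lag
    # full convolution, then fix the ramp-up edge by renormalizing
    out = np.convolve(x, w)[: len(x)]
    for t in range(min(L, len(x) - 1) + 1):
        avail = w[: t + 1]
        out[t] = avail @ x[t::-1][: t + 1] / avail.sum()
    return out


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in meters between lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def idw_interpolate(
    station_coords: np.ndarray,
    station_values: np.ndarray,
    target_coords: np.ndarray,
    power: float = 2.0,
    coincident_tol_m: float = 1.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of station values to targets.

    Coordinates are (lon, lat) pairs in degrees; distances are great-circle.
    A target within ``coincident_tol_m`` of a station returns that station's
    value exactly.  Output is bounded by the min/max station value.
    """
    sc = np.atleast_2d(np.asarray(station_coords, dtype=float))
    sv = np.atleast_1d(np.asarray(station_values, dtype=float))
    tc = np.atleast_2d(np.asarray(target_coords, dtype=float))
    if len(sc) == 0:
        raise ValueError("at least one station is required")
    if len(sc) != len(sv):
        raise ValueError("station coords and values must align")
    if power <= 0:
        raise ValueError("power must be > 0")
    out = np.empty(len(tc))
    for i, (lon, lat) in enumerate(tc):
        d = haversine_m(sc[:, 0], sc[:, 1], lon, lat)
        nearest = int(np.argmin(d))
        if d[nearest] < coincident_tol_m:
            out[i] = sv[nearest]
            continue
        w = d ** (-power)
        out[i] = (w @ sv) / w.sum()
    return out


def population_weighted_aggregate(
    zip_values: dict,
    zip_populations: dict,
    region_map: dict,
) -> dict:
    """Aggregate zip-level values to regions by population weighting.

    ``region value = sum(pop_z * v_z) / sum(pop_z)`` over the member zips.
    Every zip in ``region_map`` must have a value and a positive population.
    """
    acc: dict = {}
    for z, region in region_map.items():
        if z not in zip_values:
            raise KeyError(f"zip {z!r} has no value")
        if z not in zip_populations:
            raise KeyError(f"zip {z!r} has no population")
        pop = zip_populations[z]
        if pop <= 0:
            raise ValueError(f"zip {z!r} has nonpositive population")
        num, den = acc.get(region, (0.0, 0.0))
        acc[region] = (num + pop * np.asarray(zip_values[z], dtype=float), den + pop)
    return {r: num / den for r, (num, den) in acc.items()}


@dataclass
class MergeReport:
    """Outcome of the PM2.5/PM10 concurvity screen."""

    correlation: float
    merged: bool
    degenerate: bool = False
    note: str = ""


def merge_pm_classes(
    pm25: np.ndarray,
    pm10: np.ndarray,
    corr_threshold: float = 0.95,
):
    """Collapse the fire PM2.5/PM10 pair into one variable when concurve.

    PM10 includes PM2.5 by definition, so over short transport distances the
    two series are nearly proportional and statistically indistinguishable.
    If their Pearson correlation is at or above ``corr_threshold`` the PM10
    series is retained as the single fire-PM variable.  A degenerate pair
    (either series constant, correlation undefined) is treated as merged and
    flagged.  Below threshold both series are returned with a warning flag.

    Returns ``(series_or_pair, MergeReport)``.
    """
    a = np.asarray(pm25, dtype=float)
    b = np.asarray(pm10, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series length mismatch")
    if a.std() == 0 or b.std() == 0:
        report = MergeReport(correlation=float("nan"), merged=True, degenerate=True,
                             note="constant series; correlation undefined, merged by definition")
        return b, report
    r = float(np.corrcoef(a, b)[0, 1])
    if r >= corr_threshold:
        return b, MergeReport(correlation=r, merged=True)
    return (a, b), MergeReport(correlation=r, merged=False,
                               note="below concurvity threshold; classes kept separate")
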