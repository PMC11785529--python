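"""Reduction of raw series to the analysis-ready form.

Covers: resampling sub-annual series to annual means with a coverage
gate, mean-normalisation (so trends read as fractional change per year),
mixed-layer depth from density profiles under the 0.03 kg m⁻³ / 10 m
reference criterion, and cos(latitude) area weights.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import xarray as xr

from .errors import ValidationError
from .grid import GridSpec

__all__ = [
    "annual_mean",
    "mean_normalise",
    "density_eos80",
    "linear_eos",
    "mld_from_profiles",
    "area_weights",
]

#: relative tolerance below which a series mean counts as zero
ZERO_MEAN_RTOL = 1e-12


def annual_mean(series: xr.DataArray, min_frac: float = 0.5) -> xr.DataArray:
    """Unweighted annual means of a sub-annual (8-day or monthly) series.

    Per pixel and year, the mean of the available samples is taken; the
    year is flagged missing (NaN) when the available fraction of that
    year's time steps falls below ``min_frac`` (boundary inclusive).
    Input must carry a datetime64 ``time`` dimension; output carries an
    integer ``year`` dimension.  Annual input (a ``year`` dimension) is
    returned unchanged — the operation is idempotent.
    """
    if "year" in series.dims:
        return series.copy()
    if "time" not in series.dims:
        raise ValidationError("series must have a 'time' or 'year' dimension")
    if series.sizes["time"] == 0:
        raise ValidationError("empty time axis")
    years = series["time"].dt.year
    grouped = series.groupby(years.rename("year"))
    mean = grouped.mean(skipna=True)
    n_present = series.notnull().groupby(years.rename("year")).sum()
    n_total = xr.ones_like(series["time"], dtype=float).groupby(years.rename("year")).sum()
    frac = n_present / n_total
    out = mean.where(frac >= min_frac)
    out.attrs.update(series.attrs)
    return out


def mean_normalise(values: np.ndarray) -> np.ndarray:
    """Divide a 1-D series by its mean (over available values).

    Output has mean exactly 1 up to rounding and preserves shape and
    missingness.  A mean within ``ZERO_MEAN_RTOL × max|value|`` of zero
    is an undefined normalisation: the sentinel (all-NaN) is returned.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        return np.full_like(values, np.nan)
    m = values[finite].mean()
    scale = np.abs(values[finite]).max()
    if abs(m) <= ZERO_MEAN_RTOL * max(scale, 1.0):
        return np.full_like(values, np.nan)
    return values / m


def density_eos80(temperature: np.ndarray, salinity: np.ndarray) -> np.ndarray:
    """Surface seawater density (kg m⁻³) from the one-atmosphere
    International Equation of State of Seawater (Millero & Poisson 1981).

    temperature in °C, practical salinity dimensionless.  Valid for the
    oceanographic range (−2…40 °C, 0…42).  Serves as the default
    equation of state; any callable (T, S) → ρ may be substituted.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


def linear_eos(temperature: np.ndarray, salinity: np.ndarray) -> np.ndarray:
    """Linear test equation of state: ρ = 1027 − 0.2·T + 0.8·S (kg m⁻³)."""
    return 1027.0 - 0.2 * np.asarray(temperature) + 0.8 * np.asarray(salinity)


def mld_from_profiles(
    temperature: np.ndarray,
    salinity: np.ndarray,
    depths: np.ndarray,
    equation_of_state: Callable[[np.ndarray, np.ndarray], np.ndarray] = density_eos80,
    reference_depth: float = 10.0,
    criterion: float = 0.03,
) -> tuple[float, bool]:
    """Mixed-layer depth from a single T/S profile.

    Density is computed level-by-level by ``equation_of_state``; the MLD
    is the depth at which density first exceeds the density at the
    reference depth (default 10 m) by ``criterion`` (default
    0.03 kg m⁻³), linearly interpolated in density between the
    bracketing levels.  The reference density itself is linearly
    interpolated when no level sits exactly at the reference depth.

    Returns ``(mld, resolved)``; when the profile never exceeds the
    threshold the deepest level is returned with ``resolved=False``.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.ndim != 1 or np.any(np.diff(depths) <= 0):
        raise ValidationError("depths must be 1-D and strictly increasing")
    if depths[0] > reference_depth or depths[-1] < reference_depth:
        raise ValidationError(
            f"depth levels must bracket the reference depth {reference_depth} m"
        )
    rho = np.asarray(equation_of_state(temperature, salinity), dtype=float)
    if rho.shape != depths.shape:
        raise ValidationError("profile and depth shapes differ")

    rho_ref = float(np.interp(reference_depth, depths, rho))
    threshold = rho_ref + criterion

    below = depths >= reference_depth
    d = depths[below]
    r = rho[below]
    exceeds = r >= threshold
    if not exceeds.any():
        return float(depths[-1]), False
    j = int(np.argmax(exceeds))
    if r[j] == threshold or j == 0:
        return float(d[j]), True
    # linear interpolation in density between bracketing levels
    frac = (threshold - r[j - 1]) / (r[j] - r[j - 1])
    return float(d[j - 1] + frac * (d[j] - d[j - 1])), True


def area_weights(grid: GridSpec) -> np.ndarray:
    """Normalised cos(latitude) area weights over ocean cells.

    Returns an array of the grid's shape: weights over ocean cells sum to
    one and decrease with |latitude|; land cells carry zero.  A regular
    grid is assumed, for which cell area is proportional to cos(lat).
    """
    w = np.cos(np.deg2rad(grid.lat))[:, None] * np.ones((1, grid.lon.size))
    w = np.where(grid.ocean_mask, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValidationError("grid has no ocean cells to weight")
    return w / total
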