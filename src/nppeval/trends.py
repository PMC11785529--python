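"""Per-pixel and regional trend estimation.

The per-pixel rule mirrors standard practice for satellite time series:
pixels with under half their years available are excluded; series that
pass a D'Agostino–Pearson normality check get a robust Huber linear fit
(ε = 1.35, the value giving 95 % Gaussian efficiency), with pixels
dropped when outlier down-weighting leaves fewer than half the years;
series failing the normality check get the non-parametric Mann–Kendall
test with a Theil–Sen slope.  Regional trends are ordinary least squares
on the area-weighted, mean-normalised spatial mean, read in % per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
import xarray as xr
from scipy import stats

from .errors import ValidationError
from .preprocessing import mean_normalise

__all__ = [
    "TrendResult",
    "JackknifeAssessment",
    "jackknife_windows",
    "mann_kendall",
    "pixel_trend",
    "regional_trend",
    "delta_npp",
]

#: grams of carbon per mole, days per year, grams per petagram
CARBON_MOLAR_MASS = 12.011
DAYS_PER_YEAR = 365.0
GRAMS_PER_PG = 1e15


@dataclass(frozen=True)
class TrendResult:
    """Outcome of a single-pixel trend fit."""

    slope: float
    p_value: float
    method: str  # {"huber", "mann_kendall", "none"}
    normality_p: float
    n_used: int
    stderr: float = float("nan")  # slope standard error (Huber path only)


@dataclass(frozen=True)
class JackknifeAssessment:
    """One contiguous retained window of the time axis (indices, inclusive)."""

    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def slice(self) -> slice:
        return slice(self.start, self.end + 1)


def jackknife_windows(n_years: int, window: int) -> list[JackknifeAssessment]:
    """All contiguous windows of ``window`` years obtained by trimming only
    start and/or end years; exactly ``n_years − window + 1`` assessments
    (e.g. 26 years retained at 20 gives 7)."""
    if window <= 0:
        raise ValidationError("window must be positive")
    if window > n_years:
        raise ValidationError(f"window {window} exceeds series length {n_years}")
    return [
        JackknifeAssessment(index=i + 1, start=i, end=i + window - 1)
        for i in range(n_years - window + 1)
    ]


def mann_kendall(values: np.ndarray) -> tuple[float, float]:
    """Mann–Kendall trend test: returns (S, two-sided p).

    Uses the tie-corrected variance and a continuity-corrected normal
    approximation; p depends only on the ordering of the values, so it is
    invariant under strictly monotone transforms.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("Mann–Kendall needs at least two values")
    s = 0.0
    for i in range(n - 1):
        s += np.sign(x[i + 1 :] - x[i]).sum()
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0
    if var_s <= 0:  # all values tied
        return 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(s), float(p)


def pixel_trend(
    values: np.ndarray,
    years: np.ndarray | None = None,
    min_frac: float = 0.5,
    alpha: float = 0.05,
    huber_eps: float = 1.35,
) -> TrendResult:
    """Normality-gated per-pixel trend of an annual series.

    ``alpha`` is the significance level of the normality gate.  Missing
    values (NaN) count against the ``min_frac`` coverage rule, which is
    applied both before fitting and — for the Huber branch — after
    counting down-weighted points (final IRLS weight < 1) as removed.
    """
    y = np.asarray(values, dtype=float)
    n_total = y.size
    if years is None:
        years = np.arange(n_total, dtype=float)
    t = np.asarray(years, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    n_avail = int(ok.sum())
    if n_avail < min_frac * n_total or n_avail < 3:
        return TrendResult(np.nan, np.nan, "none", np.nan, n_avail)
    yv, tv = y[ok], t[ok]

    if np.ptp(yv) == 0:  # constant series: zero trend by definition
        return TrendResult(0.0, 1.0, "huber", np.nan, n_avail)

    if n_avail >= 8:
        _, norm_p = stats.normaltest(yv)
    else:
        norm_p = 0.0  # too short to assess normality; use the rank-based path

    if norm_p >= alpha:
        return _huber_fit(yv, tv, n_total, min_frac, huber_eps, norm_p)

    slope, _, _, _ = stats.theilslopes(yv, tv)
    _, p = mann_kendall(yv)
    return TrendResult(float(slope), p, "mann_kendall", float(norm_p), n_avail)


def _huber_fit(
    yv: np.ndarray,
    tv: np.ndarray,
    n_total: int,
    min_frac: float,
    huber_eps: float,
    norm_p: float,
) -> TrendResult:
    X = sm.add_constant(tv)
    # exact-line shortcut: a perfect linear fit has zero scale, where the
    # robust iteration is undefined; the Huber solution then IS the OLS one
    ols = sm.OLS(yv, X).fit()
    resid_scale = np.sqrt(ols.ssr / max(yv.size - 2, 1))
    if resid_scale <= 1e-12 * max(np.abs(yv).max(), 1.0):
        p = 0.0 if ols.params[1] != 0 else 1.0
        return TrendResult(float(ols.params[1]), p, "huber", float(norm_p), yv.size, 0.0)

    rlm = sm.RLM(yv, X, M=sm.robust.norms.HuberT(t=huber_eps)).fit()
    kept = int(np.sum(rlm.weights >= 1.0 - 1e-12))
    if kept < min_frac * n_total:
        return TrendResult(np.nan, np.nan, "none", float(norm_p), kept)
    slope = float(rlm.params[1])
    se = float(rlm.bse[1])
    p = 2.0 * stats.norm.sf(abs(slope / se))
    return TrendResult(slope, float(p), "huber", float(norm_p), yv.size, se)


#: integer codes used when trend maps are written to gridded layers
METHOD_CODES = {"none": 0, "huber": 1, "mann_kendall": 2}


def trend_maps(
    field: xr.DataArray,
    min_frac: float = 0.5,
    alpha: float = 0.05,
    huber_eps: float = 1.35,
) -> xr.Dataset:
    """Per-pixel trends of a (year, lat, lon) field as gridded layers:
    slope, p-value, method code (:data:`METHOD_CODES`) and normality p."""
    years = np.asarray(field["year"].values, dtype=float)
    vals = field.values
    nlat, nlon = vals.shape[1], vals.shape[2]
    slope = np.full((nlat, nlon), np.nan)
    p = np.full((nlat, nlon), np.nan)
    code = np.zeros((nlat, nlon), dtype=np.int8)
    norm_p = np.full((nlat, nlon), np.nan)
    for i in range(nlat):
        for j in range(nlon):
            r = pixel_trend(vals[:, i, j], years, min_frac, alpha, huber_eps)
            slope[i, j] = r.slope
            p[i, j] = r.p_value
            code[i, j] = METHOD_CODES[r.method]
            norm_p[i, j] = r.normality_p
    return xr.Dataset(
        {
            "slope": (("lat", "lon"), slope, {"units": "units year-1"}),
            "p_value": (("lat", "lon"), p),
            "method_code": (("lat", "lon"), code, {"codes": str(METHOD_CODES)}),
            "normality_p": (("lat", "lon"), norm_p),
        },
        coords={"lat": field["lat"], "lon": field["lon"]},
    )


def weighted_spatial_mean(field: xr.DataArray, weights: np.ndarray) -> np.ndarray:
    """Area-weighted spatial mean per year, renormalising weights over the
    cells available that year; years with zero coverage come out NaN."""
    vals = field.values  # (year, lat, lon)
    w = np.asarray(weights, dtype=float)[None, :, :]
    finite = np.isfinite(vals)
    wsum = np.where(finite, w, 0.0).sum(axis=(1, 2))
    num = np.where(finite, w * vals, 0.0).sum(axis=(1, 2))
    with np.errstate(invalid="ignore"):
        return np.where(wsum > 0, num / wsum, np.nan)


def regional_trend(field: xr.DataArray, weights: np.ndarray) -> float:
    """Trend of the area-weighted, mean-normalised spatial mean, % per year.

    Scale-invariant: multiplying the field by any positive constant leaves
    the result unchanged.
    """
    series = weighted_spatial_mean(field, weights)
    years = np.asarray(field["year"].values, dtype=float)
    ok = np.isfinite(series)
    if ok.sum() < 2:
        raise ValidationError("need at least two years with spatial coverage")
    norm = mean_normalise(series[ok])
    if not np.isfinite(norm).any():
        raise ValidationError("mean-normalisation undefined (zero-mean series)")
    slope = np.polyfit(years[ok], norm, 1)[0]
    return float(slope * 100.0)


def delta_npp(
    hist: xr.DataArray,
    future: xr.DataArray,
    weights: np.ndarray,
    ocean_area: float,
    hist_window: tuple[int, int],
    future_window: tuple[int, int],
    units: str = "mol C m-2 d-1",
) -> float:
    """Change in globally integrated NPP between two reference windows,
    in Pg C per year.

    Both windows are (first_year, last_year) inclusive and must be present
    in their respective series.  ``units`` of the input flux may be
    ``"mol C m-2 d-1"`` (converted at 12.011 g C per mole) or
    ``"mg C m-2 d-1"``; a 365-day year and 1 Pg = 1e15 g are used.
    """

    def window_mean(da: xr.DataArray, window: tuple[int, int]) -> float:
        years = np.asarray(da["year"].values)
        lo, hi = window
        sel = (years >= lo) & (years <= hi)
        if sel.sum() != hi - lo + 1:
            raise ValidationError(f"window {window} not fully present in series")
        series = weighted_spatial_mean(da.isel(year=sel), weights)
        return float(np.nanmean(series))

    diff = window_mean(future, future_window) - window_mean(hist, hist_window)
    if units == "mol C m-2 d-1":
        grams = diff * CARBON_MOLAR_MASS
    elif units == "mg C m-2 d-1":
        grams = diff * 1e-3
    else:
        raise ValidationError(f"unsupported flux units {units!r}")
    return grams * DAYS_PER_YEAR * ocean_area / GRAMS_PER_PG
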