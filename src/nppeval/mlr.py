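"""Per-pixel multiple linear regression of NPP on its drivers.

Each pixel's mean-normalised NPP series is regressed (OLS with
intercept) on the mean-normalised SST, CHL and MLD series over the
retained assessment window, with a heteroskedasticity-and-
autocorrelation-consistent (Newey–West) covariance whose lag follows the
rule of thumb ``floor(4·(T/100)^(2/9))``.  Pixels with a missing year or
a near-zero-variance driver are skipped.  Coefficients survive to the
maps only where both the coefficient's own HAC t-test and the model
F-test are significant (each gate switchable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

from .errors import ValidationError
from .preprocessing import mean_normalise
from .synthetic import DRIVERS
from .trends import JackknifeAssessment

__all__ = [
    "DriverCoefficients",
    "newey_west_lag",
    "fit_pixel_mlr",
    "mlr_coefficient_maps",
    "zonal_summary",
]

log = logging.getLogger(__name__)

#: variance below which a mean-normalised driver counts as constant ("~0")
VAR_TOL = 1e-10


@dataclass(frozen=True)
class DriverCoefficients:
    """Result of one pixel's driver regression."""

    beta: dict[str, float]
    p_values: dict[str, float]
    beta_se: dict[str, float]
    adjusted_r2: float
    model_p: float
    n: int
    hac_lag: int
    degenerate: bool = False  # zero residual variance; inference undefined


def newey_west_lag(T: int) -> int:
    """Newey–West rule-of-thumb truncation lag, floor(4·(T/100)^(2/9))."""
    if T < 1:
        raise ValidationError(f"series length must be >= 1, got {T}")
    return math.floor(4.0 * (T / 100.0) ** (2.0 / 9.0))


def fit_pixel_mlr(
    npp: np.ndarray,
    sst: np.ndarray,
    chl: np.ndarray,
    mld: np.ndarray,
    var_tol: float = VAR_TOL,
    normalise: bool = True,
) -> DriverCoefficients | None:
    """Fit one pixel's MLR; returns None (the skip sentinel) when any
    series has a missing year or any driver's variance is ~0.

    With ``normalise`` (default) each series is divided by its mean
    first, which is the scale on which coefficients are comparable
    across pixels and datasets.  HAC (Newey–West) standard errors with
    the rule-of-thumb lag and a Student-t reference distribution give
    the per-coefficient p-values; the model p is the corresponding
    robust F-test.  A perfect (zero-residual) fit is returned with
    p-values of 0 and ``degenerate=True`` since sampling inference is
    undefined there.
    """
    series = {"npp": np.asarray(npp, float), "sst": np.asarray(sst, float),
              "chl": np.asarray(chl, float), "mld": np.asarray(mld, float)}
    T = series["npp"].size
    for name, v in series.items():
        if v.size != T:
            raise ValidationError("all series must share one length")
        if not np.isfinite(v).all():
            return None
    if normalise:
        series = {k: mean_normalise(v) for k, v in series.items()}
        if any(not np.isfinite(v).all() for v in series.values()):
            return None  # zero-mean normalisation sentinel
    for d in DRIVERS:
        if np.var(series[d]) <= var_tol:
            return None

    y = series["npp"]
    X = sm.add_constant(np.column_stack([series[d] for d in DRIVERS]))
    lag = newey_west_lag(T)
    ols = sm.OLS(y, X).fit()
    resid_scale = np.sqrt(ols.ssr / max(T - X.shape[1], 1))
    if resid_scale <= 1e-10 * max(np.abs(y).max(), 1.0):
        beta = dict(zip(DRIVERS, ols.params[1:]))
        return DriverCoefficients(
            beta=beta,
            p_values={d: 0.0 for d in DRIVERS},
            beta_se={d: 0.0 for d in DRIVERS},
            adjusted_r2=1.0,
            model_p=0.0,
            n=T,
            hac_lag=lag,
            degenerate=True,
        )
    res = ols.get_robustcov_results(cov_type="HAC", maxlags=lag, use_correction=True, use_t=True)
    beta = dict(zip(DRIVERS, res.params[1:]))
    pvals = dict(zip(DRIVERS, res.pvalues[1:]))
    return DriverCoefficients(
        beta=beta,
        p_values=pvals,
        beta_se=dict(zip(DRIVERS, res.bse[1:])),
        adjusted_r2=float(ols.rsquared_adj),
        model_p=float(res.f_pvalue),
        n=T,
        hac_lag=lag,
    )


def mlr_coefficient_maps(
    dataset: xr.Dataset,
    assessment: JackknifeAssessment | None = None,
    alpha: float = 0.05,
    var_tol: float = VAR_TOL,
    require_coef_significance: bool = True,
    require_model_significance: bool = True,
) -> xr.Dataset:
    """Per-pixel MLR over one retained window, returned as coefficient maps.

    The output dataset holds, per driver, the coefficient field
    ``beta_<driver>``, its p-value field ``p_<driver>`` and a boolean
    ``sig_<driver>`` mask (coefficient p ≤ alpha and, when enabled, model
    p ≤ alpha), plus ``adjusted_r2`` and skip-count attrs.  Masked or
    skipped cells are NaN.
    """
    for v in ("npp",) + tuple(DRIVERS):
        if v not in dataset:
            raise ValidationError(f"dataset missing variable {v!r}")
    if dataset.sizes.get("lat", 0) == 0 or dataset.sizes.get("lon", 0) == 0:
        raise ValidationError("empty grid")
    if assessment is not None:
        dataset = dataset.isel(year=assessment.slice)

    nlat, nlon = dataset.sizes["lat"], dataset.sizes["lon"]
    shape = (nlat, nlon)
    out = {f"beta_{d}": np.full(shape, np.nan) for d in DRIVERS}
    out.update({f"p_{d}": np.full(shape, np.nan) for d in DRIVERS})
    out.update({f"sig_{d}": np.zeros(shape, dtype=bool) for d in DRIVERS})
    out["adjusted_r2"] = np.full(shape, np.nan)
    out["model_p"] = np.full(shape, np.nan)

    arrays = {v: dataset[v].values for v in ("npp",) + tuple(DRIVERS)}
    n_skipped = 0
    for i in range(nlat):
        for j in range(nlon):
            fit = fit_pixel_mlr(
                arrays["npp"][:, i, j],
                arrays["sst"][:, i, j],
                arrays["chl"][:, i, j],
                arrays["mld"][:, i, j],
                var_tol=var_tol,
            )
            if fit is None:
                n_skipped += 1
                continue
            model_ok = (not require_model_significance) or fit.model_p <= alpha
            for d in DRIVERS:
                out[f"beta_{d}"][i, j] = fit.beta[d]
                out[f"p_{d}"][i, j] = fit.p_values[d]
                coef_ok = (not require_coef_significance) or fit.p_values[d] <= alpha
                out[f"sig_{d}"][i, j] = coef_ok and model_ok
            out["adjusted_r2"][i, j] = fit.adjusted_r2
            out["model_p"][i, j] = fit.model_p

    maps = xr.Dataset(
        {k: (("lat", "lon"), v) for k, v in out.items()},
        coords={"lat": dataset["lat"], "lon": dataset["lon"]},
    )
    maps.attrs["n_skipped"] = n_skipped
    maps.attrs["alpha"] = alpha
    if assessment is not None:
        maps.attrs["assessment"] = assessment.index
    if n_skipped:
        log.info("mlr_coefficient_maps: skipped %d pixels (coverage/variance)", n_skipped)
    return maps


def zonal_summary(maps: xr.Dataset) -> pd.DataFrame:
    """Zonal mean ± standard deviation per driver, over significant cells only."""
    rows = []
    for d in DRIVERS:
        beta = maps[f"beta_{d}"].where(maps[f"sig_{d}"])
        rows.append(
            pd.DataFrame(
                {
                    "lat": maps["lat"].values,
                    "driver": d,
                    "mean": beta.mean(dim="lon", skipna=True).values,
                    "std": beta.std(dim="lon", skipna=True, ddof=1).values,
                    "n": beta.notnull().sum(dim="lon").values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
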