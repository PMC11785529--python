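"""Gridded file I/O.

Datasets travel as self-describing NetCDF files (classic format via the
scipy backend) with CF-like metadata: coordinate variables, ``units``
attributes and NaN missing values.  Booleans are stored as int8 with a
marker attribute and restored on read.  Truth records are serialised as
a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import xarray as xr

from .synthetic import DRIVERS, TruthRecord

__all__ = ["write_gridded", "read_gridded", "write_truth", "read_truth"]

log = logging.getLogger(__name__)

_KNOWN_UNITS = {"mg C m-2 d-1", "mol C m-2 d-1", "degC", "mg m-3", "m", "units year-1"}


def write_gridded(dataset: xr.Dataset, path: str | Path) -> None:
    """Write a dataset; round-trips values, masks, units and grid metadata."""
    ds = dataset.copy()
    for name in ds.data_vars:
        if ds[name].dtype == bool:
            attrs = dict(ds[name].attrs)
            ds[name] = ds[name].astype(np.int8)
            ds[name].attrs = {**attrs, "stored_as": "bool"}
    ds.to_netcdf(path, engine="scipy")


def read_gridded(path: str | Path) -> xr.Dataset:
    """Read a dataset written by :func:`write_gridded`.

    Unknown ``units`` attributes produce a warning, not an error; a
    malformed file raises a parse error naming the file.
    """
    try:
        ds = xr.load_dataset(path, engine="scipy")
    except (OSError, ValueError, TypeError) as exc:
        raise OSError(f"could not parse gridded file {path}: {exc}") from exc
    for name in ds.data_vars:
        if ds[name].attrs.get("stored_as") == "bool":
            attrs = {k: v for k, v in ds[name].attrs.items() if k != "stored_as"}
            ds[name] = ds[name].astype(bool)
            ds[name].attrs = attrs
        units = ds[name].attrs.get("units")
        if units is not None and units not in _KNOWN_UNITS:
            warnings.warn(f"unknown units {units!r} on variable {name!r} in {path}")
    return ds


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    payload = {
        "intercept": np.asarray(truth.intercept).tolist(),
        "beta": {d: np.asarray(truth.beta[d]).tolist() for d in DRIVERS},
        "driver_trends": {d: np.asarray(truth.driver_trends[d]).tolist() for d in DRIVERS},
        "ar1_phi": truth.ar1_phi,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "ensemble_shifts": truth.ensemble_shifts.tolist(),
        "ensemble_delta_npp": truth.ensemble_delta_npp.tolist(),
        "driver_base": truth.driver_base,
        "npp_scale": truth.npp_scale,
        "driver_cycles": {d: list(truth.driver_cycles[d]) for d in DRIVERS},
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> TruthRecord:
    raw = json.loads(Path(path).read_text())
    return TruthRecord(
        intercept=np.asarray(raw["intercept"]),
        beta={d: np.asarray(raw["beta"][d]) for d in DRIVERS},
        driver_trends={d: np.asarray(raw["driver_trends"][d]) for d in DRIVERS},
        ar1_phi=raw["ar1_phi"],
        noise_sd=raw["noise_sd"],
        seed=raw["seed"],
        ensemble_shifts=np.asarray(raw["ensemble_shifts"]),
        ensemble_delta_npp=np.asarray(raw["ensemble_delta_npp"]),
        driver_base=raw["driver_base"],
        npp_scale=raw["npp_scale"],
        driver_cycles={d: tuple(raw["driver_cycles"][d]) for d in DRIVERS},
    )
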